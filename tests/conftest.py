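import numpy as np
import pytest

from ascoh import coherence as coh
from ascoh import preprocessing as pp
from ascoh import synthetic_data as sd

#: Documented seed for the default synthetic study cohort used across tests.
COHORT_SEED = 20260


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 45 patients, 50/50 severe/mild."""
    return sd.generate_cohort(sd.SyntheticCohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_spectra(default_cohort):
    """Autocorrelation spectra + latent labels for the default cohort."""
    spectra, latent, doses = [], [], []
    for p in default_cohort.patients:
        u = pp.resample_to_uniform(p.beats)
        spectra.append(coh.autocorrelation_spectrum(u))
        latent.append(1 if p.latent_class == "severe" else 0)
        doses.append(p.dose_mcg)
    return spectra, np.array(latent), np.array(doses)


@pytest.fixture(scope="session")
def cohort_metrics(cohort_spectra):
    spectra, latent, doses = cohort_spectra
    values = np.array([coh.coherence_metric(s).value for s in spectra])
    return values, latent, doses
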