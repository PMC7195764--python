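"""Synthetic cohorts of beat-by-beat arterial-stiffness (AS) series.

The study population this emulates: patients monitored before spinal
anesthesia whose AS parameter — a unitless pulse-contour index reported
once per heartbeat — either shows slow coherent modulations on a ~3 min
time scale (patients who later needed large cumulative phenylephrine
doses to treat post-induction hypotension, "severe") or near-incoherent
noise ("mild").  Each synthetic patient carries a latent class, a beat
train at a physiologic heart rate, an AS trace, an assigned total
phenylephrine dose (mcg, quantized to the 100 mcg bolus size), and
optional baseline covariates that are independent of dose by
construction.

Nothing here simulates raw arterial pulses or blood pressure; AS values
are produced directly on an arbitrary unit scale with baseline 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortConfig",
    "BeatSeries",
    "SimPatient",
    "Cohort",
    "generate_beat_times",
    "generate_as_series",
    "assign_dose",
    "generate_cohort",
    "write_cohort",
]

#: Baseline-covariate vocabulary (names shared with :mod:`ascoh.evaluation`).
COVARIATE_NAMES = (
    "pre_op_systole_mmHg",
    "prior_cs",
    "hypertension",
    "diabetes",
    "copd",
    "atrial_fibrillation",
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generator settings; defaults are the calibrated study conditions.

    The dose link (``dose = intercept + slope * amplitude + noise``,
    clipped at 0 and quantized to 100 mcg) is calibrated so that a 50/50
    severe/mild cohort has dose mean ~460 mcg and SD ~300 mcg, with a few
    mild patients clipping to a zero dose.
    """

    n_patients: int = 45
    hr_range_bpm: tuple[float, float] = (70.0, 103.0)
    duration_s: float = 2700.0
    osc_period_s: float = 180.0
    amp_severe: float = 1.0
    amp_mild: float = 0.2
    baseline: float = 1.0
    noise_sd: float = 0.35
    ar_coeff: float = 0.3
    dose_intercept_mcg: float = 160.0
    dose_slope_mcg_per_amp: float = 500.0
    dose_noise_sd_mcg: float = 220.0
    frac_severe: float = 0.5
    artifact_burst: tuple[int, float] | None = None
    with_covariates: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.hr_range_bpm
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 < lo <= hi):
            raise ValueError("heart-rate bounds must be positive with low <= high")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.osc_period_s <= 0:
            raise ValueError("osc_period_s must be positive")
        if not 0.0 <= self.frac_severe <= 1.0:
            raise ValueError("frac_severe must lie in [0, 1]")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if self.noise_sd < 0 or self.dose_noise_sd_mcg < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class BeatSeries:
    """One patient's beat-by-beat AS observations (non-uniform timestamps)."""

    patient_id: str
    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times_s and values must be 1-D and equal length")
        if t.size < 2:
            raise ValueError("a beat series needs at least 2 beats")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("timestamps and values must be finite")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class SimPatient:
    patient_id: str
    beats: BeatSeries
    latent_class: str  # "severe" | "mild"
    dose_mcg: float
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Cohort:
    patients: tuple[SimPatient, ...]
    config: SyntheticCohortConfig | None = None
    exclusions: tuple = ()

    def __len__(self) -> int:
        return len(self.patients)

    def manifest_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {
                "patient_id": p.patient_id,
                "dose_mcg": p.dose_mcg,
                "latent_class": p.latent_class,
            }
            row.update(p.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def generate_beat_times(duration_s: float, hr_range_bpm=(70.0, 103.0), seed=0) -> np.ndarray:
    """Beat timestamps from a reflecting lag-1 random walk on heart rate.

    HR starts uniform inside ``hr_range_bpm``, takes Gaussian steps of
    SD 1 bpm per beat, and is reflected at the bounds, so every implied
    instantaneous rate 60/dt stays inside the configured band.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    lo, hi = float(hr_range_bpm[0]), float(hr_range_bpm[1])
    if not (0 < lo <= hi):
        raise ValueError("heart-rate bounds must be positive with low <= high")
    rng = _as_rng(seed)
    hr = lo if lo == hi else rng.uniform(lo, hi)
    times = [0.0]
    t = 0.0
    while True:
        t += 60.0 / hr
        if t > duration_s + 1e-9:
            break
        times.append(t)
        if hi > lo:
            hr += rng.normal(0.0, 1.0)
            # reflect into [lo, hi]
            while hr < lo or hr > hi:
                if hr > hi:
                    hr = 2 * hi - hr
                if hr < lo:
                    hr = 2 * lo - hr
    return np.asarray(times)


def generate_as_series(beat_times, class_label: str, config: SyntheticCohortConfig,
                       seed=0, patient_id: str = "sim") -> BeatSeries:
    """AS value per beat: baseline + class-amplitude sinusoid + AR(1) noise.

    The sinusoid has period ``config.osc_period_s`` (default 180 s, the
    ~3 min modulation seen in severe-hypotension patients) and a phase
    drawn uniformly per patient.  The AR(1) noise has stationary SD
    ``config.noise_sd``.  Optional square artifact bursts (10 s long,
    additive) are confined to the first 300 s of the session.
    """
    t = np.asarray(beat_times, dtype=float)
    if class_label == "severe":
        amp = config.amp_severe
    elif class_label == "mild":
        amp = config.amp_mild
    else:
        raise ValueError(f"unknown class_label {class_label!r}; expected 'severe' or 'mild'")
    rng = _as_rng(seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    signal = config.baseline + amp * np.sin(2.0 * math.pi * t / config.osc_period_s + phase)

    n = t.size
    noise = np.zeros(n)
    if config.noise_sd > 0:
        from scipy.signal import lfilter

        rho = config.ar_coeff
        innov_sd = config.noise_sd * math.sqrt(1.0 - rho * rho)
        innov = rng.normal(0.0, innov_sd, size=n)
        innov[0] = rng.normal(0.0, config.noise_sd)  # stationary start
        noise = lfilter([1.0], [1.0, -rho], innov)

    values = signal + noise
    if config.artifact_burst is not None:
        count, magnitude = config.artifact_burst
        burst_len = 10.0
        for _ in range(int(count)):
            start = rng.uniform(0.0, max(300.0 - burst_len, 0.0))
            mask = (t >= start) & (t < start + burst_len)
            values = values + np.where(mask, magnitude, 0.0)
    return BeatSeries(patient_id=patient_id, times_s=t, values=values)


def assign_dose(amplitude: float, config: SyntheticCohortConfig, seed=0) -> float:
    """Total phenylephrine dose (mcg) linked linearly to modulation amplitude.

    Clipped at zero (some patients need no vasopressor) and quantized to
    the 100 mcg bolus size.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = _as_rng(seed)
    dose = config.dose_intercept_mcg + config.dose_slope_mcg_per_amp * amplitude
    if config.dose_noise_sd_mcg > 0:
        dose += rng.normal(0.0, config.dose_noise_sd_mcg)
    dose = max(0.0, dose)
    return float(np.round(dose / 100.0) * 100.0)


def _draw_covariates(rng: np.random.Generator) -> dict:
    """Baseline covariates independent of dose; prevalences from a 45-patient
    obstetric cohort (prior C/S 9/45, hypertension 6/45, diabetes 6/45, COPD
    and atrial fibrillation absent)."""
    return {
        "pre_op_systole_mmHg": float(rng.normal(128.9, 19.14)),
        "prior_cs": int(rng.random() < 9 / 45),
        "hypertension": int(rng.random() < 6 / 45),
        "diabetes": int(rng.random() < 6 / 45),
        "copd": 0,
        "atrial_fibrillation": 0,
    }


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Deterministic cohort: latent classes, beat trains, AS traces, doses."""
    n = config.n_patients
    n_severe = int(round(n * config.frac_severe))
    labels = ["severe"] * n_severe + ["mild"] * (n - n_severe)

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n)
    patients = []
    for i, (label, child) in enumerate(zip(labels, children)):
        beat_ss, series_ss, dose_ss, cov_ss = child.spawn(4)
        pid = f"P{i + 1:03d}"
        times = generate_beat_times(config.duration_s, config.hr_range_bpm,
                                    np.random.default_rng(beat_ss))
        beats = generate_as_series(times, label, config,
                                   np.random.default_rng(series_ss), patient_id=pid)
        amp = config.amp_severe if label == "severe" else config.amp_mild
        dose = assign_dose(amp, config, np.random.default_rng(dose_ss))
        cov = _draw_covariates(np.random.default_rng(cov_ss)) if config.with_covariates else {}
        patients.append(SimPatient(pid, beats, label, dose, cov))
    return Cohort(patients=tuple(patients), config=config)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write per-patient beat CSVs (time_s, as_value) and a manifest CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    beats_dir = outdir / "beats"
    beats_dir.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        pd.DataFrame({"time_s": p.beats.times_s, "as_value": p.beats.values}).to_csv(
            beats_dir / f"{p.patient_id}.csv", index=False)
    cohort.manifest_frame().to_csv(outdir / "manifest.csv", index=False)
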