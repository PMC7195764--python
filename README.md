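# ascoh — coherence of arterial-stiffness dynamics and post-spinal hypotension

`ascoh` is an analysis pipeline for a question from obstetric anesthesia:
can the severity of hypotension after spinal anesthesia for Cesarean
section be predicted *before* induction, non-invasively?  The input is a
beat-by-beat arterial-stiffness (AS) parameter — a unitless pulse-contour
index reported once per heartbeat — recorded in the preoperative period.
The clinical severity label is the cumulative phenylephrine dose (given
as 100 mcg boluses) needed to keep systolic pressure above 90 mmHg after
induction.

The working hypothesis: patients who go on to need large vasopressor
doses show slow, coherent AS modulations (time scales on the order of
3 minutes) before induction, while mild patients show low-coherence
noise.  The pipeline quantifies this and assesses it two ways:

1. **Discrete single feature.** The beat series is cubic-spline
   resampled to a uniform 10 Hz grid over a 2000 s artifact-free window
   (20,000 samples), and the normalized autocorrelation spectrum
   r(k) = c(k)/c(0) is computed with the biased, mean-subtracted
   estimator.  The coherence statistic is the absolute-area integral
   ∫₁₀₀²⁰⁰⁰ |r(τ)| dτ, which is large for persistent oscillatory
   autocorrelation and small for rapidly decaying noise.  ROC analysis
   against dose-threshold labels, with the Youden index
   J = sensitivity + specificity − 1 selecting the operating cutoff,
   and a sweep over dosage thresholds, assess the metric.
2. **Neural network.** A from-scratch fully connected MLP (default one
   hidden layer of 12 nodes, log-sigmoid activations everywhere,
   full-batch gradient descent on MSE, learning rate 0.01, early
   stopping with patience 6 on a validation split) classifies the
   block-averaged spectra.  Performance is reported over ensembles of
   runs with random 0.7/0.15/0.15 splits and random initialization
   (mean absolute classification error, mean test AUC), plus
   width/depth sweep surfaces for architecture selection.

Because no patient-level recordings are publicly deposited, a
first-class synthetic-cohort generator emulates the study conditions
(heart rates 70–103 bpm, 180 s modulations in severe patients, a
dose distribution calibrated to mean ≈ 462 mcg / SD ≈ 299 mcg, optional
early motion artifacts) with known latent classes, so every stage can
be validated truth-in/truth-out.

## Worked example

```bash
python analysis/01_simulate_cohort.py   --out results
python analysis/02_coherence_metrics.py --out results
python analysis/03_discrete_classification.py --out results
python analysis/04_nn_ensemble.py       --out results
python analysis/05_architecture_sweep.py --out results --runs 20
```

With the default seed (20260) this prints:

```
wrote 45 patients to results/cohort
latent classes: 22 severe / 23 mild
dose mean 473 mcg, SD 258 mcg, 1 patients with zero dose

coherence metric by latent class (n=45):
               mean  std
mild           86.2  8.3
severe        465.7  5.5

dose threshold 400 mcg: AUC 0.743, Youden J 0.60 (sens 0.77, spec 0.83)
sweep optima: AUC-best threshold 200 mcg, Youden-best 300 mcg
AUC against latent class: 1.000

100 runs, nodes [12], dose threshold 450 mcg
mean abs error 0.408 (SD 0.071, range 0.276-0.600)
mean AUC 0.738, pooled AUC 0.728, run-count converged: False
```

Reading this: the coherence metric separates the latent physiological
classes perfectly (AUC 1.000 — severe patients' metrics cluster near
466 s, mild near 86 s), while classification against *dose-threshold*
labels is weaker (AUC 0.74) because the dose carries substantial
within-class noise — the dose is a noisy proxy for the latent state,
which is exactly the structure the clinical problem has.  The same
library functions power the `ascoh` CLI
(`ascoh simulate|preprocess|coherence|evaluate|nn|all --config cfg.yaml
--out dir [--seed N]`).

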