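"""Discrete-feature classification assessment.

Patients are labeled severe when their cumulative phenylephrine dose
strictly exceeds a threshold (doses come in 100 mcg boluses; the
at-threshold tie goes to the mild class).  The coherence metric is the
score, oriented a priori: higher coherence predicts severe.  AUC is the
rank (Mann-Whitney) statistic with ties half-credited, which equals the
trapezoid area under the empirical ROC; the Youden index J = sens +
spec - 1 picks the operating cutoff, ties broken toward higher
specificity.

Also here: the dosage-threshold sweep, Pearson/point-biserial
correlations of baseline covariates with dose, and the minimum-sample-
size calculation for estimating an AUC, using the Hanley-McNeil
variance with the exponential-distribution forms Q1 = A/(2-A),
Q2 = 2A^2/(1+A).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, rankdata

from .errors import DegenerateLabelsError

__all__ = [
    "PatientRecord",
    "RocResult",
    "SampleSizeResult",
    "label_by_dose",
    "roc_curve",
    "youden_optimum",
    "dose_threshold_sweep",
    "DoseSweepResult",
    "baseline_correlations",
    "auc_sample_size",
]

COVARIATE_VOCABULARY = frozenset({
    "pre_op_systole_mmHg",
    "prior_cs",
    "hypertension",
    "diabetes",
    "copd",
    "atrial_fibrillation",
})


@dataclass(frozen=True)
class PatientRecord:
    """One analyzed patient: dose label source, coherence score, covariates."""

    patient_id: str
    dose_mcg: float
    metric: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dose_mcg < 0:
            raise ValueError("dose_mcg must be non-negative")
        unknown = set(self.covariates) - COVARIATE_VOCABULARY
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    youden_j: float
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    dose_threshold_mcg: float | None = None


def label_by_dose(doses, dose_threshold_mcg: float) -> np.ndarray:
    """1 (severe) iff dose strictly exceeds the threshold, else 0."""
    if dose_threshold_mcg < 0:
        raise ValueError("dose_threshold_mcg must be non-negative")
    d = np.asarray([r.dose_mcg if isinstance(r, PatientRecord) else r for r in doses],
                   dtype=float)
    return (d > dose_threshold_mcg).astype(int)


def rank_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties half-credited."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, labels, dose_threshold_mcg: float | None = None) -> RocResult:
    """Empirical ROC over all distinct score cutoffs (predict severe if score >= cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = rank_auc(scores, labels)  # raises on single-class input
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    cutoffs = np.unique(scores)[::-1]
    tpr = np.empty(cutoffs.size + 1)
    fpr = np.empty(cutoffs.size + 1)
    thresholds = np.empty(cutoffs.size + 1)
    tpr[0], fpr[0], thresholds[0] = 0.0, 0.0, np.inf
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    for i, c in enumerate(cutoffs, start=1):
        tpr[i] = np.count_nonzero(pos_scores >= c) / n_pos
        fpr[i] = np.count_nonzero(neg_scores >= c) / n_neg
        thresholds[i] = c

    j = tpr - fpr
    best_j = float(j.max())
    # among maximizers prefer higher specificity (lower fpr)
    maximizers = np.flatnonzero(j >= best_j - 1e-12)
    k = maximizers[np.argmin(fpr[maximizers])]
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     youden_j=best_j, optimal_cutoff=float(thresholds[k]),
                     sensitivity=float(tpr[k]), specificity=float(1.0 - fpr[k]),
                     n_pos=n_pos, n_neg=n_neg, dose_threshold_mcg=dose_threshold_mcg)


def youden_optimum(roc: RocResult) -> tuple[float, float, float, float]:
    """(cutoff, J, sensitivity, specificity) at the Youden-optimal operating point."""
    return roc.optimal_cutoff, roc.youden_j, roc.sensitivity, roc.specificity


@dataclass(frozen=True)
class DoseSweepResult:
    results: tuple[RocResult, ...]
    best_auc_threshold_mcg: float
    best_youden_threshold_mcg: float
    skipped_thresholds: tuple[float, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_threshold_mcg": [r.dose_threshold_mcg for r in self.results],
            "auc": [r.auc for r in self.results],
            "youden_j": [r.youden_j for r in self.results],
            "sensitivity": [r.sensitivity for r in self.results],
            "specificity": [r.specificity for r in self.results],
            "optimal_cutoff": [r.optimal_cutoff for r in self.results],
            "n_pos": [r.n_pos for r in self.results],
            "n_neg": [r.n_neg for r in self.results],
        })


def dose_threshold_sweep(records, thresholds) -> DoseSweepResult:
    """ROC analysis at each dosage threshold; single-class thresholds are skipped."""
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds to sweep")
    scores = np.asarray([r.metric for r in records], dtype=float)
    doses = np.asarray([r.dose_mcg for r in records], dtype=float)
    results, skipped = [], []
    for thr in thresholds:
        labels = (doses > thr).astype(int)
        if labels.min() == labels.max():
            warnings.warn(f"dose threshold {thr} mcg yields a single class; skipped")
            skipped.append(float(thr))
            continue
        results.append(roc_curve(scores, labels, dose_threshold_mcg=float(thr)))
    if not results:
        raise DegenerateLabelsError("every threshold produced a single class")
    best_auc = max(results, key=lambda r: r.auc).dose_threshold_mcg
    best_j = max(results, key=lambda r: r.youden_j).dose_threshold_mcg
    return DoseSweepResult(results=tuple(results), best_auc_threshold_mcg=best_auc,
                           best_youden_threshold_mcg=best_j,
                           skipped_thresholds=tuple(skipped))


def baseline_correlations(records) -> pd.DataFrame:
    """Pearson (point-biserial for 0/1) correlation of each covariate with dose.

    Covariates without variation are flagged instead of correlated:
    all-zero binaries as "no positive patients", other constants as
    "no variance".  Two-sided p-values, no multiplicity correction.
    """
    doses = np.asarray([r.dose_mcg for r in records], dtype=float)
    names: list[str] = []
    for r in records:
        for name in r.covariates:
            if name not in names:
                names.append(name)
    rows = []
    for name in names:
        x = np.asarray([float(r.covariates[name]) for r in records])
        is_binary = set(np.unique(x)) <= {0.0, 1.0}
        if np.all(x == x[0]):
            note = "no positive patients" if is_binary and x[0] == 0.0 else "no variance"
            rows.append({"covariate": name, "r": np.nan, "p": np.nan, "note": note})
            continue
        r_val, p_val = pearsonr(x, doses)
        rows.append({"covariate": name, "r": float(r_val), "p": float(p_val), "note": ""})
    return pd.DataFrame(rows, columns=["covariate", "r", "p", "note"])


@dataclass(frozen=True)
class SampleSizeResult:
    n_total: int
    n_pos: int
    n_neg: int
    formula: str


def _hanley_mcneil_var(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    return (auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc * auc)
            + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)


def auc_sample_size(target_auc: float, margin: float, alpha: float, power: float,
                    allocation_ratio: float = 1.0,
                    null_auc: float | None = None) -> SampleSizeResult:
    """Minimum total n for an AUC study, Hanley-McNeil variance.

    Default (precision-with-power framing): smallest n such that

        (z_{1-alpha/2} + z_{power}) * SE_HM(target_auc; n) <= margin,

    i.e. the estimate pins the AUC within +/- margin at the stated
    confidence and power.  With ``null_auc`` given (typically 0.5), the
    one-sided power-against-null test framing is used instead and
    ``margin`` is ignored:

        z_{1-alpha} * SE_HM(null; n) + z_{power} * SE_HM(target; n)
            <= target_auc - null_auc.

    ``allocation_ratio`` is n_neg / n_pos.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie in (0.5, 1)")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if not (0.0 < alpha < 0.5 and 0.0 < 1.0 - power < 0.5):
        raise ValueError("need 0 < alpha < 0.5 and 0.5 < power < 1")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be positive")
    if null_auc is not None and not 0.5 <= null_auc < target_auc:
        raise ValueError("null_auc must lie in [0.5, target_auc)")

    z_power = norm.ppf(power)
    n_pos = 2
    while True:
        n_neg = max(2, math.ceil(allocation_ratio * n_pos))
        se1 = math.sqrt(_hanley_mcneil_var(target_auc, n_pos, n_neg))
        if null_auc is None:
            ok = (norm.ppf(1.0 - alpha / 2.0) + z_power) * se1 <= margin
        else:
            se0 = math.sqrt(_hanley_mcneil_var(null_auc, n_pos, n_neg))
            ok = (norm.ppf(1.0 - alpha) * se0 + z_power * se1
                  <= target_auc - null_auc)
        if ok:
            formula = ("precision: (z_{1-a/2}+z_power)*SE_HM(A) <= margin"
                       if null_auc is None else
                       f"one-sided test vs null AUC {null_auc}: "
                       "z_{1-a}*SE_HM(A0)+z_power*SE_HM(A) <= A-A0")
            return SampleSizeResult(n_total=n_pos + n_neg, n_pos=n_pos, n_neg=n_neg,
                                    formula=formula)
        n_pos += 1
        if n_pos > 10_000_000:  # pragma: no cover - guard against pathological inputs
            raise RuntimeError("sample-size search did not converge")
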