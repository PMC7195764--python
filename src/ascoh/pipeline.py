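"""End-to-end orchestration: simulate -> preprocess -> coherence -> evaluate -> nn.

Stages read their inputs from the output directory when they were not
produced in the same run, so individual stages can be re-run from disk.
Every artifact is a CSV (the domain has no standard beat-level
container) stamped with a leading comment line carrying the config hash
and master seed; the run summary is JSON.

Randomness: one master seed, from which named child seeds are derived
deterministically for the cohort generator and the network ensemble.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coherence as coh
from . import evaluation as ev
from . import neural_net as nn
from . import preprocessing as pp
from . import synthetic_data as sd
from .errors import InsufficientDataError

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "load_cohort"]

log = logging.getLogger("ascoh")

STAGES = ("simulate", "preprocess", "coherence", "evaluate", "nn")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    cohort: sd.SyntheticCohortConfig = field(default_factory=sd.SyntheticCohortConfig)
    window: pp.WindowSpec = field(default_factory=pp.WindowSpec)
    rate_hz: float = 10.0
    lag_min_s: float = 100.0
    lag_max_s: float = 2000.0
    dose_threshold_mcg: float = 400.0
    sweep_thresholds: tuple = tuple(float(t) for t in range(100, 801, 50))
    nn_dose_threshold_mcg: float = 450.0
    nn_feature_len: int = 400
    nn_nodes: tuple = (12,)
    nn_runs: int = 100
    nn_learning_rate: float = 0.01
    nn_max_epochs: int = 1000
    nn_patience: int = 6
    seed: int = 0
    stages: tuple = STAGES
    write_resampled: bool = False

    def child_seed(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = sd.SyntheticCohortConfig(**raw.pop("cohort", {}))
        window = pp.WindowSpec(**raw.pop("window", {}))
        for key in ("sweep_thresholds", "nn_nodes", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, window=window, **raw)


def _write_csv(frame: pd.DataFrame, path: Path, stamp: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        frame.to_csv(fh, index=False)


def load_cohort(manifest_path, beats_dir, min_duration_s: float | None = None) -> sd.Cohort:
    """Load a cohort from a manifest CSV plus per-patient beat CSVs.

    Rows with a missing beat file, too few beats, non-monotone or
    non-finite data, or (optionally) insufficient coverage are excluded
    with logged reasons; the exclusion list is attached to the cohort.
    """
    manifest_path, beats_dir = Path(manifest_path), Path(beats_dir)
    try:
        manifest = pd.read_csv(manifest_path, comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed manifest {manifest_path}: {exc}") from exc
    if manifest.empty:
        raise ValueError(f"manifest {manifest_path} contains no patients")

    cov_cols = [c for c in manifest.columns
                if c not in ("patient_id", "dose_mcg", "latent_class")]
    patients, exclusions = [], []
    for idx, row in manifest.iterrows():
        pid = str(row["patient_id"])
        beat_path = beats_dir / f"{pid}.csv"
        if not beat_path.exists():
            exclusions.append((pid, "beat file missing"))
            continue
        try:
            beats_df = pd.read_csv(beat_path, comment="#")
        except pd.errors.ParserError as exc:
            exclusions.append((pid, f"malformed beat CSV: {exc}"))
            continue
        try:
            beats = sd.BeatSeries(patient_id=pid,
                                  times_s=beats_df["time_s"].to_numpy(float),
                                  values=beats_df["as_value"].to_numpy(float))
        except (ValueError, KeyError) as exc:
            exclusions.append((pid, f"invalid beat series: {exc}"))
            continue
        if min_duration_s is not None and beats.times_s[-1] - beats.times_s[0] < min_duration_s:
            exclusions.append((pid, f"series too short "
                                    f"({beats.times_s[-1] - beats.times_s[0]:.0f} s)"))
            continue
        patients.append(sd.SimPatient(
            patient_id=pid, beats=beats,
            latent_class=str(row.get("latent_class", "")),
            dose_mcg=float(row["dose_mcg"]),
            covariates={c: row[c] for c in cov_cols if pd.notna(row[c])}))
    for pid, reason in exclusions:
        log.warning("excluding patient %s: %s", pid, reason)
    if not patients:
        raise ValueError("no usable patients after exclusions")
    return sd.Cohort(patients=tuple(patients), exclusions=tuple(exclusions))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the selected stages in order; returns the summary dict.

    A stage failure aborts with the stage name; artifacts written by
    earlier stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()} seed={config.seed}"
    state: dict = {}
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages_run": []}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _run_stage(stage, config, out, state, summary, stamp)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
        summary["stages_run"].append(stage)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _ensure_cohort(config, out, state) -> sd.Cohort:
    if "cohort" not in state:
        state["cohort"] = load_cohort(out / "cohort" / "manifest.csv",
                                      out / "cohort" / "beats")
    return state["cohort"]


def _ensure_uniform(config, out, state) -> dict:
    if "uniform" not in state:
        cohort = _ensure_cohort(config, out, state)
        uniform = {}
        for p in cohort.patients:
            try:
                start = pp.detect_artifact_free_start(p.beats, config.window)
                uniform[p.patient_id] = pp.resample_to_uniform(
                    p.beats, config.rate_hz, config.window, start_s=start)
            except InsufficientDataError as exc:
                log.warning("preprocess: excluding %s: %s", p.patient_id, exc)
        if not uniform:
            raise InsufficientDataError("no patient provided a usable analysis window")
        state["uniform"] = uniform
    return state["uniform"]


def _compute_spectra(config, out, state) -> None:
    uniform = _ensure_uniform(config, out, state)
    cohort = _ensure_cohort(config, out, state)
    by_id = {p.patient_id: p for p in cohort.patients}
    spectra, rows = {}, []
    for pid, u in uniform.items():
        spec = coh.autocorrelation_spectrum(u)
        metric = coh.coherence_metric(spec, config.lag_min_s, config.lag_max_s)
        crossing = coh.first_zero_crossing(spec)
        spectra[pid] = spec
        rows.append({"patient_id": pid, "dose_mcg": by_id[pid].dose_mcg,
                     "latent_class": by_id[pid].latent_class,
                     "start_s": u.start_s, "metric": metric.value,
                     "first_crossing_s": crossing.lag_s,
                     "crossing_found": crossing.found})
    state["spectra"] = spectra
    state["metrics"] = pd.DataFrame(rows)


def _ensure_spectra(config, out, state):
    if "spectra" not in state or "metrics" not in state:
        _compute_spectra(config, out, state)
    return state["spectra"], state["metrics"]


def _run_stage(stage, config, out, state, summary, stamp):
    if stage == "simulate":
        cohort_cfg = replace(config.cohort, seed=config.child_seed("cohort"))
        cohort = sd.generate_cohort(cohort_cfg)
        sd.write_cohort(cohort, out / "cohort")
        state["cohort"] = cohort
        summary["n_patients"] = len(cohort)
        dose = cohort.manifest_frame()["dose_mcg"]
        summary["dose_mean_mcg"] = float(dose.mean())
        summary["dose_sd_mcg"] = float(dose.std(ddof=1))
        return

    if stage == "preprocess":
        uniform = _ensure_uniform(config, out, state)
        cohort = state["cohort"]
        summary["preprocess_excluded"] = sorted(
            {p.patient_id for p in cohort.patients} - set(uniform))
        if config.write_resampled:
            for pid, u in uniform.items():
                _write_csv(pd.DataFrame({"time_s": u.times_s, "as_value": u.values}),
                           out / "resampled" / f"{pid}.csv", stamp)
        return

    if stage == "coherence":
        _, metrics = _ensure_spectra(config, out, state)
        _write_csv(metrics, out / "metrics.csv", stamp)
        return

    if stage == "evaluate":
        _, metrics = _ensure_spectra(config, out, state)
        cohort = state["cohort"]
        cov_by_id = {p.patient_id: p.covariates for p in cohort.patients}
        records = [ev.PatientRecord(patient_id=r.patient_id, dose_mcg=r.dose_mcg,
                                    metric=r.metric,
                                    covariates=cov_by_id.get(r.patient_id, {}))
                   for r in metrics.itertuples()]
        labels = ev.label_by_dose(records, config.dose_threshold_mcg)
        scores = np.array([r.metric for r in records])
        roc = ev.roc_curve(scores, labels, config.dose_threshold_mcg)
        _write_csv(pd.DataFrame({"cutoff": roc.thresholds, "fpr": roc.fpr,
                                 "tpr": roc.tpr}),
                   out / "roc.csv", stamp)
        sweep = ev.dose_threshold_sweep(records, config.sweep_thresholds)
        _write_csv(sweep.to_frame(), out / "dose_sweep.csv", stamp)
        if any(r.covariates for r in records):
            corr = ev.baseline_correlations([r for r in records if r.covariates])
            _write_csv(corr, out / "correlations.csv", stamp)
        summary["discrete"] = {
            "dose_threshold_mcg": config.dose_threshold_mcg,
            "auc": roc.auc, "youden_j": roc.youden_j,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
            "best_auc_threshold_mcg": sweep.best_auc_threshold_mcg,
            "best_youden_threshold_mcg": sweep.best_youden_threshold_mcg,
        }
        if "latent_class" in metrics and metrics["latent_class"].nunique() == 2:
            latent = (metrics["latent_class"] == "severe").astype(int).to_numpy()
            summary["discrete"]["latent_class_auc"] = ev.rank_auc(
                metrics["metric"].to_numpy(), latent)
        return

    if stage == "nn":
        spectra, metrics = _ensure_spectra(config, out, state)
        ordered = [spectra[pid] for pid in metrics["patient_id"]]
        X, _ = nn.prepare_inputs(ordered, config.nn_feature_len)
        targets = (metrics["dose_mcg"].to_numpy() > config.nn_dose_threshold_mcg).astype(int)
        cfg = nn.MlpConfig(input_dim=X.shape[1], hidden_layers=tuple(config.nn_nodes),
                           learning_rate=config.nn_learning_rate,
                           max_epochs=config.nn_max_epochs,
                           patience_epochs=config.nn_patience,
                           n_runs=config.nn_runs, seed=config.child_seed("nn"))
        ens = nn.run_ensemble(X, targets, cfg)
        conv = nn.check_run_convergence(ens)
        _write_csv(pd.DataFrame({
            "run": np.arange(len(ens.runs)),
            "test_error": [r.test_error for r in ens.runs],
            "test_auc": [r.test_auc for r in ens.runs],
            "epochs": [r.epochs_trained for r in ens.runs]}),
            out / "nn_runs.csv", stamp)
        summary["nn"] = {
            "dose_threshold_mcg": config.nn_dose_threshold_mcg,
            "nodes": list(config.nn_nodes), "n_runs": config.nn_runs,
            "mean_error": ens.mean_error, "error_sd": ens.error_sd,
            "error_range": list(ens.error_range), "mean_auc": ens.mean_auc,
            "pooled_auc": ens.pooled_auc, "converged": bool(conv.converged),
        }
        return

    raise ValueError(f"unknown stage {stage!r}")
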