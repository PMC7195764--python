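"""From-scratch feed-forward network and its training/evaluation protocol.

The classifier is a fully connected multilayer perceptron with
log-sigmoid activation on every layer including the single output node,
trained by full-batch gradient descent (batch size = sample size) on
mean-squared error against 0/1 targets.  Because individual gradient
searches can end in local minima, performance is always reported over
an ensemble of training runs with randomized weight initialization and
random 0.7/0.15/0.15 train/validation/test splits; each run stops when
the validation MSE has not improved for a patience of epochs and the
best-validation parameters are restored.  Per-run outputs are the test
mean absolute classification error (continuous in [0, 1]) and the test
AUC using the continuous network output as the score.

Input features are autocorrelation spectra block-averaged into
equal-width lag bins and standardized per feature over the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DegenerateCohortError
from .evaluation import rank_auc

__all__ = [
    "MlpConfig",
    "MlpModel",
    "FeatureTransform",
    "RunResult",
    "RunEnsemble",
    "ConvergenceCheck",
    "SweepSurface",
    "prepare_inputs",
    "init_model",
    "forward",
    "mse_loss",
    "train_step",
    "train_run",
    "run_ensemble",
    "check_run_convergence",
    "architecture_sweep",
]


@dataclass(frozen=True)
class MlpConfig:
    input_dim: int
    hidden_layers: tuple[int, ...] = (12,)
    learning_rate: float = 0.01
    max_epochs: int = 1000
    patience_epochs: int = 6
    split_ratios: tuple[float, float, float] = (0.7, 0.15, 0.15)
    n_runs: int = 500
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "hidden_layers", tuple(int(h) for h in self.hidden_layers))
        if self.input_dim < 1 or any(h < 1 for h in self.hidden_layers):
            raise ValueError("input_dim and all hidden node counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9 or any(r <= 0 for r in self.split_ratios):
            raise ValueError("split_ratios must be positive and sum to 1")
        if self.max_epochs < 1 or self.patience_epochs < 1 or self.n_runs < 1:
            raise ValueError("max_epochs, patience_epochs and n_runs must be >= 1")


@dataclass
class MlpModel:
    """Per-layer weights (fan_in x fan_out) and biases; last layer has 1 output."""

    weights: list
    biases: list

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    def copy(self) -> "MlpModel":
        return MlpModel([w.copy() for w in self.weights], [b.copy() for b in self.biases])


@dataclass(frozen=True)
class FeatureTransform:
    """Block-average binning + per-feature standardization parameters."""

    spectrum_len: int
    feature_len: int
    mean: np.ndarray
    std: np.ndarray

    def apply(self, coeff_matrix) -> np.ndarray:
        binned = _block_average(np.atleast_2d(np.asarray(coeff_matrix, dtype=float)),
                                self.feature_len)
        return (binned - self.mean) / self.std


def _block_average(mat: np.ndarray, feature_len: int) -> np.ndarray:
    n = mat.shape[1]
    edges = (np.arange(feature_len + 1) * n) // feature_len
    sums = np.add.reduceat(mat, edges[:-1], axis=1)
    return sums / np.diff(edges)


def prepare_inputs(spectra, feature_len: int = 400):
    """Feature matrix from autocorrelation spectra.

    Each spectrum is averaged into ``feature_len`` equal-width lag bins,
    then each feature column is standardized to zero mean and unit
    variance over the cohort.  Returns ``(X, FeatureTransform)``.
    """
    coeffs = [np.asarray(s.coeffs if hasattr(s, "coeffs") else s, dtype=float)
              for s in spectra]
    lengths = {c.size for c in coeffs}
    if len(lengths) != 1:
        raise ValueError(f"all spectra must have the same length; got {sorted(lengths)}")
    (n,) = lengths
    if not 1 <= feature_len <= n:
        raise ValueError("feature_len must lie in [1, spectrum length]")
    binned = _block_average(np.vstack(coeffs), feature_len)
    mean = binned.mean(axis=0)
    std = binned.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    transform = FeatureTransform(spectrum_len=n, feature_len=feature_len,
                                 mean=mean, std=std)
    return (binned - mean) / std, transform


def init_model(config: MlpConfig, rng) -> MlpModel:
    """Weights uniform on (-1/sqrt(fan_in), +1/sqrt(fan_in)); zero biases."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dims = (config.input_dim, *config.hidden_layers, 1)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MlpModel(weights, biases)


def _forward_all(model: MlpModel, X: np.ndarray) -> list:
    activations = [X]
    a = X
    for w, b in zip(model.weights, model.biases):
        a = expit(a @ w + b)
        activations.append(a)
    return activations


def forward(model: MlpModel, features) -> np.ndarray:
    """Network outputs in (0, 1), one per input row."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if X.shape[1] != model.weights[0].shape[0]:
        raise ValueError(f"feature dim {X.shape[1]} != model input dim "
                         f"{model.weights[0].shape[0]}")
    return _forward_all(model, X)[-1].ravel()


def mse_loss(model: MlpModel, features, targets) -> float:
    out = forward(model, features)
    t = np.asarray(targets, dtype=float).ravel()
    return float(np.mean((out - t) ** 2))


def train_step(model: MlpModel, features, targets, learning_rate: float):
    """One full-batch gradient-descent step on MSE; returns (model, pre-update loss)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.asarray(targets, dtype=float).reshape(-1, 1)
    acts = _forward_all(model, X)
    out = acts[-1]
    n = X.shape[0]
    loss = float(np.mean((out - t) ** 2))

    delta = (2.0 / n) * (out - t) * out * (1.0 - out)
    grads_w, grads_b = [], []
    for layer in range(len(model.weights) - 1, -1, -1):
        grads_w.append(acts[layer].T @ delta)
        grads_b.append(delta.sum(axis=0))
        if layer > 0:
            a_prev = acts[layer]
            delta = (delta @ model.weights[layer].T) * a_prev * (1.0 - a_prev)
    grads_w.reverse()
    grads_b.reverse()
    for w, b, gw, gb in zip(model.weights, model.biases, grads_w, grads_b):
        w -= learning_rate * gw
        b -= learning_rate * gb
    return model, loss


@dataclass(frozen=True)
class RunResult:
    test_error: float
    test_auc: float
    epochs_trained: int
    n_train: int
    n_val: int
    n_test: int
    degenerate_auc: bool
    test_scores: np.ndarray = None
    test_labels: np.ndarray = None


def _split_sizes(n: int, ratios) -> tuple[int, int, int]:
    # test and validation floored; remainder goes to training (45 -> 33/6/6)
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    return n - n_val - n_test, n_val, n_test


def train_run(features, targets, config: MlpConfig, rng) -> RunResult:
    """One training run: random split, early stopping, best-weight restore."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = X.shape[0]
    n_train, n_val, n_test = _split_sizes(n, config.split_ratios)
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("each split needs at least 1 sample")

    for _ in range(100):
        perm = rng.permutation(n)
        tr, va, te = perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]
        if y[tr].min() != y[tr].max():
            break
    else:
        raise DegenerateCohortError(
            "could not draw a training split containing both classes")

    model = init_model(config, rng)
    best = model.copy()
    best_val = np.inf
    stale = 0
    epochs = 0
    for epoch in range(config.max_epochs):
        model, _ = train_step(model, X[tr], y[tr], config.learning_rate)
        epochs = epoch + 1
        val = mse_loss(model, X[va], y[va])
        if val < best_val - 1e-12:
            best_val = val
            best = model.copy()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience_epochs:
                break

    scores = forward(best, X[te])
    test_error = float(np.mean(np.abs(scores - y[te])))
    if y[te].min() == y[te].max():
        test_auc, degenerate = float("nan"), True
    else:
        test_auc, degenerate = rank_auc(scores, y[te].astype(int)), False
    return RunResult(test_error=test_error, test_auc=test_auc, epochs_trained=epochs,
                     n_train=n_train, n_val=n_val, n_test=n_test,
                     degenerate_auc=degenerate, test_scores=scores,
                     test_labels=y[te].astype(int))


@dataclass(frozen=True)
class RunEnsemble:
    runs: tuple[RunResult, ...]
    mean_error: float
    error_sd: float
    error_range: tuple[float, float]
    mean_auc: float
    pooled_auc: float
    n_degenerate_auc: int

    def errors(self) -> np.ndarray:
        return np.array([r.test_error for r in self.runs])


def run_ensemble(features, targets, config: MlpConfig) -> RunEnsemble:
    """``config.n_runs`` independent training runs plus aggregates.

    ``mean_auc`` averages per-run test AUCs (degenerate single-class
    test sets excluded); ``pooled_auc`` ranks the concatenated test-set
    scores of all runs against their labels.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    runs = [train_run(X, y, config, np.random.default_rng(child)) for child in children]

    errors = np.array([r.test_error for r in runs])
    aucs = np.array([r.test_auc for r in runs])
    valid = ~np.isnan(aucs)
    mean_auc = float(aucs[valid].mean()) if valid.any() else float("nan")
    pooled_scores = np.concatenate([r.test_scores for r in runs])
    pooled_labels = np.concatenate([r.test_labels for r in runs])
    if pooled_labels.min() != pooled_labels.max():
        pooled_auc = rank_auc(pooled_scores, pooled_labels)
    else:
        pooled_auc = float("nan")
    return RunEnsemble(runs=tuple(runs), mean_error=float(errors.mean()),
                       error_sd=float(errors.std(ddof=1)) if len(runs) > 1 else 0.0,
                       error_range=(float(errors.min()), float(errors.max())),
                       mean_auc=mean_auc, pooled_auc=pooled_auc,
                       n_degenerate_auc=int((~valid).sum()))


@dataclass(frozen=True)
class ConvergenceCheck:
    converged: bool
    error_sd: float
    error_range: float
    threshold: float


def check_run_convergence(ensemble: RunEnsemble, tolerance_factor: float = 1.5) -> ConvergenceCheck:
    """Run-count convergence rule: SD of errors <= 0.1 x error range (with slack).

    The protocol extends the number of runs until the SD of per-run
    errors is about one tenth of the observed error range; the
    tolerance factor absorbs the "approximately".
    """
    errors = ensemble.errors()
    if errors.size < 2:
        raise ValueError("convergence check needs at least 2 runs")
    if errors.size == 2:
        warnings.warn("convergence check on only 2 runs is unreliable")
    sd = float(errors.std(ddof=1))
    rng_ = float(errors.max() - errors.min())
    threshold = 0.1 * rng_ * tolerance_factor
    return ConvergenceCheck(converged=sd <= threshold + 1e-12, error_sd=sd,
                            error_range=rng_, threshold=threshold)


@dataclass(frozen=True)
class SweepSurface:
    """Mean error / mean AUC over (depth, nodes, dose threshold) cells.

    ``diff_error`` / ``diff_auc`` subtract each deeper network's surface
    from the single-layer surface (single minus deeper): a negative
    error difference or positive AUC difference means the deeper
    network performs worse.
    """

    node_grid: tuple[int, ...]
    depth_grid: tuple[int, ...]
    thresholds: tuple[float, ...]
    mean_error: np.ndarray  # shape (depth, nodes, thresholds)
    mean_auc: np.ndarray
    failed: np.ndarray  # bool mask of failed cells

    def diff_vs_single_layer(self, depth: int):
        if 1 not in self.depth_grid:
            raise ValueError("difference surfaces need depth 1 in the grid")
        i1 = self.depth_grid.index(1)
        i = self.depth_grid.index(depth)
        return (self.mean_error[i1] - self.mean_error[i],
                self.mean_auc[i1] - self.mean_auc[i])


def architecture_sweep(features_by_threshold: dict, node_grid, depth_grid,
                       config: MlpConfig) -> SweepSurface:
    """Run an ensemble per (depth, nodes, dose threshold) cell.

    ``features_by_threshold`` maps dose threshold -> (features, targets).
    Cell failures are recorded, not fatal.
    """
    node_grid = tuple(int(v) for v in node_grid)
    depth_grid = tuple(int(v) for v in depth_grid)
    thresholds = tuple(features_by_threshold)
    if not node_grid or not depth_grid or not thresholds:
        raise ValueError("node grid, depth grid and thresholds must be nonempty")
    shape = (len(depth_grid), len(node_grid), len(thresholds))
    mean_error = np.full(shape, np.nan)
    mean_auc = np.full(shape, np.nan)
    failed = np.zeros(shape, dtype=bool)
    for (di, depth), (ni, nodes), (ti, thr) in _grid_iter(depth_grid, node_grid, thresholds):
        X, y = features_by_threshold[thr]
        cell_seed = np.random.SeedSequence((config.seed, di, ni, ti))
        cell_cfg = MlpConfig(input_dim=np.atleast_2d(X).shape[1],
                             hidden_layers=(nodes,) * depth,
                             learning_rate=config.learning_rate,
                             max_epochs=config.max_epochs,
                             patience_epochs=config.patience_epochs,
                             split_ratios=config.split_ratios,
                             n_runs=config.n_runs,
                             seed=cell_seed.generate_state(1)[0] % (2**31))
        try:
            ens = run_ensemble(X, y, cell_cfg)
        except Exception as exc:  # cell-level failure, surface stays partial
            warnings.warn(f"sweep cell (depth={depth}, nodes={nodes}, thr={thr}) "
                          f"failed: {exc}")
            failed[di, ni, ti] = True
            continue
        mean_error[di, ni, ti] = ens.mean_error
        mean_auc[di, ni, ti] = ens.mean_auc
    return SweepSurface(node_grid=node_grid, depth_grid=depth_grid,
                        thresholds=thresholds, mean_error=mean_error,
                        mean_auc=mean_auc, failed=failed)


def _grid_iter(depth_grid, node_grid, thresholds):
    for di, depth in enumerate(depth_grid):
        for ni, nodes in enumerate(node_grid):
            for ti, thr in enumerate(thresholds):
                yield (di, depth), (ni, nodes), (ti, thr)
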