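"""Cross-validated prediction of memory scores from edge features.

Implements the framework around the regression engine: per-fold min-max
scaling learned on the training subjects only, leave-one-out and repeated
k-fold cross-validation, accuracy metrics (Pearson r, covariate-adjusted
partial r, MAE), and permutation significance obtained by re-running the
entire cross-validation on label-shuffled cohorts.

Covariate adjustment applies to *evaluation* only (the partial correlation
between actual and predicted scores); training targets are never
residualized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import rvr as _rvr
from ._core import rvr_fit_predict_batch
from .connectome import DegenerateInputError

__all__ = [
    "ScalingParams",
    "CVResult",
    "PermutationResult",
    "composite_memory",
    "composite_memory_two",
    "fit_scaling",
    "apply_scaling",
    "loocv_predict",
    "repeated_kfold_predict",
    "partial_correlation",
    "permutation_test",
    "format_p",
]


# ---------------------------------------------------------------- scores

def composite_memory(avlt_dr, lmt_dr, cft_dr):
    """Composite episodic memory: mean of the three delayed-recall scores."""
    a = np.asarray(avlt_dr, dtype=float)
    l = np.asarray(lmt_dr, dtype=float)
    c = np.asarray(cft_dr, dtype=float)
    stacked = np.stack(np.broadcast_arrays(a, l, c))
    bad = ~np.all(np.isfinite(stacked), axis=0)
    if np.any(bad):
        which = np.flatnonzero(np.atleast_1d(bad))
        raise ValueError(
            f"missing/non-finite delayed-recall score for subject(s) {which.tolist()}"
        )
    out = stacked.mean(axis=0)
    return float(out) if out.ndim == 0 else out


def composite_memory_two(lmt_dr, cft_dr):
    """Two-test composite (LMT-DR and CFT-DR only), used to check that the
    result does not hinge on the score being predicted also entering the
    composite."""
    l = np.asarray(lmt_dr, dtype=float)
    c = np.asarray(cft_dr, dtype=float)
    stacked = np.stack(np.broadcast_arrays(l, c))
    bad = ~np.all(np.isfinite(stacked), axis=0)
    if np.any(bad):
        which = np.flatnonzero(np.atleast_1d(bad))
        raise ValueError(
            f"missing/non-finite delayed-recall score for subject(s) {which.tolist()}"
        )
    out = stacked.mean(axis=0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------- scaling

@dataclass
class ScalingParams:
    """Per-feature training minimum/maximum for 0-1 scaling."""

    minimum: np.ndarray
    maximum: np.ndarray


def fit_scaling(train_features: np.ndarray) -> ScalingParams:
    X = np.atleast_2d(np.asarray(train_features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to derive scaling")
    return ScalingParams(minimum=X.min(axis=0), maximum=X.max(axis=0))


def apply_scaling(params: ScalingParams, features: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min) with training-derived parameters.

    Training columns land in [0, 1]; test values may fall outside and are
    deliberately not clipped.  A constant training feature maps to 0
    everywhere (train and test alike).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    denom = params.maximum - params.minimum
    safe = np.where(denom > 0, denom, 1.0)
    out = (X - params.minimum) / safe
    out[:, denom == 0] = 0.0
    return out


# ---------------------------------------------------------------- metrics

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 by convention when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _mae(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(np.abs(np.asarray(a) - np.asarray(b))))


def partial_correlation(actual, predicted, covariates=None) -> float:
    """Pearson correlation of residuals after regressing out covariates.

    Both vectors are regressed on [1, covariates]; with no covariates this
    is the plain Pearson correlation.  Collinear covariates trigger a
    warning and a pseudoinverse solution.
    """
    x = np.asarray(actual, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("actual and predicted must have the same length")
    if covariates is None or np.size(covariates) == 0:
        return _pearson(x, y)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != x.shape[0]:
        C = C.T
    if C.shape[0] != x.shape[0]:
        raise ValueError("covariates must have one row per subject")
    n, k = C.shape
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 subjects (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "collinear covariates; using pseudoinverse", RuntimeWarning, stacklevel=2
        )
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    # a vector fully explained by the covariates has no residual signal:
    # its partial correlation is 0, not numerical noise
    if rx.std() <= 1e-10 * max(x.std(), 1.0) or ry.std() <= 1e-10 * max(y.std(), 1.0):
        return 0.0
    return _pearson(rx, ry)


# ---------------------------------------------------------------- results

@dataclass
class CVResult:
    """Out-of-sample predictions and accuracy for one CV scheme."""

    predictions: np.ndarray
    actual: np.ndarray
    r: float
    mae: float
    scheme: str
    partial_r: float | None = None
    fold_assignment: np.ndarray | None = None
    per_repeat_r: np.ndarray | None = None
    per_repeat_mae: np.ndarray | None = None
    models: list | None = None
    scalings: list | None = None
    n_nonconverged: int = 0

    def to_dict(self) -> dict:
        d = {
            "scheme": self.scheme,
            "r": self.r,
            "mae": self.mae,
            "partial_r": self.partial_r,
            "n_nonconverged": self.n_nonconverged,
            "predictions": np.asarray(self.predictions).tolist(),
            "actual": np.asarray(self.actual).tolist(),
        }
        if self.per_repeat_r is not None:
            d["per_repeat_r"] = np.asarray(self.per_repeat_r).tolist()
            d["per_repeat_mae"] = np.asarray(self.per_repeat_mae).tolist()
        return d


@dataclass
class PermutationResult:
    """Null distributions of r and MAE from label permutations."""

    n_permutations: int
    null_r: np.ndarray
    null_mae: np.ndarray
    p_r: float
    p_mae: float
    observed_r: float
    observed_mae: float
    seed: int
    scheme: str
    strict: bool = False

    @property
    def p_r_label(self) -> str:
        return format_p(self.p_r, self.n_permutations)

    @property
    def p_mae_label(self) -> str:
        return format_p(self.p_mae, self.n_permutations)

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "p_r": self.p_r,
            "p_r_label": self.p_r_label,
            "p_mae": self.p_mae,
            "p_mae_label": self.p_mae_label,
            "observed_r": self.observed_r,
            "observed_mae": self.observed_mae,
            "seed": self.seed,
            "scheme": self.scheme,
            "strict": self.strict,
            "null_r": np.asarray(self.null_r).tolist(),
            "null_mae": np.asarray(self.null_mae).tolist(),
        }


def format_p(p: float, n_perm: int) -> str:
    """A zero permutation count is a bound, not an exact zero."""
    if p <= 0.0:
        return f"< {1.0 / n_perm:g}"
    return f"{p:g}"


# ---------------------------------------------------------------- CV internals

def _loocv_folds(n: int):
    idx = np.arange(n)
    return [(np.delete(idx, i), np.array([i])) for i in range(n)]


def _kfold_folds(n: int, k: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return [(np.setdiff1d(np.arange(n), te), np.sort(te)) for te in np.array_split(perm, k)]


class _FoldCache:
    """Scaled design matrices for one train/test split (target-independent)."""

    __slots__ = ("train_idx", "test_idx", "scaling", "X_train", "X_test", "Phi_tr", "Phi_te")

    def __init__(self, X: np.ndarray, train_idx: np.ndarray, test_idx: np.ndarray):
        self.train_idx = train_idx
        self.test_idx = test_idx
        self.scaling = fit_scaling(X[train_idx])
        self.X_train = apply_scaling(self.scaling, X[train_idx])
        self.X_test = apply_scaling(self.scaling, X[test_idx])
        K = self.X_train @ self.X_train.T
        self.Phi_tr = np.ascontiguousarray(
            np.column_stack([np.ones(len(train_idx)), K])
        )
        self.Phi_te = np.ascontiguousarray(
            np.column_stack([np.ones(len(test_idx)), self.X_test @ self.X_train.T])
        )


def _check_batchable(config: _rvr.RVRFitConfig) -> None:
    if (
        config.center_kernel
        or not config.update_hyperparameters
        or config.compute_evidence
        or config.init_noise_variance is not None
    ):
        raise ValueError(
            "the batched CV path supports only the standard fit configuration "
            "(no kernel centring, hyperparameter updates on, no evidence log, "
            "target-derived initial noise variance)"
        )


def _predict_matrix(caches, Y: np.ndarray, config: _rvr.RVRFitConfig):
    """Predictions for every target column of ``Y`` under cached folds."""
    _check_batchable(config)
    n, P = Y.shape
    preds = np.empty((n, P))
    nonconv = 0
    for cache in caches:
        Ytr = np.ascontiguousarray(Y[cache.train_idx])
        pr, cv = rvr_fit_predict_batch(
            cache.Phi_tr, cache.Phi_te, Ytr,
            config.init_alpha, 0.1, config.bias_unpenalized,
            config.max_iterations, config.convergence_tol,
            config.alpha_prune_threshold, config.sigma2_floor,
        )
        preds[cache.test_idx] = pr
        nonconv += int((~cv).sum())
    return preds, nonconv


def _run_cv(X, y, folds, config, collect_models):
    """One full CV pass with per-fold models (slow, model-retaining path)."""
    n = len(y)
    preds = np.empty(n)
    models, scalings = [], []
    nonconv = 0
    for train_idx, test_idx in folds:
        scaling = fit_scaling(X[train_idx])
        Xtr = apply_scaling(scaling, X[train_idx])
        Xte = apply_scaling(scaling, X[test_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = _rvr.fit(Xtr, y[train_idx], config)
        if not model.converged:
            nonconv += 1
        preds[test_idx] = _rvr.predict(model, Xte)
        if collect_models:
            models.append(model)
            scalings.append(scaling)
    return preds, models, scalings, nonconv


# ---------------------------------------------------------------- public CV

def loocv_predict(
    features,
    targets,
    rvr_config: _rvr.RVRFitConfig | None = None,
    covariates=None,
    return_models: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation: n folds, each subject predicted by a
    model trained (and scaled) on the other n-1 subjects."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and targets disagree on sample count")
    if n < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    if n < 10:
        warnings.warn(f"only {n} subjects; CV metrics will be unstable", RuntimeWarning)
    config = rvr_config or _rvr.RVRFitConfig()
    preds, models, scalings, nonconv = _run_cv(
        X, y, _loocv_folds(n), config, return_models
    )
    partial_r = (
        partial_correlation(y, preds, covariates) if covariates is not None else None
    )
    return CVResult(
        predictions=preds,
        actual=y,
        r=_pearson(y, preds),
        mae=_mae(y, preds),
        partial_r=partial_r,
        scheme="loocv",
        fold_assignment=np.arange(n),
        models=models if return_models else None,
        scalings=scalings if return_models else None,
        n_nonconverged=nonconv,
    )


def repeated_kfold_predict(
    features,
    targets,
    k: int = 10,
    repeats: int = 100,
    seed: int | None = None,
    rvr_config: _rvr.RVRFitConfig | None = None,
    covariates=None,
    pooled: bool = False,
) -> CVResult:
    """Repeated k-fold CV with per-repeat metrics averaged across repeats.

    Each repeat partitions the cohort at random (fold sizes differ by at
    most one), predicts every subject once, and yields one r and one MAE;
    the reported accuracy is the mean over repeats.  ``pooled=True``
    instead computes the metrics on the per-subject predictions averaged
    across repeats.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be at least 2")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if seed is None:
        raise ValueError("seed is required for repeated k-fold")
    config = rvr_config or _rvr.RVRFitConfig()
    rng = np.random.default_rng(seed)
    all_preds = np.empty((repeats, n))
    rs = np.empty(repeats)
    maes = np.empty(repeats)
    assignments = np.empty((repeats, n), dtype=int)
    nonconv = 0
    for rep in range(repeats):
        folds = _kfold_folds(n, k, rng)
        for f, (_, te) in enumerate(folds):
            assignments[rep, te] = f
        preds, _, _, nc = _run_cv(X, y, folds, config, False)
        nonconv += nc
        all_preds[rep] = preds
        rs[rep] = _pearson(y, preds)
        maes[rep] = _mae(y, preds)
    mean_preds = all_preds.mean(axis=0)
    if pooled:
        r, mae = _pearson(y, mean_preds), _mae(y, mean_preds)
    else:
        r, mae = float(rs.mean()), float(maes.mean())
    partial_r = (
        partial_correlation(y, mean_preds, covariates)
        if covariates is not None
        else None
    )
    return CVResult(
        predictions=mean_preds,
        actual=y,
        r=r,
        mae=mae,
        partial_r=partial_r,
        scheme=f"kfold(k={k}, repeats={repeats}, seed={seed})",
        fold_assignment=assignments,
        per_repeat_r=rs,
        per_repeat_mae=maes,
        n_nonconverged=nonconv,
    )


# ---------------------------------------------------------------- permutation

def permutation_test(
    features,
    targets,
    covariates=None,
    scheme: str = "loocv",
    n_perm: int = 1000,
    seed: int | None = None,
    rvr_config: _rvr.RVRFitConfig | None = None,
    k: int = 10,
    repeats: int = 1,
    strict: bool = False,
) -> PermutationResult:
    """Significance of CV accuracy by whole-cohort label permutation.

    Each of ``n_perm`` repetitions shuffles the target vector across the
    cohort (without replacement), re-runs the full cross-validation, and
    records the null r and MAE.  P-values count null metrics at least as
    good as the observed one: p_r = #(r_null >= r_obs)/n_perm and
    p_mae = #(MAE_null <= MAE_obs)/n_perm; with ``strict=True`` ties do
    not count against the observed value.  A zero count is reported as a
    bound (< 1/n_perm) by ``format_p``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and targets disagree on sample count")
    if y.std() == 0:
        raise DegenerateInputError(
            "targets are constant; correlation-based significance is undefined"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    config = rvr_config or _rvr.RVRFitConfig()
    rng = np.random.default_rng(seed)

    # column 0 = observed labels, columns 1.. = permuted labels
    Y = np.empty((n, n_perm + 1))
    Y[:, 0] = y
    for p in range(n_perm):
        Y[:, p + 1] = y[rng.permutation(n)]

    if scheme == "loocv":
        fold_sets = [_loocv_folds(n)]
    elif scheme == "kfold":
        fold_rng = np.random.default_rng(rng.integers(2**31))
        fold_sets = [_kfold_folds(n, k, fold_rng) for _ in range(repeats)]
    else:
        raise ValueError("scheme must be 'loocv' or 'kfold'")

    P = n_perm + 1
    r_sum = np.zeros(P)
    mae_sum = np.zeros(P)
    for folds in fold_sets:
        caches = [_FoldCache(X, tr, te) for tr, te in folds]
        preds, _ = _predict_matrix(caches, Y, config)
        for p in range(P):
            r_sum[p] += _pearson(Y[:, p], preds[:, p])
            mae_sum[p] += _mae(Y[:, p], preds[:, p])
    r_all = r_sum / len(fold_sets)
    mae_all = mae_sum / len(fold_sets)

    obs_r, obs_mae = float(r_all[0]), float(mae_all[0])
    null_r, null_mae = r_all[1:], mae_all[1:]
    if strict:
        p_r = float(np.mean(null_r > obs_r))
        p_mae = float(np.mean(null_mae < obs_mae))
    else:
        p_r = float(np.mean(null_r >= obs_r))
        p_mae = float(np.mean(null_mae <= obs_mae))
    return PermutationResult(
        n_permutations=n_perm,
        null_r=null_r,
        null_mae=null_mae,
        p_r=p_r,
        p_mae=p_mae,
        observed_r=obs_r,
        observed_mae=obs_mae,
        seed=seed,
        scheme=scheme,
        strict=strict,
    )
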