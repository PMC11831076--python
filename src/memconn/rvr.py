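"""Relevance vector regression (sparse Bayesian linear-kernel regression).

The model places an independent zero-mean Gaussian prior N(0, 1/alpha_i)
on the weight of every training sample's kernel column (plus a bias) and
maximizes the marginal likelihood (type-II ML) over the per-sample
precisions alpha and the noise variance sigma^2.  Most alphas diverge, so
most weights are pruned to exactly zero; the surviving samples are the
"relevance vectors".  With a linear kernel the dual weights fold back into
per-feature primal regression coefficients, which is what makes the edge
weights interpretable downstream.

The kernel is fixed to the linear inner product on caller-scaled features.
Fitting is deterministic given the inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._core import rvr_fit_core

__all__ = ["RVRFitConfig", "RVRModel", "linear_kernel", "fit", "predict", "primal_weights"]


@dataclass
class RVRFitConfig:
    """Hyperparameters of the evidence-maximization loop.

    ``init_noise_variance=None`` means 0.1 x the target variance.  The
    bias is an unpenalized column by default; setting
    ``bias_unpenalized=False`` gives it an ordinary updatable alpha (the
    variant under which the marginal likelihood is a proper quantity).
    ``update_hyperparameters=False`` freezes alpha and sigma^2 at their
    initial values, which makes the posterior mean the closed-form kernel
    ridge solution with ridge sigma^2 * alpha.
    """

    max_iterations: int = 1000
    alpha_prune_threshold: float = 1e9
    convergence_tol: float = 1e-6
    init_alpha: float = 1.0
    init_noise_variance: float | None = None
    bias_unpenalized: bool = True
    update_hyperparameters: bool = True
    center_kernel: bool = False
    compute_evidence: bool = False
    sigma2_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        for name in ("alpha_prune_threshold", "convergence_tol", "init_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.init_noise_variance is not None and self.init_noise_variance <= 0:
            raise ValueError("init_noise_variance must be positive")


@dataclass
class RVRModel:
    """A fitted model: relevance vectors, posterior weights, hyperparameters."""

    X_train: np.ndarray
    mu_full: np.ndarray          # length n_train + 1; index 0 is the bias
    active: np.ndarray           # boolean, same length as mu_full
    alpha: np.ndarray
    noise_variance: float
    n_iterations: int
    converged: bool
    config: RVRFitConfig
    kernel: str = "linear"
    evidence_log: np.ndarray = field(default_factory=lambda: np.empty(0))
    _kernel_col_means: np.ndarray | None = None
    _kernel_grand_mean: float = 0.0

    @property
    def bias(self) -> float:
        return float(self.mu_full[0])

    @property
    def relevance_set(self) -> np.ndarray:
        """Indices of retained training samples (bias excluded)."""
        return np.flatnonzero(self.active[1:])

    @property
    def relevance_vectors(self) -> np.ndarray:
        return self.X_train[self.relevance_set]

    @property
    def mu(self) -> np.ndarray:
        """Posterior mean weights of the retained samples."""
        return self.mu_full[1:][self.active[1:]]

    @property
    def n_features(self) -> int:
        return self.X_train.shape[1]

    def to_json(self, path=None) -> str:
        payload = {
            "kernel": self.kernel,
            "bias": self.bias,
            "relevance_set": self.relevance_set.tolist(),
            "mu": self.mu.tolist(),
            "alpha": [None if not np.isfinite(a) else a for a in self.alpha.tolist()],
            "noise_variance": self.noise_variance,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "config": asdict(self.config),
            "relevance_vectors": self.relevance_vectors.tolist(),
            "n_features": self.n_features,
            "evidence_log": self.evidence_log.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def linear_kernel(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Inner-product (linear) kernel K = X Y'; symmetric PSD when Y is X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature dimensions disagree: {X.shape[1]} vs {Y.shape[1]}"
        )
    return X @ Y.T


def _design(model_or_X, K: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(K.shape[0]), K])


def fit(features: np.ndarray, targets: np.ndarray, config: RVRFitConfig | None = None) -> RVRModel:
    """Train RVR on caller-scaled features by evidence maximization.

    Non-convergence within ``max_iterations`` is flagged on the returned
    model (with a warning), never silently dropped.
    """
    if config is None:
        config = RVRFitConfig()
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(features, dtype=float)))
    y = np.ascontiguousarray(np.asarray(targets, dtype=float).ravel())
    n = X.shape[0]
    if n != y.shape[0]:
        raise ValueError("features and targets disagree on sample count")
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("features and targets must be finite")

    K = linear_kernel(X)
    col_means = None
    grand = 0.0
    if config.center_kernel:
        col_means = K.mean(axis=0)
        grand = float(K.mean())
        K = K - col_means[None, :] - col_means[:, None] + grand
    Phi = np.ascontiguousarray(_design(X, K))

    s2 = config.init_noise_variance
    if s2 is None:
        s2 = max(0.1 * float(np.var(y)), config.sigma2_floor)
    mu_full, active, alpha, sigma2, n_iter, converged, evidence = rvr_fit_core(
        np.ascontiguousarray(Phi.T @ Phi),
        np.ascontiguousarray(Phi.T @ y),
        Phi,
        y,
        float(config.init_alpha),
        float(s2),
        bool(config.bias_unpenalized),
        bool(config.update_hyperparameters),
        int(config.max_iterations),
        float(config.convergence_tol),
        float(config.alpha_prune_threshold),
        float(config.sigma2_floor),
        bool(config.compute_evidence),
        1e-8,
    )
    if not converged:
        warnings.warn(
            f"RVR hyperparameters did not converge (stopped after {int(n_iter)} "
            f"iterations; cap {config.max_iterations}); posterior is still valid",
            RuntimeWarning,
            stacklevel=2,
        )
    return RVRModel(
        X_train=X,
        mu_full=mu_full,
        active=active,
        alpha=alpha,
        noise_variance=float(sigma2),
        n_iterations=int(n_iter),
        converged=bool(converged),
        config=config,
        evidence_log=np.asarray(evidence),
        _kernel_col_means=col_means,
        _kernel_grand_mean=grand,
    )


def predict(model: RVRModel, features: np.ndarray) -> np.ndarray:
    """Predict targets: y_hat = k(x, relevance vectors) . mu + bias."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    K = linear_kernel(X, model.X_train)
    if model.config.center_kernel:
        K = (
            K
            - model._kernel_col_means[None, :]
            - K.mean(axis=1, keepdims=True)
            + model._kernel_grand_mean
        )
    return K @ model.mu_full[1:] + model.bias


def primal_weights(model: RVRModel) -> np.ndarray:
    """Per-feature regression coefficients of a linear-kernel model.

    w = sum_i mu_i x_i over the relevance vectors, so the primal form
    w . x + bias reproduces the kernel-form predictions exactly.
    """
    if model.kernel != "linear":
        raise NotImplementedError("primal weights require a linear kernel")
    if model.config.center_kernel:
        raise NotImplementedError(
            "primal weights are not defined for a centred kernel"
        )
    return model.X_train.T @ model.mu_full[1:]
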