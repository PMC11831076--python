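"""Synthetic cohorts with the statistical structure the analysis assumes.

Real resting-state cohorts of this kind are rarely shareable, so every
downstream stage is exercised on generated data: per-subject Fisher-z FC
matrices (optionally realized through ROI time series), an episodic-memory
score carrying a sparse linear signal on designated edges, covariates
(age, sex, education) correlated with the score, and a null regime with no
edge signal at all.  The generating model for subject s is

    y_s = b0 + sum_e beta_e z_e(s) + sum_c gamma_c c_s + eps_s,
    eps_s ~ N(0, noise_sd^2),

where z_e are the Fisher-z connectivity values at the signal edges.  The
truth record keeps the generating coefficients so feature-selection
enrichment and parameter-recovery tests have an exact reference.

Cohorts are bit-reproducible from ``random_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import (
    CANONICAL_MODULES,
    AtlasDefinition,
    devectorize,
    edge_index,
    fisher_z,
    n_edges,
    pearson_fc,
    stack_features,
    vectorize,
)

__all__ = [
    "CovariateSpec",
    "ExtraFeature",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_atlas",
    "simulate_cohort",
    "add_nuisance",
]

# MNI-scale bounding box for centroids (mm): +-90 LR, +-110 AP, +-70 SI,
# large enough that both short- and long-range (>75 mm) edges occur.
_BOX = np.array([[-90.0, 90.0], [-110.0, 110.0], [-70.0, 70.0]])


@dataclass
class CovariateSpec:
    """Covariate distributions and their linear effects on the score.

    Defaults mirror a typical amnestic-MCI cohort: age 68.0 +- 7.3 years,
    education 11.9 +- 3.4 years, 60% male (30/20).  Effects are expressed
    per unit of the (mean-centred) covariate so the intercept keeps the
    score scale.
    """

    age_mean: float = 68.0
    age_sd: float = 7.3
    education_mean: float = 11.9
    education_sd: float = 3.4
    p_male: float = 0.6
    age_beta: float = -0.05
    education_beta: float = 0.08
    sex_beta: float = -0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_male <= 1.0):
            raise ValueError("p_male must be in [0, 1]")
        if self.age_sd < 0 or self.education_sd < 0:
            raise ValueError("covariate SDs must be non-negative")


@dataclass
class ExtraFeature:
    """An optional scalar feature (e.g. hippocampal volume, in cm^3)."""

    name: str
    mean: float
    sd: float
    score_corr: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (-1.0 <= self.score_corr <= 1.0):
            raise ValueError("score_corr must be in [-1, 1]")


@dataclass
class SimulationConfig:
    """Everything needed to generate one cohort.

    Between-subject variation of the z-FC edges follows a low-rank factor
    model — ``n_factors`` latent subject factors with decaying strengths
    plus a small i.i.d. residual (``residual_sd``) — mimicking the strong
    inter-edge correlation of real connectomes (global connectivity
    strength, arousal, residual motion), which is what keeps the effective
    dimensionality of a 4005-edge feature space low enough for prediction
    to work at n ~ 50 subjects.  Signal edges additionally carry subject
    variation of SD ``edge_sd`` that is correlated within
    ``signal_groups`` groups (within-group correlation ``signal_corr``):
    the planted connections behave as coherently co-varying subsystems,
    the way a degenerating network system does, rather than as thousands
    of independent coordinates — a sparse signal with fully independent
    edges would sit below the feature-noise floor of a 4005-edge space at
    these sample sizes for any non-sparse learner.

    ``signal_edges`` are unordered node pairs carrying the planted linear
    edge->score signal with per-edge coefficients ``edge_effect_sizes`` (a
    scalar is broadcast).  The effect-size scale is arbitrary by nature of
    the problem; the defaults place a cohort with 40 signal edges at a
    population edge-signal R^2 near 0.4, an operating point at which
    leave-one-out prediction accuracy around r = 0.5 is attainable at
    n = 50-100 subjects.

    ``n_timepoints`` defaults to 230: an 8-minute run at TR = 2 s gives
    240 volumes of which the first 10 are discarded.
    """

    n_subjects: int
    n_nodes: int = 90
    n_timepoints: int = 230
    signal_edges: tuple[tuple[int, int], ...] = ()
    edge_effect_sizes: float | tuple[float, ...] = 0.4
    noise_sd: float = 1.0
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    nuisance_amplitude: float = 0.0
    random_seed: int | None = None
    fc_mode: str = "direct"          # "direct" edges, or "timeseries"
    intercept: float = 2.5
    edge_mean_loc: float = 0.25      # cohort-mean z-FC per edge ~ N(loc, scale)
    edge_mean_scale: float = 0.25
    n_factors: int = 20              # latent subject factors across edges
    factor_scale: float = 0.1        # factor k has strength scale/sqrt(k)
    residual_sd: float = 0.03        # i.i.d. per-edge residual SD
    edge_sd: float = 0.15            # extra subject SD on signal edges
    signal_groups: int = 2           # signal edges co-vary in this many groups
    signal_corr: float = 0.5         # within-group correlation of signal edges
    truncate_scores: tuple[float, float] | None = None
    extra_features: tuple[ExtraFeature, ...] = ()

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_nodes < 1 or self.n_timepoints < 1:
            raise ValueError("n_subjects, n_nodes, n_timepoints must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.nuisance_amplitude < 0:
            raise ValueError("nuisance_amplitude must be non-negative")
        if self.fc_mode not in ("direct", "timeseries"):
            raise ValueError("fc_mode must be 'direct' or 'timeseries'")
        if self.random_seed is None:
            raise ValueError("random_seed is required (no silent default)")
        if self.edge_sd < 0 or self.residual_sd < 0 or self.factor_scale < 0:
            raise ValueError("edge/residual/factor scales must be non-negative")
        if self.n_factors < 0:
            raise ValueError("n_factors must be non-negative")
        if self.residual_sd == 0 and self.n_factors == 0:
            raise ValueError("edges need some between-subject variation")
        if not (0.0 <= self.signal_corr <= 1.0):
            raise ValueError("signal_corr must be in [0, 1]")
        if self.signal_groups < 1:
            raise ValueError("signal_groups must be positive")
        edges = []
        seen = set()
        for i, j in self.signal_edges:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"signal edge ({i}, {j}) is a self-loop")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(
                    f"signal edge ({i}, {j}) outside atlas with {self.n_nodes} nodes"
                )
            pair = (min(i, j), max(i, j))
            if pair in seen:
                raise ValueError(f"duplicate signal edge {pair}")
            seen.add(pair)
            edges.append(pair)
        self.signal_edges = tuple(edges)
        if np.isscalar(self.edge_effect_sizes):
            self.edge_effect_sizes = tuple(
                [float(self.edge_effect_sizes)] * len(self.signal_edges)
            )
        else:
            self.edge_effect_sizes = tuple(float(b) for b in self.edge_effect_sizes)
            if len(self.edge_effect_sizes) != len(self.signal_edges):
                raise ValueError("one effect size per signal edge required")
        if not all(np.isfinite(self.edge_effect_sizes)):
            raise ValueError("effect sizes must be finite")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    fc_matrices: np.ndarray                  # subjects x nodes x nodes, z-space
    subject_table: pd.DataFrame
    atlas: AtlasDefinition
    truth: dict
    time_series: np.ndarray | None = None    # subjects x nodes x timepoints
    nuisance_regressors: np.ndarray | None = None  # timepoints x 10

    @property
    def n_subjects(self) -> int:
        return self.fc_matrices.shape[0]

    def features(self, extra: bool = False) -> np.ndarray:
        """Subjects x edges feature matrix (optionally with extra scalars)."""
        ex = None
        if extra and self.truth.get("extra_feature_names"):
            ex = self.subject_table[list(self.truth["extra_feature_names"])].to_numpy()
        return stack_features(self.fc_matrices, ex)


def generate_atlas(n_nodes: int, n_modules: int = 8, seed: int = 0) -> AtlasDefinition:
    """A random parcellation with named modules and MNI-scale centroids.

    When ``n_modules`` is 8 the modules carry the canonical system names
    (default mode, fronto-parietal, ventral attention, dorsal attention,
    visual, sensorimotor, limbic, subcortical); every module receives at
    least one node.  Centroids are drawn uniformly in a brain-sized box so
    short- and long-range edges both occur.
    """
    if n_nodes < 1 or n_modules < 1:
        raise ValueError("n_nodes and n_modules must be positive")
    if n_modules > n_nodes:
        raise ValueError("cannot have more modules than nodes")
    rng = np.random.default_rng(seed)
    if n_modules == 8:
        names = list(CANONICAL_MODULES)
    else:
        names = [f"module_{k + 1}" for k in range(n_modules)]
    assignment = np.concatenate(
        [np.arange(n_modules), rng.integers(0, n_modules, n_nodes - n_modules)]
    )
    rng.shuffle(assignment)
    centroids = np.column_stack(
        [rng.uniform(lo, hi, n_nodes) for lo, hi in _BOX]
    )
    return AtlasDefinition(
        labels=[f"region_{i:03d}" for i in range(n_nodes)],
        modules=[names[a] for a in assignment],
        centroids=centroids,
        abbreviations=[f"R{i}" for i in range(n_nodes)],
    )


def _edge_positions(pairs, n_nodes: int) -> np.ndarray:
    """Map unordered node pairs to positions in the canonical edge index."""
    idx = edge_index(n_nodes)
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(idx)}
    return np.array([lookup[p] for p in pairs], dtype=int)


def _nearest_correlation(R: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix."""
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    w = np.clip(w, floor, None)
    A = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    np.fill_diagonal(A, 1.0)
    return A


def add_nuisance(
    time_series: np.ndarray, amplitude: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Contaminate ROI series with shared low-rank nuisance signals.

    Ten regressors are emulated — one global signal, three tissue-like
    signals (smooth filtered noise) and six motion-like parameters (random
    walks) — and added to every node with random loadings scaled by
    ``amplitude``.  Returns ``(contaminated_series, regressors)`` with the
    regressor matrix timepoints x 10, so a least-squares clean-up can
    remove exactly what was injected.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    series = np.atleast_2d(np.asarray(time_series, dtype=float))
    n_nodes, n_t = series.shape
    rng = np.random.default_rng(seed)
    kernel = np.hanning(9)
    kernel /= kernel.sum()

    def smooth(x):
        return np.convolve(x, kernel, mode="same")

    cols = [smooth(rng.standard_normal(n_t))]            # global
    cols += [smooth(rng.standard_normal(n_t)) for _ in range(3)]   # tissue-like
    cols += [np.cumsum(rng.standard_normal(n_t)) for _ in range(6)]  # motion-like
    regressors = np.column_stack(cols)
    regressors = (regressors - regressors.mean(axis=0)) / regressors.std(axis=0)
    if amplitude == 0:
        return series.copy(), regressors
    loadings = np.empty((n_nodes, 10))
    loadings[:, 0] = rng.normal(1.0, 0.3, n_nodes)       # global hits all nodes alike
    loadings[:, 1:] = rng.normal(0.0, 1.0, (n_nodes, 9))
    return series + amplitude * loadings @ regressors.T, regressors


def simulate_cohort(
    config: SimulationConfig, atlas: AtlasDefinition | None = None
) -> SyntheticCohort:
    """Generate a cohort under the linear edge->score model.

    ``atlas`` lets the caller supply a parcellation (e.g. so signal edges
    can be planted within chosen modules); by default one is generated
    from the cohort seed.

    In ``direct`` mode the z-FC edges are drawn straight from the latent
    edge model (cohort-mean edge value + subject deviation).  In
    ``timeseries`` mode each subject's target correlation matrix is
    realized through multivariate-normal ROI time series and the FC is
    recomputed from those series, so the whole connectome stage is
    exercised end to end; scores are computed from the realized edges in
    that case, keeping the linear truth exact either way.
    """
    cfg = config
    rng = np.random.default_rng(cfg.random_seed)
    S, n = cfg.n_subjects, cfg.n_nodes
    m = n_edges(n)
    atlas_seed = int(rng.integers(2**31))  # drawn regardless, for stream stability
    if atlas is None:
        atlas = generate_atlas(n, 8 if n >= 8 else n, seed=atlas_seed)
    elif atlas.n_nodes != n:
        raise ValueError(
            f"supplied atlas has {atlas.n_nodes} nodes but config says {n}"
        )

    edge_means = rng.normal(cfg.edge_mean_loc, cfg.edge_mean_scale, m)
    positions = _edge_positions(cfg.signal_edges, n)
    # factor-structured between-subject edge variation + i.i.d. residual
    Z = edge_means[None, :] + cfg.residual_sd * rng.standard_normal((S, m))
    if cfg.n_factors > 0:
        tau = cfg.factor_scale / np.sqrt(np.arange(1, cfg.n_factors + 1))
        loadings = rng.standard_normal((m, cfg.n_factors)) * tau[None, :]
        factors = rng.standard_normal((S, cfg.n_factors))
        Z += factors @ loadings.T
    if positions.size:
        # signal edges: group-correlated subject variation (coherent
        # subsystems) plus an independent per-edge remainder
        k_sig = min(cfg.signal_groups, positions.size)
        group = np.arange(positions.size) % k_sig
        shared = rng.standard_normal((S, k_sig))[:, group]
        indiv = rng.standard_normal((S, positions.size))
        Z[:, positions] += cfg.edge_sd * (
            np.sqrt(cfg.signal_corr) * shared
            + np.sqrt(1.0 - cfg.signal_corr) * indiv
        )

    time_series = None
    regressors = None
    if cfg.fc_mode == "timeseries":
        ts = np.empty((S, n, cfg.n_timepoints))
        for s in range(S):
            R = np.tanh(devectorize(Z[s], n))
            np.fill_diagonal(R, 1.0)
            R = _nearest_correlation(R)
            L = np.linalg.cholesky(R)
            ts[s] = L @ rng.standard_normal((n, cfg.n_timepoints))
        # realized FC replaces the latent edges so the truth stays linear
        for s in range(S):
            Z[s] = vectorize(fisher_z(pearson_fc(ts[s]))).values
        time_series = ts
        if cfg.nuisance_amplitude > 0:
            contaminated = np.empty_like(ts)
            for s in range(S):
                contaminated[s], regressors = add_nuisance(
                    ts[s], cfg.nuisance_amplitude, seed=int(rng.integers(2**31))
                )
            time_series = contaminated

    cov = cfg.covariates
    age = rng.normal(cov.age_mean, cov.age_sd, S)
    education = rng.normal(cov.education_mean, cov.education_sd, S)
    sex = rng.binomial(1, cov.p_male, S).astype(float)   # 1 = male

    betas = np.asarray(cfg.edge_effect_sizes)
    edge_signal = Z[:, positions] @ betas if positions.size else np.zeros(S)
    y = (
        cfg.intercept
        + edge_signal
        + cov.age_beta * (age - cov.age_mean)
        + cov.education_beta * (education - cov.education_mean)
        + cov.sex_beta * (sex - cov.p_male)
        + cfg.noise_sd * rng.standard_normal(S)
    )
    if cfg.truncate_scores is not None:
        lo, hi = cfg.truncate_scores
        y = np.clip(y, lo, hi)

    # companion delayed-recall scores correlated with the primary one, on
    # scales resembling LMT-DR (3.3 +- 2.3) and CFT-DR (13.5 +- 6.0)
    y_sd = y.std() if y.std() > 0 else 1.0
    zy = (y - y.mean()) / y_sd
    lmt = 3.34 + 2.26 * (0.6 * zy + 0.8 * rng.standard_normal(S))
    cft = 13.47 + 6.03 * (0.5 * zy + np.sqrt(0.75) * rng.standard_normal(S))
    composite = (y + lmt + cft) / 3.0

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{s + 1:03d}" for s in range(S)],
            "avlt_dr": y,
            "lmt_dr": lmt,
            "cft_dr": cft,
            "composite": composite,
            "age": age,
            "sex": sex,
            "education": education,
        }
    )
    extra_names = []
    for ef in cfg.extra_features:
        noise = rng.standard_normal(S)
        table[ef.name] = ef.mean + ef.sd * (
            ef.score_corr * zy + np.sqrt(max(1.0 - ef.score_corr**2, 0.0)) * noise
        )
        extra_names.append(ef.name)

    fc = np.empty((S, n, n))
    for s in range(S):
        fc[s] = devectorize(Z[s], n)

    truth = {
        "signal_edges": [list(p) for p in cfg.signal_edges],
        "edge_positions": positions.tolist(),
        "edge_effect_sizes": betas.tolist(),
        "intercept": cfg.intercept,
        "noise_sd": cfg.noise_sd,
        "covariate_betas": {
            "age": cov.age_beta,
            "education": cov.education_beta,
            "sex": cov.sex_beta,
        },
        "edge_sd": cfg.edge_sd,
        "n_factors": cfg.n_factors,
        "factor_scale": cfg.factor_scale,
        "residual_sd": cfg.residual_sd,
        "fc_mode": cfg.fc_mode,
        "random_seed": cfg.random_seed,
        "extra_feature_names": extra_names,
    }
    return SyntheticCohort(
        fc_matrices=fc,
        subject_table=table,
        atlas=atlas,
        truth=truth,
        time_series=time_series,
        nuisance_regressors=regressors,
    )
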