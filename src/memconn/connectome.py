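"""Functional-connectivity construction and edge bookkeeping.

Regional BOLD time series are turned into Fisher-z Pearson connectivity
matrices, and each symmetric matrix is flattened into a canonical edge
feature vector (strict upper triangle, row-major, 0-based node ids — 4005
edges for a 90-node parcellation).  Atlas metadata attaches a network
module and an MNI-mm centroid to every node, so each edge can be labelled
by its module pair and by its Euclidean (anatomical) length; edges longer
than 75 mm are called long-range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

__all__ = [
    "CANONICAL_MODULES",
    "LONG_RANGE_MM",
    "AtlasDefinition",
    "ConnectivityMatrix",
    "FeatureVector",
    "DegenerateInputError",
    "edge_index",
    "n_edges",
    "detrend_and_bandpass",
    "regress_nuisance",
    "pearson_fc",
    "fisher_z",
    "vectorize",
    "devectorize",
    "stack_features",
    "edge_distance",
    "edge_distances",
    "is_long_range",
    "edge_module_pair",
]

#: The eight large-scale systems used to partition a 90-node parcellation:
#: the Yeo seven cortical networks plus a subcortical module.
CANONICAL_MODULES = (
    "default mode",
    "fronto-parietal",
    "ventral attention",
    "dorsal attention",
    "visual",
    "sensorimotor",
    "limbic",
    "subcortical",
)

#: Threshold (strict) on centroid Euclidean distance for calling an edge
#: long-range, in MNI millimetres.
LONG_RANGE_MM = 75.0


class DegenerateInputError(ValueError):
    """Raised when an input is degenerate (e.g. a constant time series)."""


@dataclass
class AtlasDefinition:
    """A parcellation: node labels, module memberships and MNI centroids.

    Node ids are implicit 0..n-1 positions.  ``modules`` holds one module
    name per node; ``centroids`` is an (n, 3) array of MNI coordinates in
    millimetres.
    """

    labels: list[str]
    modules: list[str]
    centroids: np.ndarray
    abbreviations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        n = len(self.labels)
        if len(self.modules) != n:
            raise ValueError("modules must have one entry per node")
        if self.centroids.shape != (n, 3):
            raise ValueError(f"centroids must be ({n}, 3), got {self.centroids.shape}")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if n == 0:
            raise ValueError("atlas must contain at least one node")
        if not self.abbreviations:
            self.abbreviations = [lab[:12] for lab in self.labels]
        elif len(self.abbreviations) != n:
            raise ValueError("abbreviations must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def module_names(self) -> list[str]:
        """Unique module names in order of first appearance."""
        seen: dict[str, None] = {}
        for m in self.modules:
            seen.setdefault(m)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes),
                "label": self.labels,
                "abbrev": self.abbreviations,
                "module": self.modules,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtlasDefinition":
        required = {"node_id", "label", "module", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        df = df.sort_values("node_id").reset_index(drop=True)
        ids = df["node_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(df))):
            raise ValueError("node_id must be 0..n-1 with no gaps or duplicates")
        abbrevs = (
            df["abbrev"].astype(str).tolist() if "abbrev" in df.columns else []
        )
        return cls(
            labels=df["label"].astype(str).tolist(),
            modules=df["module"].astype(str).tolist(),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
            abbreviations=abbrevs,
        )


@dataclass
class ConnectivityMatrix:
    """A symmetric node x node connectivity matrix for one subject.

    ``space`` is ``"r"`` for raw Pearson correlations and ``"z"`` after the
    Fisher transform.  The diagonal is self-connectivity and is ignored
    downstream (stored as 1 in r-space, 0 in z-space).
    """

    values: np.ndarray
    subject_id: str = ""
    space: str = "r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.space not in ("r", "z"):
            raise ValueError("space must be 'r' or 'z'")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric (tol 1e-10)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Edge features for one subject, aligned to the canonical edge index.

    ``extra_features`` holds named scalars (e.g. hippocampal volume)
    appended after the edges when a combined feature matrix is assembled.
    """

    values: np.ndarray
    subject_id: str = ""
    n_nodes: int = 0
    extra_features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.n_nodes:
            if self.values.size != n_edges(self.n_nodes):
                raise ValueError("edge vector length does not match n_nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("edge features must be finite")


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs: n(n-1)/2 (4005 for n=90)."""
    return n_nodes * (n_nodes - 1) // 2


def edge_index(n_nodes: int) -> np.ndarray:
    """Canonical edge index: (m, 2) array of node pairs (i, j), i < j.

    Row-major strict upper-triangle order, so position k of every feature
    vector, weight vector and truth record refers to the same edge.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def detrend_and_bandpass(
    series: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Linear detrending followed by zero-phase band-pass filtering.

    ``series`` is node x timepoint.  The band [low_hz, high_hz] keeps the
    slow BOLD fluctuations and removes drift and high-frequency
    physiological noise.  A third-order Butterworth filter is applied
    forward and backward (``filtfilt``), so the pass-band is effectively
    sixth order with zero phase shift.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_t = series.shape[1]
    if n_t < 16:
        raise ValueError("need at least 16 timepoints to filter")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 <= low < high < "
            f"Nyquist ({nyquist:g} Hz at TR={tr_seconds:g} s)"
        )
    detrended = sp_signal.detrend(series, axis=1, type="linear")
    if low_hz > 0:
        sos = sp_signal.butter(
            3, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos"
        )
    else:
        sos = sp_signal.butter(
            3, high_hz, btype="lowpass", fs=1.0 / tr_seconds, output="sos"
        )
    return sp_signal.sosfiltfilt(sos, detrended, axis=1)


def regress_nuisance(series: np.ndarray, regressors: np.ndarray | None) -> np.ndarray:
    """Residualize each node series against nuisance regressors.

    The design is [1, regressors] (timepoint x (k+1)); with an empty
    regressor set the series are simply mean-centred.  Rank-deficient
    designs fall back to the pseudoinverse with a warning.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n_t = series.shape[1]
    if regressors is None or np.size(regressors) == 0:
        design = np.ones((n_t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != n_t:
            raise ValueError("regressor rows must match timepoints")
        if regressors.shape[1] >= n_t:
            raise ValueError("need fewer regressors than timepoints")
        design = np.column_stack([np.ones(n_t), regressors])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(
                "nuisance design is rank deficient; using pseudoinverse",
                RuntimeWarning,
                stacklevel=2,
            )
    beta, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    return series - (design @ beta).T


def pearson_fc(series: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time series."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sds = series.std(axis=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        raise DegenerateInputError(
            f"constant time series at node(s) {constant.tolist()}; "
            "correlation undefined"
        )
    r = np.corrcoef(series)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(values=r, subject_id=subject_id, space="r")


def fisher_z(matrix: ConnectivityMatrix, clamp: float = 1e-7) -> ConnectivityMatrix:
    """Fisher z-transform: z = atanh(r), with |r| clamped to 1 - clamp.

    Clamping keeps perfect correlations finite so degenerate inputs never
    inject infinities downstream.  The diagonal is set to 0 in z-space.
    """
    if matrix.space != "r":
        raise ValueError("fisher_z expects an r-space matrix")
    r = np.clip(matrix.values, -1.0 + clamp, 1.0 - clamp)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(values=z, subject_id=matrix.subject_id, space="z")


def vectorize(
    matrix: ConnectivityMatrix | np.ndarray,
    atlas: AtlasDefinition | None = None,
    atol: float = 1e-8,
    subject_id: str | None = None,
) -> FeatureVector:
    """Flatten a symmetric matrix into the canonical edge feature vector."""
    if isinstance(matrix, ConnectivityMatrix):
        values = matrix.values
        sid = subject_id if subject_id is not None else matrix.subject_id
    else:
        values = np.asarray(matrix, dtype=float)
        sid = subject_id or ""
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(values, values.T, atol=atol):
        raise ValueError(f"matrix asymmetric beyond tolerance {atol:g}")
    n = values.shape[0]
    if atlas is not None and atlas.n_nodes != n:
        raise ValueError(
            f"matrix has {n} nodes but atlas has {atlas.n_nodes}"
        )
    iu = np.triu_indices(n, k=1)
    return FeatureVector(values=values[iu].copy(), subject_id=sid, n_nodes=n)


def devectorize(values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size != n_edges(n_nodes):
        raise ValueError(
            f"expected {n_edges(n_nodes)} edges for {n_nodes} nodes, "
            f"got {values.size}"
        )
    mat = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = values
    return mat + mat.T


def stack_features(
    fc_matrices: np.ndarray | list[np.ndarray],
    extra: np.ndarray | None = None,
) -> np.ndarray:
    """Stack per-subject FC matrices into a subjects x edges feature matrix.

    ``extra`` (subjects x p) scalar features, e.g. hippocampal volume, are
    appended after the edge block; they are scaled together with the edges
    by the prediction framework.
    """
    mats = np.asarray(fc_matrices, dtype=float)
    if mats.ndim != 3:
        raise ValueError("fc_matrices must be subjects x nodes x nodes")
    n = mats.shape[1]
    iu = np.triu_indices(n, k=1)
    X = mats[:, iu[0], iu[1]]
    if extra is not None:
        extra = np.atleast_2d(np.asarray(extra, dtype=float))
        if extra.shape[0] != X.shape[0]:
            extra = extra.T
        if extra.shape[0] != X.shape[0]:
            raise ValueError("extra features must have one row per subject")
        X = np.column_stack([X, extra])
    return X


def edge_distance(edge: tuple[int, int], atlas: AtlasDefinition) -> float:
    """Euclidean distance in mm between the two node centroids of an edge."""
    i, j = edge
    n = atlas.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"edge ({i}, {j}) outside atlas with {n} nodes")
    return float(np.linalg.norm(atlas.centroids[i] - atlas.centroids[j]))


def edge_distances(atlas: AtlasDefinition) -> np.ndarray:
    """Distances for every edge in canonical order (vectorized)."""
    idx = edge_index(atlas.n_nodes)
    diffs = atlas.centroids[idx[:, 0]] - atlas.centroids[idx[:, 1]]
    return np.linalg.norm(diffs, axis=1)


def is_long_range(distance_mm: float | np.ndarray) -> bool | np.ndarray:
    """An edge is long-range iff its length strictly exceeds 75 mm."""
    return np.asarray(distance_mm) > LONG_RANGE_MM if np.ndim(distance_mm) else distance_mm > LONG_RANGE_MM


def edge_module_pair(
    edge: tuple[int, int], atlas: AtlasDefinition
) -> tuple[str, str, bool]:
    """Unordered module pair of an edge and whether it is within-module."""
    i, j = edge
    n = atlas.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"edge ({i}, {j}) outside atlas with {n} nodes")
    a, b = atlas.modules[i], atlas.modules[j]
    mod_a, mod_b = sorted((a, b))
    return mod_a, mod_b, a == b
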