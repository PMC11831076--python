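"""Plain-text readers and writers.

Everything on disk is diff-able text: atlases and FC matrices as TSV,
feature matrices and subject tables as CSV with headers, truth records
and result summaries as JSON, plus BrainNet Viewer ``.node``/``.edge``
exports for visualization tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import AtlasDefinition, devectorize, edge_index, n_edges
from .interpretation import ContributionReport

__all__ = [
    "read_atlas",
    "write_atlas",
    "read_fc_matrix",
    "write_fc_matrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_subject_table",
    "write_subject_table",
    "read_timeseries",
    "write_timeseries",
    "read_truth",
    "write_truth",
    "write_json",
    "write_brainnet_node",
    "write_brainnet_edge",
]


def write_atlas(atlas: AtlasDefinition, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def read_atlas(path) -> AtlasDefinition:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"atlas file not found: {path}")
    return AtlasDefinition.from_frame(pd.read_csv(path, sep="\t"))


def write_fc_matrix(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.10g")


def read_fc_matrix(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FC matrix file not found: {path}")
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: FC matrix must be square, got {values.shape}")
    return values


def write_timeseries(series: np.ndarray, path) -> None:
    """Node x timepoint TSV for one subject."""
    np.savetxt(path, np.atleast_2d(np.asarray(series, dtype=float)),
               delimiter="\t", fmt="%.10g")


def read_timeseries(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series file not found: {path}")
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def _edge_columns(n_nodes: int) -> list[str]:
    return [f"{i}_{j}" for i, j in edge_index(n_nodes)]


def write_feature_matrix(
    X: np.ndarray, path, n_nodes: int, subject_ids=None, extra_names=()
) -> None:
    """Stacked subjects x edges CSV with an ``i_j`` edge-index header."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = n_edges(n_nodes)
    cols = _edge_columns(n_nodes) + list(extra_names)
    if X.shape[1] != len(cols):
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns; expected {m} edges"
            + (f" + {len(extra_names)} extras" if extra_names else "")
        )
    if subject_ids is None:
        subject_ids = [f"sub-{s + 1:03d}" for s in range(X.shape[0])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (features, subject_ids, feature_column_names)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature matrix file not found: {path}")
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'subject_id'")
    ids = df["subject_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate subject_ids")
    feats = df.drop(columns=["subject_id"])
    bad = [c for c in feats.columns if not np.issubdtype(feats[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric feature columns {bad}")
    if feats.isna().any().any():
        raise ValueError(f"{path}: missing values in feature matrix")
    return feats.to_numpy(dtype=float), ids, list(feats.columns)


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_subject_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Subject table CSV with per-row validation of the used columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"subject table not found: {path}")
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'subject_id'")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    ids = df["subject_id"].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate subject_id(s) {dup}")
    for col in required:
        series = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[series.isna()].tolist()
        if bad_rows:
            raise ValueError(
                f"{path}: column '{col}' has missing/non-numeric values "
                f"at row(s) {bad_rows}"
            )
        df[col] = series
    return df


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_brainnet_node(atlas: AtlasDefinition, path, sizes=None) -> None:
    """BrainNet Viewer .node: x y z module_code size label."""
    module_code = {m: c + 1 for c, m in enumerate(atlas.module_names)}
    if sizes is None:
        sizes = np.ones(atlas.n_nodes)
    with open(path, "w") as fh:
        for i in range(atlas.n_nodes):
            x, y, z = atlas.centroids[i]
            fh.write(
                f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{module_code[atlas.modules[i]]}\t"
                f"{float(sizes[i]):.3f}\t{atlas.abbreviations[i]}\n"
            )


def write_brainnet_edge(
    report: ContributionReport, atlas: AtlasDefinition, path, signed: bool = True
) -> None:
    """BrainNet Viewer .edge: n x n adjacency of the selected edges."""
    n = atlas.n_nodes
    vals = np.zeros(n_edges(n))
    idx = {tuple(e): k for k, e in enumerate(map(tuple, edge_index(n)))}
    for e in report.edges:
        vals[idx[e.edge]] = e.mean_weight if signed else e.mean_abs_weight
    adj = devectorize(vals, n)
    np.savetxt(path, adj, delimiter="\t", fmt="%.6g")
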