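"""Interpretation of predictive connections.

A feature's contribution to the fitted model is measured by the absolute
value of its (fold-averaged) primal regression weight.  The top fraction
of edges by mean absolute weight — top 1% by default, i.e. 40 of 4005
edges on a 90-node parcellation — is selected and characterized two ways:
by unordered network-module pair (within-module vs between-module) and by
anatomical length (long-range iff centroid distance > 75 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .connectome import (
    LONG_RANGE_MM,
    AtlasDefinition,
    edge_distances,
    edge_index,
    n_edges,
)
from .rvr import RVRModel, primal_weights

__all__ = [
    "EdgeContribution",
    "ContributionReport",
    "aggregate_weights",
    "top_percent_count",
    "select_top_edges",
    "module_pair_summary",
    "report_to_frame",
]


@dataclass
class EdgeContribution:
    """One selected edge with its weight, rank and anatomical labels."""

    edge: tuple[int, int]
    mean_weight: float
    mean_abs_weight: float
    rank: int                      # 1-based dense rank by mean |weight|
    module_pair: tuple[str, str]   # unordered (alphabetical)
    within_module: bool
    distance_mm: float
    long_range: bool


@dataclass
class ContributionReport:
    """The selected edge set and its module/distance breakdown."""

    fraction: float
    n_selected: int
    n_total_edges: int
    edges: list[EdgeContribution]
    module_pair_counts: dict[tuple[str, str], int]
    n_long_range: int

    @property
    def n_short_range(self) -> int:
        return self.n_selected - self.n_long_range

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "n_selected": self.n_selected,
            "n_total_edges": self.n_total_edges,
            "n_long_range": self.n_long_range,
            "n_short_range": self.n_short_range,
            "module_pair_counts": {
                " | ".join(pair): count
                for pair, count in sorted(self.module_pair_counts.items())
            },
            "edges": [
                {
                    "i": e.edge[0],
                    "j": e.edge[1],
                    "mean_weight": e.mean_weight,
                    "mean_abs_weight": e.mean_abs_weight,
                    "rank": e.rank,
                    "module_a": e.module_pair[0],
                    "module_b": e.module_pair[1],
                    "within_module": e.within_module,
                    "distance_mm": e.distance_mm,
                    "long_range": e.long_range,
                }
                for e in self.edges
            ],
        }


def aggregate_weights(fold_models) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean and mean-absolute primal weights across CV folds.

    Accepts a list of fitted models or raw per-fold weight vectors.  The
    mean tracks signed consistency; the mean absolute value measures
    contribution magnitude and is what drives edge ranking.
    """
    if len(fold_models) == 0:
        raise ValueError("need at least one fold model")
    rows = []
    for fm in fold_models:
        w = primal_weights(fm) if isinstance(fm, RVRModel) else np.asarray(fm, dtype=float)
        rows.append(w.ravel())
    lengths = {len(w) for w in rows}
    if len(lengths) != 1:
        raise ValueError(f"heterogeneous feature counts across folds: {sorted(lengths)}")
    W = np.vstack(rows)
    return W.mean(axis=0), np.abs(W).mean(axis=0)


def top_percent_count(m: int, fraction: float) -> int:
    """Number of edges at a top-percent threshold.

    Round half away from zero, minimum 1 — this reconciles both canonical
    counts on 4005 edges: 1% -> 40.05 -> 40 and 10% -> 400.5 -> 401.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be positive")
    return max(int(np.floor(fraction * m + 0.5)), 1)


def select_top_edges(
    mean_weights: np.ndarray,
    mean_abs_weights: np.ndarray,
    atlas: AtlasDefinition,
    fraction: float = 0.01,
) -> ContributionReport:
    """Select the top-fraction edges by mean absolute weight.

    Ties at the cut are broken deterministically by canonical edge order
    (smaller i, then smaller j).  Extra scalar features appended after the
    edge block, if any, are outside the edge ranking and must be stripped
    by the caller.
    """
    mw = np.asarray(mean_weights, dtype=float).ravel()
    maw = np.asarray(mean_abs_weights, dtype=float).ravel()
    m = n_edges(atlas.n_nodes)
    if mw.size != m or maw.size != m:
        raise ValueError(
            f"expected {m} edge weights for {atlas.n_nodes} nodes, got {mw.size}"
        )
    idx = edge_index(atlas.n_nodes)
    # lexsort: last key is primary
    order = np.lexsort((idx[:, 1], idx[:, 0], -maw))
    k = top_percent_count(m, fraction)
    selected = order[:k]
    dense_rank = sp_stats.rankdata(-maw, method="dense").astype(int)
    dists = edge_distances(atlas)

    edges = []
    pair_counts: dict[tuple[str, str], int] = {}
    n_long = 0
    for e in selected:
        i, j = int(idx[e, 0]), int(idx[e, 1])
        pair = tuple(sorted((atlas.modules[i], atlas.modules[j])))
        pair_counts[pair] = pair_counts.get(pair, 0) + 1
        lr = bool(dists[e] > LONG_RANGE_MM)
        n_long += lr
        edges.append(
            EdgeContribution(
                edge=(i, j),
                mean_weight=float(mw[e]),
                mean_abs_weight=float(maw[e]),
                rank=int(dense_rank[e]),
                module_pair=pair,
                within_module=atlas.modules[i] == atlas.modules[j],
                distance_mm=float(dists[e]),
                long_range=lr,
            )
        )
    return ContributionReport(
        fraction=fraction,
        n_selected=k,
        n_total_edges=m,
        edges=edges,
        module_pair_counts=pair_counts,
        n_long_range=n_long,
    )


def module_pair_summary(
    report: ContributionReport, atlas: AtlasDefinition
) -> pd.DataFrame:
    """Counts of selected edges per unordered module pair.

    With M modules there are at most M within-module bins plus C(M, 2)
    between-module bins; counts always sum to the selected edge count.
    """
    rows = [
        {
            "module_a": pair[0],
            "module_b": pair[1],
            "within_module": pair[0] == pair[1],
            "count": count,
        }
        for pair, count in sorted(report.module_pair_counts.items())
    ]
    df = pd.DataFrame(rows, columns=["module_a", "module_b", "within_module", "count"])
    if len(df) and df["count"].sum() != report.n_selected:
        raise AssertionError("module-pair counts do not partition the selection")
    unknown = {m for pair in report.module_pair_counts for m in pair} - set(
        atlas.module_names
    )
    if unknown:
        raise ValueError(f"modules not in atlas: {sorted(unknown)}")
    return df


def report_to_frame(report: ContributionReport, atlas: AtlasDefinition) -> pd.DataFrame:
    """Ranked edge table for CSV export."""
    return pd.DataFrame(
        [
            {
                "rank": e.rank,
                "node_i": e.edge[0],
                "node_j": e.edge[1],
                "label_i": atlas.labels[e.edge[0]],
                "label_j": atlas.labels[e.edge[1]],
                "module_i": atlas.modules[e.edge[0]],
                "module_j": atlas.modules[e.edge[1]],
                "within_module": e.within_module,
                "mean_weight": e.mean_weight,
                "mean_abs_weight": e.mean_abs_weight,
                "distance_mm": e.distance_mm,
                "long_range": e.long_range,
            }
            for e in report.edges
        ]
    )
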