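"""Graph-topology metrics on thresholded connectivity graphs.

Two global metrics are computed on the *binarized* thresholded graph:

* global efficiency, ``E = mean over ordered pairs of 1/d_ij`` with ``d_ij``
  the unweighted shortest-path length (disconnected pairs contribute 0), a
  proxy for network integration;
* average clustering coefficient, ``C = mean_i 2 t_i / (k_i (k_i - 1))``
  with ``t_i`` the triangles through node ``i`` (``C_i = 0`` for ``k_i < 2``),
  a proxy for local segregation.

Subnetwork analyses operate on the unthresholded Fisher-z matrix: weighted
efficiency on a min-max 0-1 normalised submatrix, within-network mean FC,
and node strength (mean absolute connectivity of a seed to all other
regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectivity import FcMatrix, ThresholdedGraph, mean_nonzero_fc, proportional_threshold
from .parcellation import NetworkDefinition

__all__ = [
    "MetricCurve",
    "global_efficiency_binary",
    "clustering_coefficient_binary",
    "weighted_efficiency",
    "node_strength",
    "network_mean_fc",
    "metric_curves",
    "DEFAULT_SPARSITY_LEVELS",
]

#: Default proportional-threshold grid: 5% to 50% in 5% steps (10 levels).
DEFAULT_SPARSITY_LEVELS: tuple[float, ...] = tuple(range(5, 55, 5))

METRIC_NAMES = ("mean_fc", "global_efficiency", "clustering_coefficient")


@dataclass
class MetricCurve:
    """One metric evaluated over the sparsity grid for one subject-session."""

    metric: str
    sparsity_levels: tuple[float, ...]
    values: np.ndarray
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.sparsity_levels) != self.values.size:
            raise ValueError("values length must equal number of levels")
        lv = np.asarray(self.sparsity_levels, dtype=float)
        if np.any(np.diff(lv) <= 0):
            raise ValueError("sparsity levels must be strictly increasing")


def _as_adjacency(g: ThresholdedGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, ThresholdedGraph):
        return g.binary_adjacency()
    a = (np.asarray(g) != 0).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return a


def global_efficiency_binary(g: ThresholdedGraph | np.ndarray) -> float:
    """Binary global efficiency: mean inverse shortest-path length.

    Disconnected pairs contribute 0 (1/inf); a complete graph scores 1 and
    an edgeless graph 0.
    """
    a = _as_adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient_binary(g: ThresholdedGraph | np.ndarray) -> float:
    """Average binary clustering coefficient (C_i = 0 for degree < 2)."""
    a = _as_adjacency(g).astype(float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    k = a.sum(axis=1)
    t = np.diag(a @ a @ a) / 2.0  # triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return float(c.mean())


def _normalized_submatrix(fc: FcMatrix, net: NetworkDefinition) -> np.ndarray:
    idx = net.indices(fc.roi_names)
    w = fc.z[np.ix_(idx, idx)].copy()
    m = w.shape[0]
    off = ~np.eye(m, dtype=bool)
    lo, hi = w[off].min(), w[off].max()
    if hi == lo:
        raise ValueError("degenerate normalization: constant subnetwork matrix")
    w[off] = (w[off] - lo) / (hi - lo)
    np.fill_diagonal(w, 0.0)
    return w


def weighted_efficiency(fc: FcMatrix, net: NetworkDefinition) -> float:
    """Weighted efficiency on a 0-1 min-max normalised subnetwork.

    Edge lengths are the reciprocal of the normalised weights (infinite for
    zero weights); efficiency is the mean over ordered node pairs of the
    inverse weighted shortest-path distance.
    """
    w = _normalized_submatrix(fc, net)
    m = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, np.inf)
    lengths[~np.isfinite(lengths)] = 0.0  # csgraph treats 0 as "no edge"
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (m * (m - 1)))


def node_strength(fc: FcMatrix, seeds: Sequence[str]) -> pd.DataFrame:
    """Mean absolute connectivity of each seed region to all other regions.

    Operates on the unthresholded Fisher-z matrix.  Returns a long-format
    table (subject_id, timepoint, region, value, value_kind).
    """
    if len(seeds) == 0:
        raise ValueError("seed list is empty")
    unknown = [s for s in seeds if s not in fc.roi_names]
    if unknown:
        raise ValueError(f"unknown ROI name(s): {unknown}")
    rows = []
    for s in seeds:
        i = fc.roi_names.index(s)
        row = np.abs(np.delete(fc.z[i], i))
        rows.append((fc.subject_id, fc.timepoint, s, float(row.mean()),
                     "node_strength"))
    return pd.DataFrame(
        rows, columns=["subject_id", "timepoint", "region", "value",
                       "value_kind"])


def network_mean_fc(fc: FcMatrix, net: NetworkDefinition) -> float:
    """Mean Fisher-z over all within-network pairs, unthresholded."""
    idx = net.indices(fc.roi_names)
    sub = fc.z[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def metric_curves(fc: FcMatrix,
                  levels: Iterable[float] = DEFAULT_SPARSITY_LEVELS,
                  ranking: str = "signed") -> dict[str, MetricCurve]:
    """Evaluate mean FC, global efficiency and clustering over the grid.

    ``levels`` are percentages in (0, 100]; the default 5..50% grid yields
    10 values per metric.
    """
    levels = tuple(float(l) for l in levels)
    if any(not 0 < l <= 100 for l in levels):
        raise ValueError("sparsity levels must lie in (0, 100]")
    vals = {m: [] for m in METRIC_NAMES}
    for lv in levels:
        g = proportional_threshold(fc, lv / 100.0, ranking=ranking)
        vals["mean_fc"].append(mean_nonzero_fc(g))
        vals["global_efficiency"].append(global_efficiency_binary(g))
        vals["clustering_coefficient"].append(clustering_coefficient_binary(g))
    return {
        m: MetricCurve(metric=m, sparsity_levels=levels,
                       values=np.array(v), subject_id=fc.subject_id,
                       timepoint=fc.timepoint)
        for m, v in vals.items()
    }


def curves_to_frame(curves: Iterable[MetricCurve]) -> pd.DataFrame:
    """Long-format table (subject, timepoint, metric, sparsity, value)."""
    rows = []
    for c in curves:
        for lv, v in zip(c.sparsity_levels, c.values):
            rows.append((c.subject_id, c.timepoint, c.metric, lv, v))
    return pd.DataFrame(
        rows, columns=["subject_id", "timepoint", "metric", "sparsity",
                       "value"])
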