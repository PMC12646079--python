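"""ROI time courses to functional-connectivity graphs.

Functional connectivity is estimated as the Pearson correlation between
regional BOLD time courses, Fisher z-transformed (z = atanh r) so that edge
weights are approximately variance-stabilised.  Graphs are sparsified by
proportional thresholding: at sparsity ``s`` the top ``round(s * E)`` of the
``E = R(R-1)/2`` edges (ranked by signed z by default) are retained and the
rest set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TimecourseMatrix",
    "FcMatrix",
    "ThresholdedGraph",
    "SeedMap",
    "pearson_fc",
    "fisher_z",
    "fc_from_timecourses",
    "proportional_threshold",
    "mean_nonzero_fc",
    "seed_correlation_map",
]

#: Correlations are clipped to +-(1 - CLIP_EPS) before atanh so z stays finite.
CLIP_EPS = 1e-7


@dataclass
class TimecourseMatrix:
    """T x R matrix of ROI signals for one subject-session."""

    values: np.ndarray
    roi_names: list[str]
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("timecourse values must be a T x R matrix")
        if self.values.shape[0] < 3:
            raise ValueError("need T >= 3 samples for correlation")
        if self.values.shape[1] != len(self.roi_names):
            raise ValueError("roi_names length must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timecourse contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class FcMatrix:
    """Symmetric R x R Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    roi_names: list[str]
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        r = self.z.shape[0]
        if self.z.shape != (r, r) or r != len(self.roi_names):
            raise ValueError("z must be R x R matching roi_names")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite entries")
        if np.max(np.abs(self.z - self.z.T)) > 1e-12:
            raise ValueError("z must be symmetric within 1e-12")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be exactly zero")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def upper_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.z[iu]


@dataclass
class ThresholdedGraph:
    """A proportionally thresholded connectivity graph.

    ``z_thresholded`` keeps the retained edges' z values; everything below
    the cut (and the diagonal) is zero.
    """

    z_thresholded: np.ndarray
    sparsity: float
    retained_edges: int
    roi_names: list[str]
    ranking: str = "signed"

    @property
    def n_rois(self) -> int:
        return self.z_thresholded.shape[0]

    def binary_adjacency(self) -> np.ndarray:
        a = (self.z_thresholded != 0).astype(np.uint8)
        np.fill_diagonal(a, 0)
        return a


def pearson_fc(tc: TimecourseMatrix | np.ndarray,
               roi_names: Sequence[str] | None = None) -> np.ndarray:
    """Pearson correlation matrix of ROI time courses.

    Parameters
    ----------
    tc
        A :class:`TimecourseMatrix` or a plain T x R array.
    roi_names
        ROI labels used in error messages when a plain array is given.

    Returns
    -------
    R x R symmetric correlation matrix with unit diagonal.
    """
    if isinstance(tc, TimecourseMatrix):
        x = tc.values
        names = tc.roi_names
    else:
        x = np.asarray(tc, dtype=float)
        names = list(roi_names) if roi_names is not None else [
            f"roi{i}" for i in range(x.shape[1])
        ]
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            "zero-variance time course for ROI(s): "
            + ", ".join(names[i] for i in bad)
        )
    r = np.corrcoef(x, rowvar=False)
    # corrcoef can exceed [-1, 1] by float error
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(corr: np.ndarray, roi_names: Sequence[str] | None = None,
             **meta) -> FcMatrix:
    """Fisher z-transform a correlation matrix into an :class:`FcMatrix`.

    |r| is clipped to ``1 - 1e-7`` so perfectly correlated pairs map to a
    large finite z (~8.4) instead of infinity; the diagonal is forced to 0.
    """
    r = np.asarray(corr, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -(1 - CLIP_EPS), 1 - CLIP_EPS))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    if roi_names is None:
        roi_names = [f"roi{i}" for i in range(r.shape[0])]
    return FcMatrix(z=z, roi_names=list(roi_names), **meta)


def fc_from_timecourses(tc: TimecourseMatrix) -> FcMatrix:
    """Pearson correlation followed by Fisher z, keeping session metadata."""
    return fisher_z(pearson_fc(tc), tc.roi_names,
                    subject_id=tc.subject_id, timepoint=tc.timepoint)


def _edge_order(z: np.ndarray, ranking: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices sorted by descending strength.

    Ties are broken by (row, column) lexicographic order, which makes the
    retained sets nested across sparsity levels.
    """
    r = z.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    vals = z[iu, ju]
    key = np.abs(vals) if ranking == "absolute" else vals
    # stable sort on descending key; row-major upper-triangle order breaks ties
    order = np.argsort(-key, kind="stable")
    return iu[order], ju[order]


def proportional_threshold(fc: FcMatrix, sparsity: float,
                           ranking: Literal["signed", "absolute"] = "signed",
                           ) -> ThresholdedGraph:
    """Keep the strongest fraction of edges, zeroing the rest.

    Edges are ranked by signed z (largest first) by default; ``ranking=
    "absolute"`` ranks by |z| instead.  The retained edge count is
    ``round(sparsity * R(R-1)/2)`` with half-away-from-zero rounding.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    r = fc.n_rois
    n_edges = r * (r - 1) // 2
    keep = int(np.floor(sparsity * n_edges + 0.5))
    ii, jj = _edge_order(fc.z, ranking)
    out = np.zeros_like(fc.z)
    ki, kj = ii[:keep], jj[:keep]
    out[ki, kj] = fc.z[ki, kj]
    out[kj, ki] = fc.z[kj, ki]
    return ThresholdedGraph(out, float(sparsity), keep, list(fc.roi_names),
                            ranking=ranking)


def mean_nonzero_fc(g: ThresholdedGraph) -> float:
    """Mean of the retained (non-zero) upper-triangle z values."""
    if g.retained_edges < 1:
        raise ValueError("graph has no retained edges")
    iu = np.triu_indices(g.n_rois, k=1)
    vals = g.z_thresholded[iu]
    vals = vals[vals != 0]
    if vals.size == 0:
        raise ValueError("graph has no non-zero edges")
    return float(vals.mean())


@dataclass
class SeedMap:
    """Per-voxel Fisher-z correlation with a seed time course."""

    z: np.ndarray
    n_constant_voxels: int = 0


def seed_correlation_map(seed_tc: np.ndarray, voxel_tcs: np.ndarray) -> SeedMap:
    """Correlate a seed time course against every voxel time course.

    Parameters
    ----------
    seed_tc
        Length-T seed signal.
    voxel_tcs
        T x V matrix of voxel signals sharing the seed's sampling.

    Returns
    -------
    :class:`SeedMap` with a length-V Fisher-z vector.  Zero-variance voxels
    map to z = 0 and are counted in ``n_constant_voxels`` (with a warning).
    """
    s = np.asarray(seed_tc, dtype=float).ravel()
    v = np.asarray(voxel_tcs, dtype=float)
    if v.ndim != 2 or v.shape[0] != s.shape[0]:
        raise ValueError("voxel_tcs must be T x V with T matching the seed")
    if s.std() == 0:
        raise ValueError("seed time course has zero variance")
    sc = s - s.mean()
    vc = v - v.mean(axis=0)
    denom = np.sqrt((sc**2).sum()) * np.sqrt((vc**2).sum(axis=0))
    constant = denom == 0
    n_const = int(constant.sum())
    if n_const:
        warnings.warn(f"{n_const} zero-variance voxel(s) mapped to z=0",
                      stacklevel=2)
    denom = np.where(constant, 1.0, denom)
    r = np.clip(sc @ vc / denom, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -(1 - CLIP_EPS), 1 - CLIP_EPS))
    z[constant] = 0.0
    return SeedMap(z=z, n_constant_voxels=n_const)
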