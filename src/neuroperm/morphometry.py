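"""ROI-based morphometry from Jacobian-determinant maps.

Regional volume is the sum of Jacobian determinants over the region's
voxels times the voxel volume (tensor-based morphometry convention); the
total brain volume is the same sum over the template brain mask, and
relative volumes are region/total.  A coefficient-of-variation audit
(CV = sd/mean per region per group) quantifies measurement variability,
and ROI medians summarise FA images over white-matter parcels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "JacobianVolume",
    "LabelVolume",
    "regional_volumes",
    "region_cv",
    "roi_median",
]


@dataclass
class JacobianVolume:
    """3D Jacobian-determinant map with voxel size and brain mask."""

    values: np.ndarray
    voxel_volume: float  # mm^3
    mask: np.ndarray | None = None
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Jacobian map must be 3D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None,
                   **meta) -> "JacobianVolume":
        import nibabel as nib

        img = nib.load(str(path))
        vox = float(np.prod(img.header.get_zooms()[:3]))
        return cls(values=np.asanyarray(img.dataobj, dtype=float),
                   voxel_volume=vox, mask=mask, **meta)


@dataclass
class LabelVolume:
    """Integer atlas labels (0 = background) with a label -> name lookup."""

    labels: np.ndarray
    lookup: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.lookup)
        if unknown:
            raise ValueError(f"labels without lookup entry: {sorted(unknown)}")

    @classmethod
    def from_nifti(cls, path, lookup: dict[int, str]) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(labels=np.asanyarray(img.dataobj).astype(int),
                   lookup=lookup)


def regional_volumes(jac: JacobianVolume, atlas: LabelVolume) -> pd.DataFrame:
    """Absolute (mm^3) and relative regional volumes from a Jacobian map.

    Region volume is the sum of J over labelled voxels times the voxel
    volume; total brain volume sums J over the brain mask; relative volume
    is region/total.  Non-positive Jacobians inside the mask are a warning
    (a valid diffeomorphism has positive determinant).
    """
    if jac.values.shape != atlas.labels.shape:
        raise ValueError("Jacobian and atlas shapes differ: "
                         f"{jac.values.shape} vs {atlas.labels.shape}")
    bad = int(np.sum((jac.values <= 0) & jac.mask))
    if bad:
        warnings.warn(f"{bad} non-positive Jacobian voxel(s) inside mask",
                      stacklevel=2)
    total = float(jac.values[jac.mask].sum() * jac.voxel_volume)
    lab = atlas.labels.ravel()
    vals = jac.values.ravel()
    sums = np.bincount(lab, weights=vals)
    rows = []
    for label, name in sorted(atlas.lookup.items()):
        vol = float(sums[label] * jac.voxel_volume) if label < sums.size else 0.0
        rows.append((jac.subject_id, jac.timepoint, name, vol,
                     "absolute_mm3"))
        rows.append((jac.subject_id, jac.timepoint, name,
                     vol / total if total > 0 else np.nan,
                     "relative_fraction"))
    rows.append((jac.subject_id, jac.timepoint, "total brain", total,
                 "absolute_mm3"))
    return pd.DataFrame(rows, columns=["subject_id", "timepoint", "region",
                                       "value", "value_kind"])


def region_cv(table: pd.DataFrame, group_cols: list[str] | str = "genotype",
              value_col: str = "value",
              region_col: str = "region") -> pd.DataFrame:
    """Coefficient of variation sd/mean (sample sd, ddof=1) per region per
    group."""
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    rows = []
    for keys, sub in table.groupby(group_cols + [region_col], sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"need >= 2 subjects per group for {keys}")
        mean = v.mean()
        if mean <= 0:
            raise ValueError(f"non-positive mean for {keys}")
        rows.append((*keys, float(v.std(ddof=1) / mean)))
    return pd.DataFrame(rows, columns=group_cols + [region_col, "cv"])


def roi_median(image: np.ndarray, atlas: LabelVolume,
               regions: list[str] | None = None,
               value_kind: str = "fa_median", **meta) -> pd.DataFrame:
    """Per-region voxel median (even counts -> midpoint).

    Regions without labelled voxels get NaN and are flagged in the
    ``empty`` column.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != atlas.labels.shape:
        raise ValueError("image and atlas shapes differ")
    name_to_label = {v: k for k, v in atlas.lookup.items()}
    if regions is None:
        regions = [atlas.lookup[k] for k in sorted(atlas.lookup)]
    if not regions:
        raise ValueError("regions must be non-empty")
    unknown = [r for r in regions if r not in name_to_label]
    if unknown:
        raise ValueError(f"unknown region name(s): {unknown}")
    rows = []
    for r in regions:
        sel = atlas.labels == name_to_label[r]
        n = int(sel.sum())
        med = float(np.median(image[sel])) if n else np.nan
        rows.append((meta.get("subject_id"), meta.get("timepoint"), r, med,
                     value_kind, n == 0))
    return pd.DataFrame(rows, columns=["subject_id", "timepoint", "region",
                                       "value", "value_kind", "empty"])
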