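"""Voxel-wise permutation inference with TFCE and max-statistic FWE.

Threshold-free cluster enhancement integrates cluster support over all
heights:

    TFCE(v) = sum over h = dh, 2dh, ..., peak of  e(v, h)^E * h^H * dh

where ``e(v, h)`` is the voxel count of the connected suprathreshold
(>= h) component containing v.  Defaults H = 2, E = 0.5, 26-connectivity.
The negative tail is handled by transforming ``-values`` and negating.

Family-wise error correction uses the permutation distribution of the
maximum |TFCE| over the mask: corrected
``p(v) = (1 + #{max_perm >= TFCE_obs(v)}) / (1 + n_perm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "StatImage",
    "TfceConfig",
    "tfce",
    "PermutationFWE",
    "FWEResult",
]


@dataclass
class StatImage:
    """A 3D statistical map with a boolean mask."""

    values: np.ndarray
    mask: np.ndarray | None = None
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("stat image must be 3D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None) -> "StatImage":
        import nibabel as nib

        img = nib.load(str(path))
        vox = float(np.prod(img.header.get_zooms()[:3]))
        return cls(values=np.asanyarray(img.dataobj, dtype=float), mask=mask,
                   voxel_volume=vox)


@dataclass
class TfceConfig:
    """TFCE parameters.

    ``dh`` fixes the integration step explicitly; otherwise the step is
    ``peak / n_steps`` of each map being transformed.
    """

    height_power: float = 2.0
    extent_power: float = 0.5
    n_steps: int = 100
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.height_power <= 0 or self.extent_power <= 0:
            raise ValueError("height and extent powers must be > 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


def _tfce_one_sided(values: np.ndarray, mask: np.ndarray,
                    cfg: TfceConfig) -> np.ndarray:
    """TFCE of the positive tail of ``values``."""
    v = np.where(mask, values, 0.0)
    peak = v.max(initial=0.0)
    out = np.zeros_like(v)
    if peak <= 0:
        return out
    # crop to the positive support's bounding box: labeling cost then
    # scales with the active region, not the field of view
    pos = v > 0
    sl = ndimage.find_objects(pos.astype(np.int8), max_label=1)[0]
    vc = v[sl]
    oc = np.zeros_like(vc)
    dh = cfg.dh if cfg.dh is not None else peak / cfg.n_steps
    structure = cfg.structure()
    h = dh
    hp, ep = cfg.height_power, cfg.extent_power
    while h <= peak + 1e-12:
        supra = vc >= h
        if not supra.any():
            break
        lab, n = ndimage.label(supra, structure=structure)
        if n:
            counts = np.bincount(lab.ravel())
            counts[0] = 0
            oc += np.where(supra, counts[lab] ** ep * (h ** hp) * dh, 0.0)
        h += dh
    out[sl] = oc
    return out


def tfce(stat: StatImage | np.ndarray, cfg: TfceConfig | None = None,
         mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed 3D map.

    Positive and negative tails are enhanced separately (the negative tail
    by transforming the negated map) and recombined with their signs.
    """
    if cfg is None:
        cfg = TfceConfig()
    if isinstance(stat, StatImage):
        values, m = stat.values, stat.mask
    else:
        values = np.asarray(stat, dtype=float)
        m = np.ones(values.shape, dtype=bool) if mask is None else mask
    if not m.any():
        raise ValueError("mask is empty")
    pos = _tfce_one_sided(values, m, cfg)
    neg = _tfce_one_sided(-values, m, cfg)
    return pos - neg


def _t_map(images: np.ndarray, ga: np.ndarray, mask_flat: np.ndarray,
           ) -> np.ndarray:
    """Pooled two-sample t over the flattened mask (vectorised)."""
    xa = images[ga][:, mask_flat]
    xb = images[~ga][:, mask_flat]
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    sp2 = ((na - 1) * xa.var(axis=0, ddof=1)
           + (nb - 1) * xb.var(axis=0, ddof=1)) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0),
                     0.0)
    return t


@dataclass
class FWEResult:
    """Max-statistic FWE-corrected voxel-wise comparison."""

    p_corrected: np.ndarray  # 3D, 1.0 outside mask
    tfce_map: np.ndarray     # observed signed TFCE
    t_map: np.ndarray        # observed t map
    null_max: np.ndarray     # per-permutation max |TFCE|
    mask: np.ndarray
    n_permutations: int
    seed: int | None
    config: TfceConfig

    @property
    def min_p(self) -> float:
        return float(self.p_corrected[self.mask].min())

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_corrected < alpha) & self.mask

    def p_band_mask(self, lo: float = 0.05, hi: float = 0.5) -> np.ndarray:
        """Sub-threshold reporting band: lo < p < hi inside the mask."""
        p = self.p_corrected
        return (p > lo) & (p < hi) & self.mask


class PermutationFWE:
    """Two-group voxel-wise comparison with TFCE and FWE correction.

    Parameters
    ----------
    images
        Per-subject 3D maps, as an (n, X, Y, Z) array or list of
        :class:`StatImage` / arrays.
    labels
        Group label per subject (two distinct values).
    config
        :class:`TfceConfig`; defaults to H=2, E=0.5, 26-connectivity.
    mask
        Shared analysis mask (taken from the first StatImage if absent).
    """

    def __init__(self, images, labels, config: TfceConfig | None = None,
                 mask: np.ndarray | None = None):
        if isinstance(images, np.ndarray) and images.ndim == 4:
            stack = images.astype(float)
        else:
            arrs = []
            for im in images:
                if isinstance(im, StatImage):
                    if mask is None:
                        mask = im.mask
                    arrs.append(im.values)
                else:
                    arrs.append(np.asarray(im, dtype=float))
            stack = np.stack(arrs)
        self.shape = stack.shape[1:]
        self.mask = (np.ones(self.shape, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValueError("labels must take exactly two values")
        if min((labels == u).sum() for u in uniq) < 2:
            raise ValueError("each group needs >= 2 subjects")
        self.group_a = labels == uniq[0]
        self.images_flat = stack.reshape(stack.shape[0], -1)
        self.mask_flat = self.mask.ravel()
        self.config = config if config is not None else TfceConfig()

    def _tfce_of_labels(self, ga: np.ndarray) -> np.ndarray:
        t_flat = _t_map(self.images_flat, ga, self.mask_flat)
        t3 = np.zeros(self.shape)
        t3[self.mask] = t_flat
        return tfce(t3, self.config, mask=self.mask)

    def fit(self, n_permutations: int = 1000,
            seed: int | None = None) -> FWEResult:
        if n_permutations < 100:
            warnings.warn("n_permutations < 100 gives a coarse p-value",
                          stacklevel=2)
        obs_tfce = self._tfce_of_labels(self.group_a)
        obs_abs = np.abs(obs_tfce)
        rng = np.random.default_rng(seed)
        n = self.group_a.size
        na = int(self.group_a.sum())
        null_max = np.empty(n_permutations)
        for k in range(n_permutations):
            perm = rng.permutation(n)
            ga = np.zeros(n, dtype=bool)
            ga[perm[:na]] = True
            null_max[k] = np.abs(self._tfce_of_labels(ga)).max()
        exceed = (null_max[None, :] >= obs_abs[self.mask][:, None]).sum(axis=1)
        p = np.ones(self.shape)
        p[self.mask] = (1 + exceed) / (1 + n_permutations)
        t3 = np.zeros(self.shape)
        t3[self.mask] = _t_map(self.images_flat, self.group_a, self.mask_flat)
        return FWEResult(p_corrected=p, tfce_map=obs_tfce, t_map=t3,
                         null_max=null_max, mask=self.mask,
                         n_permutations=n_permutations, seed=seed,
                         config=self.config)
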