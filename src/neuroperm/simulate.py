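"""Synthetic cohorts with known statistical ground truth.

Emulates a longitudinal two-genotype, two-sex, two-timepoint mouse MRI
study: ROI BOLD time courses with modular correlation structure, regional
volume tables (72 atlas regions, log-normal with a configurable coefficient
of variation), paired white-matter FA tables with a developmental increment,
and small 3D stat images with an optional planted spherical signal.

Every generator is deterministic given ``SimulationConfig.seed``.  With
``genotype_edge_delta = 0`` (and zero planted image amplitude) the two
genotypes are exchangeable, so every downstream group test is a null
experiment — the basis of the calibration suites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .connectivity import TimecourseMatrix
from .parcellation import DEFAULT_NETWORKS, DEFAULT_ROI_NAMES

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "GENOTYPES",
    "SEXES",
    "TIMEPOINTS",
    "WM_REGIONS",
    "make_cohort",
    "build_target_correlation",
    "simulate_timecourses",
    "simulate_regional_volumes",
    "simulate_fa_table",
    "simulate_stat_images",
    "SimulatedImages",
]

GENOTYPES = ("wildtype", "knockout")
SEXES = ("F", "M")
TIMEPOINTS = ("adolescence", "adulthood")

#: White-matter regions for the FA table; the olfactory tract matures early
#: and receives no developmental increment.
WM_REGIONS = (
    "corpus callosum",
    "anterior commissure",
    "internal capsule",
    "optic tract",
    "cerebral peduncle",
    "fimbria",
    "external capsule",
    "hippocampal commissure",
    "fornix",
    "olfactory tract",
)
ZERO_DELTA_REGION = "olfactory tract"


@dataclass
class SubjectRecord:
    subject_id: str
    genotype: str
    sex: str
    litter_id: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Parameters
    ----------
    n_per_cell
        Subjects per genotype x sex cell (default 9, approximating the
        study scale of ~17-18 per sex per genotype halved).
    n_rois, roi_names
        Parcellation size (default 36: 18 per hemisphere) and labels.
    n_timepoints_scan
        Scan length T in samples (default 500).
    modules
        Mapping network name -> ROI list defining the modular correlation
        structure (defaults to the bundled DMN/salience/anxiety networks).
    r_within, r_between
        Target Pearson correlation inside / between modules.
    genotype_edge_delta, genotype_edges
        Additive correlation effect on a designated edge set in knockout
        sessions (default edge set: all within-DMN pairs).
    ar1_coef
        Temporal autocorrelation of the AR(1) noise model.
    developmental_delta_fa, fa_noise_sd
        FA increment adulthood - adolescence and measurement noise sd.
    volume_region_count, volume_cv
        Atlas regions for the volume table (default 72) and generating
        coefficient of variation (default 0.05, the observed ~4-5% range).
    sex_volume_effect, volume_growth
        Relative male volume excess in adolescence, and adolescence ->
        adulthood growth factor.
    image_shape, signal_amplitude, signal_radius, image_smoothing,
    mask_border
        Stat-image geometry: Gaussian-smoothed unit-variance noise, a
        spherical signal (amplitude in noise-sd units) added to knockout
        images, mask excluding a border.
    seed
        Master RNG seed; all generators are deterministic given it.
    """

    n_per_cell: int = 9
    n_rois: int = 36
    n_timepoints_scan: int = 500
    roi_names: list[str] | None = None
    modules: dict[str, list[str]] | None = None
    r_within: float = 0.6
    r_between: float = 0.2
    genotype_edge_delta: float = 0.0
    genotype_edges: list[tuple[str, str]] | None = None
    ar1_coef: float = 0.3
    developmental_delta_fa: float = 0.03
    fa_noise_sd: float = 0.01
    volume_region_count: int = 72
    volume_cv: float = 0.05
    sex_volume_effect: float = 0.03
    volume_growth: float = 0.08
    image_shape: tuple[int, int, int] = (16, 16, 16)
    signal_amplitude: float = 0.0
    signal_radius: float = 3.0
    image_smoothing: float = 1.0
    mask_border: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not (0 <= self.r_between <= self.r_within < 1):
            raise ValueError("need 0 <= r_between <= r_within < 1")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.developmental_delta_fa < 0:
            raise ValueError("developmental_delta_fa must be >= 0")
        if self.volume_region_count < 2:
            raise ValueError("volume_region_count must be >= 2")
        if self.roi_names is None:
            if self.n_rois == 36:
                self.roi_names = list(DEFAULT_ROI_NAMES)
            else:
                half = self.n_rois // 2
                if 2 * half != self.n_rois:
                    raise ValueError("n_rois must be even (unilateral pairs)")
                self.roi_names = [f"L region {i:02d}" for i in range(half)]
                self.roi_names += [f"R region {i:02d}" for i in range(half)]
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names must have n_rois entries")
        n_left = sum(1 for r in self.roi_names if r.startswith("L "))
        n_right = sum(1 for r in self.roi_names if r.startswith("R "))
        if not (n_left == n_right == self.n_rois // 2):
            raise ValueError("roi_names must be half left- and half "
                             "right-prefixed ('L '/'R ')")
        if self.modules is None:
            if self.n_rois == 36:
                self.modules = {k: list(v.rois)
                                for k, v in DEFAULT_NETWORKS.items()}
            else:
                self.modules = {}
        for name, rois in self.modules.items():
            missing = [r for r in rois if r not in self.roi_names]
            if missing:
                raise ValueError(f"module {name!r} has unknown ROIs {missing}")
        if self.genotype_edges is None:
            if "DMN" in self.modules:
                rois = self.modules["DMN"]
                self.genotype_edges = [
                    (rois[i], rois[j])
                    for i in range(len(rois)) for j in range(i + 1, len(rois))
                ]
            else:
                self.genotype_edges = []

    @property
    def n_subjects(self) -> int:
        return 2 * 2 * self.n_per_cell


def make_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Lay out the cohort: 2 genotypes x 2 sexes x n_per_cell subjects,
    each scanned at both timepoints.

    Litters are assigned round-robin over ``n_per_cell`` litters within each
    genotype, so every litter mixes genotypes (littermate design) whenever
    ``n_per_cell >= 1``.
    """
    n_litters = config.n_per_cell
    records = []
    for genotype in GENOTYPES:
        counter = 0
        for sex in SEXES:
            for i in range(config.n_per_cell):
                sid = f"sub-{genotype[:2]}-{sex}-{i + 1:02d}"
                litter = f"litter-{(counter % n_litters) + 1:02d}"
                counter += 1
                for tp in TIMEPOINTS:
                    records.append(SubjectRecord(sid, genotype, sex, litter, tp))
    return records


def _eigen_floor(c: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Repair a symmetric matrix to PD by flooring eigenvalues, then
    renormalise to unit diagonal.  Returns (matrix, repaired_flag)."""
    w, v = np.linalg.eigh(c)
    if w.min() > floor:
        return c, False
    w = np.maximum(w, floor)
    c2 = (v * w) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    c2 = (c2 + c2.T) / 2.0
    np.fill_diagonal(c2, 1.0)
    wmin = np.linalg.eigvalsh(c2).min()
    if wmin <= 0:
        raise ValueError(
            f"target correlation not positive definite after repair "
            f"(min eigenvalue {wmin:.3e})")
    return c2, True


def build_target_correlation(config: SimulationConfig,
                             knockout: bool = False,
                             ) -> tuple[np.ndarray, bool]:
    """Block target correlation: r_within inside any shared module,
    r_between elsewhere; knockouts add ``genotype_edge_delta`` on the
    designated edges.  Returns (matrix, repaired_flag)."""
    r = config.n_rois
    c = np.full((r, r), config.r_between)
    for rois in config.modules.values():
        idx = [config.roi_names.index(x) for x in rois]
        c[np.ix_(idx, idx)] = config.r_within
    if knockout and config.genotype_edge_delta != 0:
        for a, b in config.genotype_edges:
            i, j = config.roi_names.index(a), config.roi_names.index(b)
            c[i, j] += config.genotype_edge_delta
            c[j, i] = c[i, j]
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -0.999, 0.999)
    np.fill_diagonal(c, 1.0)
    return _eigen_floor(c)


def simulate_timecourses(config: SimulationConfig,
                         subjects: Sequence[SubjectRecord],
                         ) -> dict[tuple[str, str], TimecourseMatrix]:
    """Draw each subject-session's T x R BOLD time courses.

    Samples a zero-mean multivariate normal with the genotype's target
    correlation, then applies AR(1) filtering
    ``x_t = a x_{t-1} + sqrt(1 - a^2) e_t`` which adds temporal
    autocorrelation while preserving the stationary cross-correlation.
    """
    t = config.n_timepoints_scan
    if t < 50:
        raise ValueError("need T >= 50 samples")
    chol = {}
    for genotype in GENOTYPES:
        c, _ = build_target_correlation(config,
                                        knockout=(genotype == "knockout"))
        chol[genotype] = np.linalg.cholesky(c)
    rng = np.random.default_rng(config.seed)
    a = config.ar1_coef
    scale = np.sqrt(1.0 - a * a)
    out: dict[tuple[str, str], TimecourseMatrix] = {}
    # deterministic session order: input order of (subject, timepoint) pairs
    for rec in subjects:
        key = (rec.subject_id, rec.timepoint)
        if key in out:
            raise ValueError(f"duplicate session {key}")
        e = rng.standard_normal((t, config.n_rois)) @ chol[rec.genotype].T
        if a > 0:
            x = np.empty_like(e)
            x[0] = e[0]
            for k in range(1, t):
                x[k] = a * x[k - 1] + scale * e[k]
        else:
            x = e
        out[key] = TimecourseMatrix(values=x, roi_names=list(config.roi_names),
                                    subject_id=rec.subject_id,
                                    timepoint=rec.timepoint)
    return out


def _subject_frame(subjects: Sequence[SubjectRecord]):
    import pandas as pd

    return pd.DataFrame(
        [(s.subject_id, s.genotype, s.sex, s.litter_id, s.timepoint)
         for s in subjects],
        columns=["subject_id", "genotype", "sex", "litter_id", "timepoint"])


def simulate_regional_volumes(config: SimulationConfig,
                              subjects: Sequence[SubjectRecord]):
    """Log-normal regional volume table for ``volume_region_count`` regions.

    The generating distribution has exact coefficient of variation
    ``volume_cv`` per region (``volume_cv = 0`` gives every subject the
    region mean exactly).  Males are ``sex_volume_effect`` larger in
    adolescence; adulthood volumes grow by ``volume_growth``.  There is no
    genotype effect: volumes are a null channel.
    """
    import pandas as pd

    n_reg = config.volume_region_count
    regions = [f"region {i + 1:02d}" for i in range(n_reg)]
    # deterministic spread of region sizes, ~0.5-30 mm^3
    mu = np.geomspace(0.5, 30.0, n_reg)
    cv = config.volume_cv
    sigma = np.sqrt(np.log1p(cv * cv))
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for rec in subjects:
        eff = 1.0
        if rec.sex == "M" and rec.timepoint == "adolescence":
            eff *= 1.0 + config.sex_volume_effect
        if rec.timepoint == "adulthood":
            eff *= 1.0 + config.volume_growth
        z = rng.standard_normal(n_reg)
        vals = mu * eff * np.exp(sigma * z - sigma * sigma / 2.0)
        for r, v in zip(regions, vals):
            rows.append((rec.subject_id, rec.genotype, rec.sex, rec.litter_id,
                         rec.timepoint, r, v, "absolute_mm3"))
    return pd.DataFrame(rows, columns=[
        "subject_id", "genotype", "sex", "litter_id", "timepoint", "region",
        "value", "value_kind"])


def simulate_fa_table(config: SimulationConfig,
                      subjects: Sequence[SubjectRecord]):
    """Paired white-matter FA medians at both timepoints.

    Adulthood = adolescence + ``developmental_delta_fa`` + noise for every
    region except the olfactory tract (zero increment); values are clamped
    to the FA range [0, 1].
    """
    import pandas as pd

    regions = list(WM_REGIONS)
    base = np.linspace(0.30, 0.60, len(regions))
    delta = np.full(len(regions), config.developmental_delta_fa)
    delta[regions.index(ZERO_DELTA_REGION)] = 0.0
    rng = np.random.default_rng(config.seed + 2)
    sids = sorted({s.subject_id for s in subjects})
    meta = {s.subject_id: s for s in subjects}
    rows = []
    for sid in sids:
        rec = meta[sid]
        adol = base + rng.normal(0.0, config.fa_noise_sd, len(regions))
        adult = adol + delta + rng.normal(0.0, config.fa_noise_sd,
                                          len(regions))
        for tp, vals in (("adolescence", adol), ("adulthood", adult)):
            vals = np.clip(vals, 0.0, 1.0)
            for r, v in zip(regions, vals):
                rows.append((sid, rec.genotype, rec.sex, rec.litter_id, tp,
                             r, v, "fa_median"))
    return pd.DataFrame(rows, columns=[
        "subject_id", "genotype", "sex", "litter_id", "timepoint", "region",
        "value", "value_kind"])


@dataclass
class SimulatedImages:
    """Per-subject 3D stat images with group labels and a shared mask."""

    images: np.ndarray  # (n_subjects, X, Y, Z)
    labels: np.ndarray  # 0 = wildtype, 1 = knockout (signal group)
    mask: np.ndarray    # 3D boolean, border excluded
    signal_mask: np.ndarray  # 3D boolean: the planted sphere


def simulate_stat_images(config: SimulationConfig,
                         n_per_group: int | None = None) -> SimulatedImages:
    """Smooth Gaussian noise fields with an optional planted sphere.

    Noise is white Gaussian smoothed with a ``image_smoothing``-sigma kernel
    and rescaled to unit voxel variance.  Knockout images receive an added
    sphere of radius ``signal_radius`` and amplitude ``signal_amplitude``
    (noise-sd units) at the volume centre.  The mask excludes a
    ``mask_border``-voxel border.
    """
    from scipy.ndimage import gaussian_filter

    shape = tuple(config.image_shape)
    if min(shape) < 8:
        raise ValueError("image shape must be >= 8 in every dimension")
    if n_per_group is None:
        n_per_group = 2 * config.n_per_cell
    rng = np.random.default_rng(config.seed + 3)
    labels = np.array([0] * n_per_group + [1] * n_per_group)

    centre = np.array([(s - 1) / 2.0 for s in shape])
    grid = np.indices(shape).astype(float)
    dist2 = sum((grid[d] - centre[d]) ** 2 for d in range(3))
    sphere = dist2 <= config.signal_radius ** 2

    b = config.mask_border
    mask = np.zeros(shape, dtype=bool)
    mask[b:shape[0] - b, b:shape[1] - b, b:shape[2] - b] = True

    imgs = np.empty((labels.size,) + shape)
    for i, lab in enumerate(labels):
        noise = gaussian_filter(rng.standard_normal(shape),
                                config.image_smoothing)
        noise /= noise.std()
        if lab == 1 and config.signal_amplitude != 0:
            noise = noise + config.signal_amplitude * sphere
        imgs[i] = noise
    return SimulatedImages(images=imgs, labels=labels, mask=mask,
                           signal_mask=sphere & mask)
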