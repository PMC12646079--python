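# Methods

This note documents the statistical procedures implemented in `neuroperm`,
the synthetic cohort generator that exercises them, the numerical choices
made where a convention had to be fixed, and the limits of what the
package's own validation can show.

## Study design being modelled

The package targets a longitudinal preclinical MRI design: two genotypes
(wild-type and knockout littermates), two sexes, each animal scanned at
two timepoints (adolescence and adulthood). Mixed-genotype litters are the
experimental backbone: the simulated cohort assigns animals of both
genotypes to every litter round-robin, mirroring a littermate-control
breeding scheme. The default cohort scale is 9 animals per genotype × sex
cell (36 animals, 72 scan sessions), in the range of a well-powered mouse
imaging study.

## Functional connectivity

Connectivity between two regional BOLD time courses is the Pearson
correlation, Fisher z-transformed. |r| is clipped to `1 − 1e−7` before
`atanh` so degenerate perfectly-correlated pairs map to a large finite
value (≈8.4) rather than infinity; the diagonal is identically zero.

Proportional thresholding ranks the `E = R(R−1)/2` upper-triangle edges by
**signed** z (largest first) and keeps the top `round(s·E)`, with
half-away-from-zero rounding (5% of 630 edges → 32) and ties at the cut
broken by row-major edge order. Signed ranking is the default because the
procedure targets the *strongest* connections and typical cohort mean FC
is positive; ranking by |z| is available via `ranking="absolute"`. With a
fixed tie-break the retained edge sets are nested across sparsity levels,
which makes mean non-zero FC non-increasing, and both binary graph metrics
non-decreasing, in sparsity — properties the test suite asserts.

## Graph metrics

Global efficiency and average clustering are computed on the **binarized**
thresholded graph: efficiency as the mean inverse unweighted shortest-path
length over ordered pairs (disconnected pairs contribute 0 — the relevant
convention at 5% sparsity, where graphs are usually fragmented), and
clustering as the mean over nodes of `2t_i / (k_i(k_i−1))` with `C_i = 0`
for degree < 2. Shortest paths use compiled graph routines
(`scipy.sparse.csgraph`); triangles come from the `A³` diagonal. Both are
validated against exhaustive pure-Python BFS / triangle-enumeration
oracles on every graph with ≤ 6 nodes, and against networkx on random
graphs.

Subnetwork weighted efficiency follows the small-network convention:
extract the subnetwork's z submatrix, min-max normalise its off-diagonal
entries to [0, 1] per subject (per-subject normalisation makes each
subject's value scale-free), set edge lengths to 1/weight (zero weight =
no edge), and average inverse weighted shortest-path distances. A constant
submatrix makes the normalisation degenerate and raises an error rather
than guessing.

Node strength of a seed region is the mean **absolute** z to all other
regions, unthresholded. The bundled seed list holds 20 anxiety/fear-related
regions (10 per hemisphere); default-mode (bilateral prefrontal,
cingulate, dorsal hippocampus) and salience (bilateral cingulate,
amygdala, striatum) networks are bundled as fixed ROI subsets of the
36-region parcellation.

## Group inference

**AUC permutation test.** Each subject's metric-vs-sparsity curve is
reduced to its trapezoidal AUC over sparsity in percentage points; the
group difference in mean AUC is referenced to a group-label permutation
null. P-values use the add-one estimator `(1+k)/(1+N)`, which is never
zero, has resolution `1/(N+1)`, and counts ties against the observed
statistic (conservative). For ≤ 8 subjects total the test can enumerate
all label splits exactly (`fit(exact=True)`), and the Monte-Carlo p is
tested to converge to that enumeration.

**Edge-wise tests.** Student (pooled-variance) t per upper-triangle edge —
Welch is deliberately not the default, matching the pooled convention for
balanced designs — with BH-FDR over exactly the 630-edge family. Edges
with zero pooled variance get t = 0 and are flagged.

**NBS.** The t matrix is thresholded at `|t| ≥ τ`; connected components of
the suprathreshold adjacency are found by breadth-first search (union-find
in the vectorised permutation path), components with ≥ 2 nodes are
retained, and component size is measured in **edges** (a node-count mode
exists behind `size_measure="nodes"`). The null shuffles group labels,
recording the maximal component size; a component's p is the proportion of
null maxima at least as large (ties count against the component).
Permutations exchange labels freely, without stratification by sex or
litter, matching a sexes-combined analysis; the permuted t statistics are
computed in vectorised blocks so 500-permutation runs on 36-region data
take milliseconds.

The primary threshold τ is an analyst choice, as it is in any NBS
analysis. At τ = 2 with df ≈ 58, about 5% of the 630 edges are
suprathreshold under the null — a mean degree of ~1.75, which is above the
random-graph percolation threshold, so the null maximal component is a
giant component of ~25–30 edges. τ = 2 is therefore appropriate for
detecting broad, distributed effects, while focal effects (e.g. a planted
5-node module whose edges carry |t| ≈ 6) are far better resolved at τ = 3,
where the null graph is subcritical. The validation suite calibrates the
null at τ = 2 and demonstrates recovery of the planted module at τ = 3 for
exactly this reason.

**Longitudinal change.** Per region (or per sparsity level),
adulthood − adolescence differences across matched subjects are tested
with a two-sided one-sample t against zero and BH-corrected within the
declared family; subjects missing either timepoint are dropped and
counted.

**Mixed ANOVA.** Classical split-plot sums of squares for one
between-subjects factor (genotype) and one within-subjects factor
(region): the between effect is tested against subjects-within-groups,
the within and interaction effects against the subject × region residual.
Reports F, df, p and partial η² per effect. Sphericity correction is off
by default (matching the plain mixed-ANOVA convention); a
Greenhouse–Geisser epsilon from the double-centred covariance of the
within-subject measures can be applied via
`fit(sphericity_correction=True)`. The implementation was verified to
agree with pingouin's `mixed_anova` to well below 1e-8 on random balanced
data, and that agreement is a permanent test.

**Power.** The two-sample t power function uses the noncentral t
distribution with `df = n1+n2−2` and noncentrality `d·√(n1·n2/(n1+n2))`;
`min_detectable_d` inverts it by bisection to 1e−6. At n = 34 per group,
α = 0.05 and 80% power this gives d = 0.690.

## Voxel statistics

TFCE integrates `e(v,h)^E · h^H · dh` over thresholds `h = dh, 2dh, …,
peak`, where `e(v,h)` is the voxel count of the connected component (26-
connectivity by default; 6 and 18 available) containing v at threshold h.
Defaults H = 2, E = 0.5 are the established defaults of the standard
implementation. The step is `dh = peak/n_steps` with `n_steps = 100` by
default; the flat-plateau closed form `e^E·h^(H+1)/(H+1)` is matched
within 1% and convergence was checked by step-halving. The negative tail
is enhanced by transforming the negated map and recombining with sign.
Labeling is restricted to the positive support's bounding box, which is
what makes dense permutation loops affordable on a single CPU.

FWE correction is the max-statistic method: each label shuffle records the
maximum |TFCE| over the mask, and a voxel's corrected p is the add-one
proportion of null maxima at least as large as its observed |TFCE|. This
makes corrected p monotone in observed TFCE by construction, and identical
groups give p = 1 everywhere under the tie convention.

## Morphometry

Region volume = Σ J(v) × voxel volume over the parcel; total brain volume
sums over the brain mask; relative volume = region/total (invariant to
global scaling of J, mirroring the absolute/relative split of
deformation-based volumetry). Jacobian maps are inputs — registration and
deformation-field generation are upstream of this package — and
log-transformation of Jacobians belongs to the voxel-statistics pathway,
not the ROI sums. The CV audit uses sample sd (ddof = 1), the conventional
estimator at n ≈ 35 per group. ROI medians use the midpoint rule for even
counts; empty parcels are flagged, not silently dropped.

## The synthetic generator

`SimulationConfig` fixes the study conditions. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_per_cell` | 9 | animals per genotype × sex cell |
| `n_rois` | 36 | unilateral regions, 18 per hemisphere |
| `n_timepoints_scan` | 500 | BOLD samples per session |
| `r_within` / `r_between` | 0.6 / 0.2 | modular target correlation |
| `ar1_coef` | 0.3 | temporal autocorrelation |
| `genotype_edge_delta` | 0 | knockout edge effect (0 = null study) |
| `developmental_delta_fa` | 0.03 | FA increment, adulthood − adolescence |
| `fa_noise_sd` | 0.01 | FA measurement noise |
| `volume_region_count` | 72 | atlas regions in the volume table |
| `volume_cv` | 0.05 | generating CV (the observed ~4–5% range) |
| `image_shape` | 16³ | stat-image geometry |

Time courses are zero-mean multivariate normal draws with a block target
correlation (`r_within` inside any shared network module, `r_between`
elsewhere; knockout sessions add `genotype_edge_delta` to a designated
edge set, by default all within-DMN pairs), passed through an AR(1) filter
`x_t = a·x_{t−1} + √(1−a²)·e_t` that adds temporal autocorrelation while
preserving the stationary cross-correlation. A 500-sample scan is long
enough for stable 36×36 correlation estimates while staying fast; AR(1) is
the minimal temporal-noise model. Non-positive-definite targets are
repaired by eigenvalue flooring at 1e−6 with renormalisation to unit
diagonal, and the repair is reported.

Volumes are log-normal with the generating CV exact by construction
(CV = 0 collapses to the region mean); a male volume excess applies in
adolescence only and a growth factor separates the timepoints, so the sex
difference fades by adulthood while genotype stays null. FA tables are
paired within subject with one early-maturing region (olfactory-tract
analogue) receiving a zero increment; values are clamped to [0, 1]. Stat
images are Gaussian-smoothed unit-variance noise fields with an optional
planted central sphere (amplitude in noise-sd units) in the knockout
group and a mask excluding a 2-voxel border.

With `genotype_edge_delta = 0` and zero image amplitude the genotypes are
exchangeable by construction, so every downstream group test is a null
experiment — that is the basis of the calibration suite.

What the generator does **not** emulate: physiological and motion noise,
scanner drift, spatially varying smoothness, hemispheric asymmetries,
inter-litter variance components, registration error, or any behavioural
channel. Passing tests demonstrate that the inferential machinery is
calibrated and sensitive under a clean, exchangeable model — not that any
particular real dataset satisfies those assumptions.

## Validation problem sizes

The calibration suite measures empirical type-I error at nominal α = 0.05
against its 95% binomial band: 1000 null datasets for the AUC test, 500
for NBS (n = 10/group, 36 regions) and 400 for TFCE/FWE (8³ images,
n = 6/group, 20-step TFCE integration — the validity of a max-statistic
null does not depend on the integration step), each at 500 permutations.
Recovery uses an edge shift of 1.5 pooled-sd on a 5-node module at
n = 30/group (30 replicates; edge-wise FDR and NBS at τ = 3), and a 5σ
sphere of radius 3 on 16³ images at n = 10/group with 500 permutations
(10 replicates). These sizes keep the full validation run in the
minutes range on one CPU.

## Known limitations

- Only two-group contrasts are implemented for NBS and the voxel engine;
  no covariates, exchangeability blocks, or general linear model designs.
- The mixed ANOVA assumes a complete design and, beyond the optional
  Greenhouse–Geisser correction, does not model heterogeneous covariance.
- No mixed-effects (random-slope) longitudinal models; change is analysed
  by paired differencing.
- Permutation p-values inherit `1/(N+1)` resolution; sub-resolution
  significance claims need more permutations.
- The seed-to-voxel map is a per-subject transform; its group stage is
  the generic voxel engine, with no seed-family multiplicity correction.
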