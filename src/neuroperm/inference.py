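"""Group-level inference: AUC permutation tests, edge-wise FDR, the
network-based statistic, longitudinal change, mixed ANOVA, Kruskal-Wallis
and power calculations.

The stochastic procedures follow the statsmodels convention of a model
object constructed from data whose :meth:`fit` returns a results object
carrying estimates, p-values, the permutation null and the seed used.

Permutation p-values use the add-one estimator ``(1 + k) / (1 + N)`` where
``k`` counts permuted statistics at least as extreme as the observed one;
ties count against the observed statistic.  This keeps p-values in
``(0, 1]`` with resolution ``1/(N + 1)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .connectivity import FcMatrix
from .graphs import MetricCurve

__all__ = [
    "auc",
    "benjamini_hochberg",
    "kruskal_wallis",
    "min_detectable_d",
    "two_sample_power",
    "AUCPermutationTest",
    "AUCTestResult",
    "edgewise_ttests",
    "EdgeStats",
    "NetworkBasedStatistic",
    "NBSResult",
    "longitudinal_change",
    "ChangeResult",
    "MixedANOVA",
    "MixedANOVAResult",
]


# ---------------------------------------------------------------------------
# curve summaries

def auc(curve: MetricCurve | tuple[Sequence[float], Sequence[float]]) -> float:
    """Trapezoidal area under a metric-vs-sparsity curve.

    Sparsity is expressed in percentage points, so a constant 0.5 curve over
    the 5-50% grid integrates to 0.5 * 45 = 22.5.
    """
    if isinstance(curve, MetricCurve):
        x = np.asarray(curve.sparsity_levels, dtype=float)
        y = curve.values
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    if x.size < 2:
        raise ValueError("AUC needs at least 2 sparsity levels")
    return float(np.trapezoid(y, x))


def _curve_aucs(curves: Iterable[MetricCurve | tuple]) -> np.ndarray:
    return np.array([auc(c) for c in curves], dtype=float)


# ---------------------------------------------------------------------------
# AUC permutation test

@dataclass
class AUCTestResult:
    """Two-group AUC permutation test result."""

    metric: str | None
    group_means: tuple[float, float]
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metric": [self.metric],
            "mean_A": [self.group_means[0]],
            "mean_B": [self.group_means[1]],
            "diff": [self.observed_diff],
            "p_value": [self.p_value],
            "n_permutations": [self.n_permutations],
            "exact": [self.exact],
        })


class AUCPermutationTest:
    """Two-sided permutation test on the difference of group mean AUCs.

    Parameters
    ----------
    curves_a, curves_b
        Per-subject :class:`~neuroperm.graphs.MetricCurve` objects (or
        precomputed AUC scalars) for the two groups.
    metric
        Optional metric name carried into the result.
    """

    def __init__(self, curves_a, curves_b, metric: str | None = None):
        curves_a, curves_b = list(curves_a), list(curves_b)
        self.auc_a = _to_aucs(curves_a)
        self.auc_b = _to_aucs(curves_b)
        if self.auc_a.size < 2 or self.auc_b.size < 2:
            raise ValueError("each group needs >= 2 subjects")
        if metric is None and curves_a and isinstance(curves_a[0], MetricCurve):
            metric = curves_a[0].metric
        self.metric = metric

    def fit(self, n_permutations: int = 10_000, seed: int | None = None,
            exact: bool = False) -> AUCTestResult:
        """Run the permutation test.

        With ``exact=True`` (feasible for small groups) all label
        assignments are enumerated instead of Monte-Carlo sampling.
        """
        a, b = self.auc_a, self.auc_b
        na, nb = a.size, b.size
        obs = a.mean() - b.mean()
        pooled = np.concatenate([a, b])
        if exact:
            total = pooled.sum()
            count = 0
            nsplit = 0
            for idx in itertools.combinations(range(na + nb), na):
                sa = pooled[list(idx)].sum()
                d = sa / na - (total - sa) / nb
                if abs(d) >= abs(obs) - 1e-12:
                    count += 1
                nsplit += 1
            # the identity assignment is one of the enumerated splits
            p = count / nsplit
            return AUCTestResult(self.metric, (a.mean(), b.mean()),
                                 float(obs), float(p), nsplit, seed,
                                 exact=True)
        if n_permutations < 100:
            warnings.warn("n_permutations < 100 gives a coarse p-value",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            d = perm[:na].mean() - perm[na:].mean()
            if abs(d) >= abs(obs) - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_permutations)
        return AUCTestResult(self.metric, (float(a.mean()), float(b.mean())),
                             float(obs), float(p), n_permutations, seed)


def _to_aucs(curves: list) -> np.ndarray:
    """Accept per-subject MetricCurves or precomputed AUC scalars."""
    if curves and isinstance(curves[0], (MetricCurve, tuple)):
        return _curve_aucs(curves)
    return np.asarray(curves, dtype=float)


def auc_permutation_test(curves_a, curves_b, n_permutations: int = 10_000,
                         seed: int | None = None,
                         exact: bool = False) -> AUCTestResult:
    """Functional wrapper around :class:`AUCPermutationTest`."""
    return AUCPermutationTest(curves_a, curves_b).fit(
        n_permutations=n_permutations, seed=seed, exact=exact)


# ---------------------------------------------------------------------------
# edge-wise t-tests and BH-FDR

@dataclass
class EdgeStats:
    """Edge-wise two-sample t statistics with BH-adjusted q values.

    Matrices are symmetric with NaN diagonals; the BH family is the set of
    upper-triangle edges (630 for a 36-ROI parcellation).
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    roi_names: list[str]
    n_zero_variance: int = 0

    def significant_edges(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.t.shape[0], k=1)
        out = []
        for i, j in zip(*iu):
            if self.q[i, j] < alpha:
                out.append((self.roi_names[i], self.roi_names[j]))
        return out


def _stack_upper(matrices: Sequence[FcMatrix | np.ndarray]) -> tuple[np.ndarray, int, list[str]]:
    first = matrices[0]
    if isinstance(first, FcMatrix):
        r = first.n_rois
        names = list(first.roi_names)
        arrs = [m.z for m in matrices]
    else:
        r = np.asarray(first).shape[0]
        names = [f"roi{i}" for i in range(r)]
        arrs = [np.asarray(m) for m in matrices]
    iu = np.triu_indices(r, k=1)
    x = np.stack([a[iu] for a in arrs])
    return x, r, names


def _pooled_t(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Vectorised pooled-variance two-sample t along axis 0."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va = xa.var(axis=0, ddof=1)
    vb = xb.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0),
                     0.0)
    return t


def edgewise_ttests(group_a: Sequence[FcMatrix | np.ndarray],
                    group_b: Sequence[FcMatrix | np.ndarray]) -> EdgeStats:
    """Student (pooled-variance) t test per upper-triangle edge, BH over
    the edge family.

    Edges with zero pooled variance get t = 0 (counted in
    ``n_zero_variance``).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 subjects")
    xa, r, names = _stack_upper(group_a)
    xb, r2, _ = _stack_upper(group_b)
    if r != r2:
        raise ValueError("group matrices have different sizes")
    df = xa.shape[0] + xb.shape[0] - 2
    t = _pooled_t(xa, xb)
    n_zero = int(np.sum((xa.var(axis=0) == 0) & (xb.var(axis=0) == 0)
                        & (xa.mean(axis=0) == xb.mean(axis=0))))
    p = 2 * stats.t.sf(np.abs(t), df)
    q = benjamini_hochberg(p)
    iu = np.triu_indices(r, k=1)

    def mirror(vec):
        m = np.full((r, r), np.nan)
        m[iu] = vec
        m.T[iu] = vec
        return m

    return EdgeStats(mirror(t), mirror(p), mirror(q), names,
                     n_zero_variance=n_zero)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


# ---------------------------------------------------------------------------
# network-based statistic

class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def _components_from_edges(edge_nodes: np.ndarray, n_nodes: int,
                           ) -> list[tuple[frozenset, int]]:
    """Connected components (node set, edge count) from an edge list;
    only components spanning >= 2 nodes are returned."""
    uf = _UnionFind(n_nodes)
    for i, j in edge_nodes:
        uf.union(int(i), int(j))
    edge_count: dict[int, int] = {}
    nodes: dict[int, set] = {}
    for i, j in edge_nodes:
        r = uf.find(int(i))
        edge_count[r] = edge_count.get(r, 0) + 1
        nodes.setdefault(r, set()).update((int(i), int(j)))
    return [(frozenset(v), edge_count[k]) for k, v in nodes.items()]


def _max_component_edges(edge_nodes: np.ndarray, n_nodes: int) -> int:
    comps = _components_from_edges(edge_nodes, n_nodes)
    return max((e for _, e in comps), default=0)


@dataclass
class NBSResult:
    """Network-based statistic result.

    ``components`` lists (ROI-name set, edge count) for every retained
    suprathreshold component (>= 2 nodes); ``p_values`` gives, per
    component, the proportion of permutation maximal component sizes at
    least as large (ties counted, add-one estimator).
    """

    threshold: float
    components: list[tuple[frozenset, int]]
    max_component_edges: int
    null_max_sizes: np.ndarray
    p_values: np.ndarray
    seed: int | None
    size_measure: str = "edges"

    @property
    def empty(self) -> bool:
        return len(self.components) == 0

    @property
    def min_p(self) -> float:
        return float(self.p_values.min()) if not self.empty else float("nan")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": [sorted(c) for c, _ in self.components],
            "n_nodes": [len(c) for c, _ in self.components],
            "n_edges": [e for _, e in self.components],
            "p_value": list(self.p_values),
        })


class NetworkBasedStatistic:
    """NBS: family-wise inference on suprathreshold connected components.

    The edge-wise pooled t matrix is thresholded at ``|t| >= threshold``;
    connected components of the resulting adjacency are measured in edges
    (the ``size_measure='nodes'`` flag counts nodes instead).  The null
    distribution of the maximal component size is built by shuffling group
    labels across subjects.

    Parameters
    ----------
    matrices
        All subjects' FC matrices (both groups).
    labels
        Group label per subject (two distinct values).
    threshold
        |t| cutoff (> 0), default 2.
    """

    def __init__(self, matrices: Sequence[FcMatrix | np.ndarray],
                 labels: Sequence, threshold: float = 2.0,
                 size_measure: str = "edges"):
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        if size_measure not in ("edges", "nodes"):
            raise ValueError("size_measure must be 'edges' or 'nodes'")
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValueError("labels must take exactly two values")
        if min((labels == u).sum() for u in uniq) < 2:
            raise ValueError("each group needs >= 2 subjects")
        self.x, self.r, self.roi_names = _stack_upper(list(matrices))
        self.group_a = labels == uniq[0]
        self.threshold = float(threshold)
        self.size_measure = size_measure
        self.iu = np.triu_indices(self.r, k=1)
        self.edge_nodes = np.column_stack(self.iu)

    def _component_size(self, comps) -> list[int]:
        if self.size_measure == "edges":
            return [e for _, e in comps]
        return [len(nset) for nset, _ in comps]

    def _supra_edges(self, ga: np.ndarray) -> np.ndarray:
        t = _pooled_t(self.x[ga], self.x[~ga])
        return self.edge_nodes[np.abs(t) >= self.threshold]

    def _null_max_sizes(self, n_permutations: int,
                        rng: np.random.Generator) -> np.ndarray:
        """Null maximal component sizes, with the permuted t statistics
        computed in vectorised blocks."""
        x = self.x
        n = x.shape[0]
        na = int(self.group_a.sum())
        nb = n - na
        x2 = x * x
        tot1 = x.sum(axis=0)
        tot2 = x2.sum(axis=0)
        df = n - 2
        null_max = np.empty(n_permutations, dtype=int)
        block = 256
        done = 0
        while done < n_permutations:
            b = min(block, n_permutations - done)
            sel = np.zeros((b, n))
            for r in range(b):
                sel[r, rng.permutation(n)[:na]] = 1.0
            s1a = sel @ x
            s2a = sel @ x2
            ma = s1a / na
            mb = (tot1 - s1a) / nb
            va = (s2a - na * ma * ma) / (na - 1)
            vb = ((tot2 - s2a) - nb * mb * mb) / (nb - 1)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / df
            denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / na + 1.0 / nb))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(denom > 0, (ma - mb) / np.where(denom > 0,
                                                             denom, 1.0), 0.0)
            supra = np.abs(t) >= self.threshold
            for r in range(b):
                en = self.edge_nodes[supra[r]]
                pc = _components_from_edges(en, self.r)
                null_max[done + r] = max(self._component_size(pc), default=0)
            done += b
        return null_max

    def fit(self, n_permutations: int = 10_000,
            seed: int | None = None) -> NBSResult:
        obs_edges = self._supra_edges(self.group_a)
        comps = _components_from_edges(obs_edges, self.r)
        named = [(frozenset(self.roi_names[i] for i in nset), e)
                 for nset, e in comps]
        sizes = self._component_size(comps)
        rng = np.random.default_rng(seed)
        null_max = self._null_max_sizes(n_permutations, rng)
        if not comps:
            warnings.warn("no suprathreshold edges; NBS result is empty",
                          stacklevel=2)
            pvals = np.array([])
        else:
            pvals = np.array([
                (1 + np.sum(null_max >= s)) / (1 + n_permutations)
                for s in sizes
            ])
        max_edges = max((e for _, e in comps), default=0)
        return NBSResult(self.threshold, named, max_edges, null_max, pvals,
                         seed, size_measure=self.size_measure)


# ---------------------------------------------------------------------------
# longitudinal change

@dataclass
class ChangeResult:
    """Per-unit adulthood - adolescence change with one-sample t and BH."""

    table: pd.DataFrame  # unit, delta_mean, t_stat, p, q, n
    unit: str
    n_dropped: int = 0

    def summary(self) -> pd.DataFrame:
        return self.table


def longitudinal_change(table: pd.DataFrame, value_col: str = "value",
                        unit_col: str = "region",
                        subject_col: str = "subject_id",
                        time_col: str = "timepoint",
                        t1: str = "adolescence",
                        t2: str = "adulthood") -> ChangeResult:
    """Test per-unit change t2 - t1 against zero across matched subjects.

    Subjects missing either timepoint are dropped (their count is
    reported); the two-sided one-sample t p-values are BH-corrected within
    the unit family.  Units with zero change variance get NaN p/q.
    """
    wide = table.pivot_table(index=[subject_col, unit_col], columns=time_col,
                             values=value_col, aggfunc="first")
    if t1 not in wide.columns or t2 not in wide.columns:
        raise ValueError(f"timepoints {t1!r}/{t2!r} not both present")
    have_both = wide[t1].notna() & wide[t2].notna()
    per_subj = have_both.groupby(level=0).all()
    matched = per_subj[per_subj].index
    n_dropped = int((~per_subj).sum())
    wide = wide.loc[wide.index.get_level_values(0).isin(matched)]
    delta = (wide[t2] - wide[t1]).rename("delta")
    rows = []
    for unit, vals in delta.groupby(level=1, sort=False):
        v = vals.to_numpy()
        n = v.size
        mean = float(v.mean())
        if n < 2 or v.std(ddof=1) == 0:
            t_stat, p = (0.0, np.nan) if mean == 0 else (np.nan, np.nan)
        else:
            t_stat, p = stats.ttest_1samp(v, 0.0)
        rows.append((unit, mean, float(t_stat), p, n))
    out = pd.DataFrame(rows, columns=[unit_col, "delta_mean", "t_stat", "p",
                                      "n"])
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        q[valid.to_numpy()] = benjamini_hochberg(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    return ChangeResult(table=out, unit=unit_col, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# mixed ANOVA

@dataclass
class MixedANOVAResult:
    """Split-plot (mixed-design) ANOVA results.

    ``effects`` maps 'between' / 'within' / 'interaction' to dicts with
    F, df1, df2, p and partial eta squared (np2).
    """

    effects: dict[str, dict[str, float]]
    between: str
    within: str
    sphericity_corrected: bool = False
    gg_epsilon: float | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append((name, e["F"], e["df1"], e["df2"], e["p"], e["np2"]))
        return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p",
                                           "np2"])


class MixedANOVA:
    """Two-way mixed ANOVA: one between-subjects and one within-subjects
    factor (e.g. genotype x region), classical split-plot sums of squares.

    The design must be complete: every subject measured at every within
    level.  Greenhouse-Geisser correction of the within/interaction tests
    is available via ``fit(sphericity_correction=True)``.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within: str,
                 between: str, subject: str):
        piv = data.pivot_table(index=[between, subject], columns=within,
                               values=dv, aggfunc="first")
        if piv.isna().any().any():
            missing = piv.isna().sum().sum()
            raise ValueError(f"incomplete design: {int(missing)} missing "
                             "cell(s)")
        self.x = piv.to_numpy(dtype=float)
        self.groups = piv.index.get_level_values(0).to_numpy()
        self.within_levels = list(piv.columns)
        self.between = between
        self.within = within

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str, within: str,
                       between: str, subject: str) -> "MixedANOVA":
        return cls(data, dv, within, between, subject)

    def fit(self, sphericity_correction: bool = False) -> MixedANOVAResult:
        x = self.x
        groups = self.groups
        n_total, b = x.shape
        uniq = pd.unique(groups)
        a = uniq.size
        grand = x.mean()
        subj_means = x.mean(axis=1)
        level_means = x.mean(axis=0)
        ss_a = ss_subj = ss_ab = ss_err = 0.0
        for g in uniq:
            sel = groups == g
            ng = int(sel.sum())
            mg = x[sel].mean()
            ss_a += b * ng * (mg - grand) ** 2
            ss_subj += b * float(((subj_means[sel] - mg) ** 2).sum())
            mgj = x[sel].mean(axis=0)
            ss_ab += ng * float(((mgj - mg - level_means + grand) ** 2).sum())
            resid = x[sel] - mgj[None, :] - subj_means[sel][:, None] + mg
            ss_err += float((resid ** 2).sum())
        ss_b = n_total * float(((level_means - grand) ** 2).sum())
        df_a, df_subj = a - 1, n_total - a
        df_b, df_ab = b - 1, (a - 1) * (b - 1)
        df_err = (n_total - a) * (b - 1)
        eps = None
        if sphericity_correction:
            eps = self._gg_epsilon()
        def f_test(ss, df1, ss_e, df2, corrected):
            f = (ss / df1) / (ss_e / df2)
            d1, d2 = df1, df2
            if corrected and eps is not None:
                d1, d2 = df1 * eps, df2 * eps
            return {"F": float(f), "df1": float(d1), "df2": float(d2),
                    "p": float(stats.f.sf(f, d1, d2)),
                    "np2": float(ss / (ss + ss_e))}
        effects = {
            "between": f_test(ss_a, df_a, ss_subj, df_subj, False),
            "within": f_test(ss_b, df_b, ss_err, df_err,
                             sphericity_correction),
            "interaction": f_test(ss_ab, df_ab, ss_err, df_err,
                                  sphericity_correction),
        }
        return MixedANOVAResult(effects, self.between, self.within,
                                sphericity_corrected=sphericity_correction,
                                gg_epsilon=eps)

    def _gg_epsilon(self) -> float:
        """Greenhouse-Geisser epsilon from the double-centred covariance of
        the within-subject measures."""
        x = self.x
        b = x.shape[1]
        s = np.cov(x, rowvar=False)
        j = np.eye(b) - np.ones((b, b)) / b
        sc = j @ s @ j
        lam = np.linalg.eigvalsh(sc)
        num = lam.sum() ** 2
        den = (b - 1) * (lam ** 2).sum()
        return float(min(1.0, num / den)) if den > 0 else 1.0


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str,
                sphericity_correction: bool = False) -> MixedANOVAResult:
    """Functional wrapper around :class:`MixedANOVA`."""
    return MixedANOVA(data, dv, within, between, subject).fit(
        sphericity_correction=sphericity_correction)


# ---------------------------------------------------------------------------
# simple tests and power

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p.

    Degenerate all-identical input returns (0, 1) rather than an error.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def two_sample_power(d: float, n1: int, n2: int,
                     alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at effect size d, via the
    noncentral t distribution (df = n1+n2-2, ncp = d*sqrt(n1*n2/(n1+n2)))."""
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc)
                 + stats.nct.cdf(-tcrit, df, nc))


def min_detectable_d(n1: int, n2: int, alpha: float = 0.05,
                     power: float = 0.80) -> float:
    """Smallest Cohen's d at which the two-sided two-sample t test reaches
    the target power, by bisection of the noncentral-t power function.

    For the study scale (34 per group, alpha 0.05, 80% power) this gives
    d = 0.690, i.e. 80% power to detect moderate effects.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha:
        raise ValueError("target power must exceed alpha")
    f = lambda d: two_sample_power(d, n1, n2, alpha) - power
    hi = 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise ValueError("target power unattainable at these sizes")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-6))
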