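"""Group-level statistics: AUC tests, FDR, NBS, mixed ANOVA, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroperm.connectivity import FcMatrix
from neuroperm.graphs import MetricCurve
from neuroperm.inference import (AUCPermutationTest, MixedANOVA,
                                 NetworkBasedStatistic, auc,
                                 auc_permutation_test, benjamini_hochberg,
                                 edgewise_ttests, kruskal_wallis,
                                 longitudinal_change, min_detectable_d,
                                 two_sample_power)
from neuroperm.inference import _components_from_edges

LEVELS = tuple(range(5, 55, 5))


def curve(values, metric="mean_fc", **kw):
    return MetricCurve(metric=metric, sparsity_levels=LEVELS,
                       values=np.asarray(values, dtype=float), **kw)


class TestAuc:
    def test_constant_curve(self):
        assert auc(curve(np.full(10, 0.5))) == pytest.approx(0.5 * 45)

    def test_linear_curve(self):
        assert auc(curve(np.linspace(0, 1, 10))) == pytest.approx(22.5)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            auc(([5.0], [1.0]))


class TestAucPermutationTest:
    def test_identical_groups_p_one(self, rng):
        cs = [curve(rng.random(10)) for _ in range(4)]
        res = auc_permutation_test(cs, list(cs), n_permutations=200, seed=0)
        assert res.p_value == pytest.approx(1.0)

    def test_monte_carlo_matches_exhaustive_3v3(self, rng):
        a = [curve(rng.random(10) + 0.3) for _ in range(3)]
        b = [curve(rng.random(10)) for _ in range(3)]
        exact = AUCPermutationTest(a, b).fit(exact=True)
        assert exact.n_permutations == 20  # C(6,3) splits
        mc = AUCPermutationTest(a, b).fit(n_permutations=20_000, seed=1)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    @pytest.mark.parametrize("na,nb", [(2, 2), (4, 4), (3, 5)])
    def test_exhaustive_convergence_small_n(self, rng, na, nb):
        """Monte-Carlo p approaches full enumeration for n1+n2 <= 8."""
        a = list(rng.normal(1.0, 1.0, na))
        b = list(rng.normal(0.0, 1.0, nb))
        exact = AUCPermutationTest(a, b).fit(exact=True)
        mc = AUCPermutationTest(a, b).fit(n_permutations=20_000, seed=2)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_deterministic_given_seed(self, rng):
        a = [curve(rng.random(10)) for _ in range(5)]
        b = [curve(rng.random(10)) for _ in range(5)]
        r1 = auc_permutation_test(a, b, n_permutations=300, seed=9)
        r2 = auc_permutation_test(a, b, n_permutations=300, seed=9)
        assert r1.p_value == r2.p_value

    def test_p_resolution(self, rng):
        a = [curve(rng.random(10)) for _ in range(5)]
        b = [curve(rng.random(10) + 5) for _ in range(5)]
        res = auc_permutation_test(a, b, n_permutations=199, seed=0)
        assert res.p_value >= 1 / 200
        assert (res.p_value * 200) == pytest.approx(round(res.p_value * 200))


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        # q_i = min_k>=i (m * p_k / k): all four become 0.04
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1, 1, 1]), 1.0)

    def test_order_invariance_and_dominance(self, rng):
        p = rng.random(50)
        q = benjamini_hochberg(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), q[perm])
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)

    def test_degenerate_all_equal(self):
        assert kruskal_wallis([[2, 2], [2, 2]]) == (0.0, 1.0)

    def test_disjoint_groups_maximal_h(self):
        # ranks 1..6; R1=6, R2=15; H = 12/(6*7)*(12+75) - 21
        h, _ = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        expected = 12 / (6 * 7) * (6 ** 2 / 3 + 15 ** 2 / 3) - 3 * 7
        assert h == pytest.approx(expected)

    def test_matches_rank_enumeration(self, rng):
        """Oracle: H from explicit rank sums on random tied data."""
        a = list(rng.integers(0, 5, 6))
        b = list(rng.integers(0, 5, 6))
        h, _ = kruskal_wallis([a, b])
        ranks = stats.rankdata(a + b)
        n = len(ranks)
        r1, r2 = ranks[:6].sum(), ranks[6:].sum()
        hh = 12 / (n * (n + 1)) * (r1 ** 2 / 6 + r2 ** 2 / 6) - 3 * (n + 1)
        _, counts = np.unique(a + b, return_counts=True)
        tie = 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
        assert h == pytest.approx(hh / tie)


class TestEdgewise:
    def _mats(self, rng, n, r=10, shift=None):
        out = []
        for _ in range(n):
            z = rng.normal(0.3, 0.1, (r, r))
            z = (z + z.T) / 2
            np.fill_diagonal(z, 0)
            if shift is not None:
                (i, j), d = shift
                z[i, j] += d
                z[j, i] = z[i, j]
            out.append(FcMatrix(z=z, roi_names=[f"r{k}" for k in range(r)]))
        return out

    def test_identical_groups_all_zero_t(self, rng):
        g = self._mats(rng, 5)
        res = edgewise_ttests(g, list(g))
        iu = np.triu_indices(10, k=1)
        assert np.allclose(res.t[iu], 0.0)
        assert np.allclose(res.q[iu], 1.0)

    def test_family_size_is_630_for_36_rois(self, rng):
        g1 = [FcMatrix(z=np.zeros((36, 36)),
                       roi_names=[f"r{i}" for i in range(36)])
              for _ in range(3)]
        res = edgewise_ttests(g1, self._mats(rng, 3, r=36))
        iu = np.triu_indices(36, k=1)
        assert np.isfinite(res.p[iu]).sum() == 630

    def test_matches_scipy_per_edge(self, rng):
        ga = self._mats(rng, 6)
        gb = self._mats(rng, 7)
        res = edgewise_ttests(ga, gb)
        i, j = 2, 5
        a = [m.z[i, j] for m in ga]
        b = [m.z[i, j] for m in gb]
        t, p = stats.ttest_ind(a, b)
        assert res.t[i, j] == pytest.approx(t)
        assert res.p[i, j] == pytest.approx(p)

    def test_planted_edge_detected(self, rng):
        ga = self._mats(rng, 30)
        gb = self._mats(rng, 30, shift=((1, 2), 0.15))  # 1.5 pooled sd
        res = edgewise_ttests(ga, gb)
        assert res.q[1, 2] < 0.05


class TestNbsComponents:
    def test_two_edge_chain_one_component(self):
        comps = _components_from_edges(np.array([[1, 2], [2, 3]]), 5)
        assert len(comps) == 1
        nodes, edges = comps[0]
        assert nodes == frozenset({1, 2, 3})
        assert edges == 2

    def test_disjoint_pairs(self):
        comps = _components_from_edges(np.array([[0, 1], [2, 3]]), 5)
        sizes = sorted(e for _, e in comps)
        assert sizes == [1, 1]
        assert max(e for _, e in comps) == 1

    def test_singletons_never_returned(self):
        assert _components_from_edges(np.empty((0, 2)), 4) == []


class TestNbs:
    def _dataset(self, rng, n_per_group, r=12, clique=None, delta=0.0):
        mats, labels = [], []
        for g in range(2):
            for _ in range(n_per_group):
                z = rng.normal(0.3, 0.1, (r, r))
                z = (z + z.T) / 2
                np.fill_diagonal(z, 0)
                if g == 1 and clique:
                    for i, j in itertools.combinations(clique, 2):
                        z[i, j] += delta
                        z[j, i] = z[i, j]
                mats.append(z)
                labels.append(g)
        return mats, labels

    def test_planted_clique_found_with_small_p(self, rng):
        mats, labels = self._dataset(rng, 20, clique=(0, 1, 2, 3, 4),
                                     delta=0.15)
        res = NetworkBasedStatistic(mats, labels, threshold=2.0).fit(
            n_permutations=300, seed=0)
        assert not res.empty
        big = max(res.components, key=lambda c: c[1])
        assert {"roi0", "roi1", "roi2", "roi3", "roi4"} <= set(big[0])
        assert res.min_p < 0.05

    def test_no_suprathreshold_edges_flagged_empty(self, rng):
        mats, labels = self._dataset(rng, 3)
        with pytest.warns(UserWarning, match="no suprathreshold"):
            res = NetworkBasedStatistic(mats, labels, threshold=50.0).fit(
                n_permutations=50, seed=0)
        assert res.empty
        assert res.max_component_edges == 0

    def test_deterministic_given_seed(self, rng):
        mats, labels = self._dataset(rng, 4)
        r1 = NetworkBasedStatistic(mats, labels).fit(n_permutations=100,
                                                     seed=5)
        r2 = NetworkBasedStatistic(mats, labels).fit(n_permutations=100,
                                                     seed=5)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)

    def test_node_size_measure_flag(self, rng):
        mats, labels = self._dataset(rng, 10, clique=(0, 1, 2), delta=0.3)
        res = NetworkBasedStatistic(mats, labels,
                                    size_measure="nodes").fit(
            n_permutations=100, seed=1)
        assert res.size_measure == "nodes"


class TestLongitudinalChange:
    def _table(self, rng, n=6, delta=0.0, regions=("a", "b")):
        rows = []
        for s in range(n):
            for r in regions:
                base = rng.normal(0.4, 0.02)
                rows.append((f"s{s}", "adolescence", r, base))
                rows.append((f"s{s}", "adulthood", r, base + delta))
        return pd.DataFrame(rows, columns=["subject_id", "timepoint",
                                           "region", "value"])

    def test_no_change_gives_zero_t(self, rng):
        res = longitudinal_change(self._table(rng, delta=0.0))
        assert np.allclose(res.table.delta_mean, 0.0)

    def test_unmatched_subject_dropped_and_counted(self, rng):
        tab = self._table(rng)
        tab = tab[~((tab.subject_id == "s0")
                    & (tab.timepoint == "adulthood"))]
        res = longitudinal_change(tab)
        assert res.n_dropped == 1
        assert (res.table.n == 5).all()

    def test_strong_increment_significant(self, rng):
        tab = self._table(rng, n=30, delta=0.03)
        noise = rng.normal(0, 0.01, len(tab))
        tab["value"] = tab.value + noise
        res = longitudinal_change(tab)
        assert (res.table.q < 0.001).all()


class TestMixedAnova:
    def _long(self, rng, n=8, b=5, group_effect=0.0, region_scale=1.0):
        rows = []
        for g, gname in enumerate(("wildtype", "knockout")):
            for s in range(n):
                sid = f"{gname}{s}"
                intercept = rng.normal()
                for j in range(b):
                    y = (intercept + region_scale * j
                         + group_effect * g + rng.normal())
                    rows.append((sid, gname, f"reg{j}", y))
        return pd.DataFrame(rows, columns=["subject", "genotype", "region",
                                           "y"])

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = self._long(rng)
        res = MixedANOVA(df, dv="y", within="region", between="genotype",
                         subject="subject").fit()
        ref = pg.mixed_anova(data=df, dv="y", within="region",
                             between="genotype", subject="subject")
        ref = ref.set_index("Source")
        assert res.effects["between"]["F"] == pytest.approx(
            ref.loc["genotype", "F"], abs=1e-8)
        assert res.effects["within"]["F"] == pytest.approx(
            ref.loc["region", "F"], abs=1e-8)
        assert res.effects["interaction"]["F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)
        assert res.effects["within"]["np2"] == pytest.approx(
            ref.loc["region", "np2"], abs=1e-8)

    def test_identical_group_profiles_null_genotype(self, rng):
        df = self._long(rng, group_effect=0.0, region_scale=0.0)
        # make the two genotypes literally identical
        wt = df[df.genotype == "wildtype"].copy()
        ko = wt.copy()
        ko["genotype"] = "knockout"
        ko["subject"] = ko.subject.str.replace("wildtype", "knockout")
        res = MixedANOVA(pd.concat([wt, ko]), dv="y", within="region",
                         between="genotype", subject="subject").fit()
        assert res.effects["between"]["F"] == pytest.approx(0.0, abs=1e-20)

    def test_strong_region_effect_large_partial_eta(self, rng):
        df = self._long(rng, n=20, region_scale=1.5)
        res = MixedANOVA(df, dv="y", within="region", between="genotype",
                         subject="subject").fit()
        assert res.effects["within"]["p"] < 0.001
        assert res.effects["within"]["np2"] > 0.5
        assert res.effects["between"]["p"] > 0.05

    def test_missing_cells_error(self, rng):
        df = self._long(rng).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            MixedANOVA(df, dv="y", within="region", between="genotype",
                       subject="subject")

    def test_gg_epsilon_bounds(self, rng):
        df = self._long(rng)
        m = MixedANOVA(df, dv="y", within="region", between="genotype",
                       subject="subject")
        res = m.fit(sphericity_correction=True)
        b = len(m.within_levels)
        assert 1.0 / (b - 1) - 1e-9 <= res.gg_epsilon <= 1.0


class TestPower:
    def test_study_scale_rounds_to_printed_value(self):
        d = min_detectable_d(34, 34, alpha=0.05, power=0.80)
        assert round(d, 1) == 0.7

    def test_small_n_value_from_grid_oracle(self):
        """Oracle: coarse grid search over the noncentral-t power curve."""
        grid = np.arange(0.5, 5.0, 1e-4)
        powers = np.array([two_sample_power(d, 4, 4) for d in grid])
        expected = grid[np.argmax(powers >= 0.80)]
        d = min_detectable_d(4, 4)
        assert d == pytest.approx(expected, abs=1e-3)
        assert d == pytest.approx(2.3808, abs=1e-3)

    def test_monotone_in_n_and_power(self):
        assert min_detectable_d(50, 50) < min_detectable_d(20, 20)
        assert min_detectable_d(20, 20, power=0.9) > min_detectable_d(
            20, 20, power=0.8)

    def test_achieved_power_at_solution(self):
        d = min_detectable_d(12, 18, alpha=0.01, power=0.85)
        assert two_sample_power(d, 12, 18, alpha=0.01) == pytest.approx(
            0.85, abs=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_detectable_d(1, 5)
        with pytest.raises(ValueError):
            min_detectable_d(5, 5, alpha=0.5, power=0.2)
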