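"""Overlap chi-square inference, Holm-Sidak correction, marker localization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

import zonemap as zm
from zonemap.correspond import adjust_family, results_table
from zonemap.de import DirectionalGeneList


def universe_of(n):
    return [f"u{i}" for i in range(n)]


def chi2_bruteforce(k, n_a, n_b, N):
    obs = np.array([[k, n_a - k], [n_b - k, N - n_a - n_b + k]], dtype=float)
    exp = np.array([[n_a * n_b, n_a * (N - n_b)],
                    [(N - n_a) * n_b, (N - n_a) * (N - n_b)]]) / N
    return ((obs - exp) ** 2 / exp).sum()


def overlap(k, n_a, n_b, N, **kw):
    uni = universe_of(N)
    a = uni[:n_a]
    b = uni[:k] + uni[n_a:n_a + n_b - k]
    return zm.directional_overlap_test(a, b, uni, **kw)


class TestIntersectUniverse:
    def test_disjoint(self):
        assert zm.intersect_universe({"a"}, {"b"}) == []

    def test_case_insensitive(self):
        assert zm.intersect_universe({"Prg4"}, {"PRG4"}) == ["prg4"]

    def test_subset(self):
        assert zm.intersect_universe({"a", "b"}, {"a", "b", "c"}) == ["a", "b"]


class TestDirectionalOverlapTest:
    def test_overlap_at_expectation_is_null(self):
        res = overlap(k=1, n_a=10, n_b=10, N=100)
        assert np.isclose(res.chi2, 0.0)
        assert np.isclose(res.p_raw, 1.0)
        assert res.direction == "none"

    def test_enriched_overlap_hand_values(self):
        res = overlap(k=20, n_a=100, n_b=50, N=1000)
        assert np.isclose(res.expected, 5.0)
        assert np.isclose(res.chi2, chi2_bruteforce(20, 100, 50, 1000))
        assert res.chi2 > 50
        assert res.direction == "more_than_chance"

    def test_perfect_overlap_hand_computation(self):
        res = overlap(k=50, n_a=50, n_b=50, N=100)
        assert np.isclose(res.chi2, 100.0)
        assert res.direction == "more_than_chance"

    def test_degenerate_margins_flagged(self):
        res = zm.directional_overlap_test([], universe_of(10)[:3], universe_of(10))
        assert res.degenerate and np.isnan(res.p_raw)
        assert res.direction == "none"

    def test_symmetry_in_list_order(self, rng):
        uni = universe_of(200)
        a = list(rng.choice(uni, 40, replace=False))
        b = list(rng.choice(uni, 60, replace=False))
        r1 = zm.directional_overlap_test(a, b, uni)
        r2 = zm.directional_overlap_test(b, a, uni)
        assert np.isclose(r1.chi2, r2.chi2)
        assert np.isclose(r1.p_raw, r2.p_raw)
        assert r1.k == r2.k and np.isclose(r1.expected, r2.expected)

    def test_matches_scipy_contingency(self):
        res = overlap(k=12, n_a=40, n_b=70, N=500)
        table = np.array([[12, 28], [58, 402]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert np.isclose(res.chi2, chi2)
        assert np.isclose(res.p_raw, p)

    def test_chi2_equals_two_proportion_z_squared(self):
        res = overlap(k=12, n_a=40, n_b=70, N=500)
        z, p = proportions_ztest([12, 70 - 12], [40, 500 - 40])
        assert np.isclose(res.chi2, z ** 2)
        assert np.isclose(res.p_raw, p)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_chi2_matches_bruteforce_on_random_tables(self, data):
        N = data.draw(st.integers(10, 2000))
        n_a = data.draw(st.integers(1, N - 1))
        n_b = data.draw(st.integers(1, N - 1))
        k = data.draw(st.integers(max(0, n_a + n_b - N), min(n_a, n_b)))
        res = overlap(k, n_a, n_b, N)
        assert np.isclose(res.chi2, chi2_bruteforce(k, n_a, n_b, N), atol=1e-9)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            zm.directional_overlap_test({"a"}, {"a"}, [])


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert np.isclose(zm.holm_sidak_adjust([0.2])[0], 0.2)

    def test_two_p_hand_computation(self):
        adj = zm.holm_sidak_adjust([0.01, 0.04])
        assert np.isclose(adj[0], 1 - (1 - 0.01) ** 2)  # 0.0199
        assert np.isclose(adj[1], 0.04)

    def test_all_zero(self):
        assert np.allclose(zm.holm_sidak_adjust([0.0, 0.0, 0.0]), 0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_bounded_by_raw_and_bonferroni(self, p):
        p = np.asarray(p)
        adj = zm.holm_sidak_adjust(p)
        bonf = np.minimum(p * len(p), 1.0)
        assert (adj >= p - 1e-12).all()
        assert (adj <= bonf + 1e-12).all()
        assert ((adj >= 0) & (adj <= 1)).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            zm.holm_sidak_adjust([1.2])


class TestAllPairsCorrespondence:
    @staticmethod
    def study_lists(seed=3, rho=0.8):
        design = zm.default_study_design(seed=seed, n_genes=1000,
                                         program_size=100, rho=rho,
                                         platform_overlap=1.0)
        mat_a, mat_b, truth = zm.simulate_tissue_pair(design)
        lists_a, lists_b = [], []
        for m, store in ((mat_a, lists_a), (mat_b, lists_b)):
            for za, zb in design.zone_pairs(m.platform):
                _, ua, ub = zm.call_spatially_regulated(m, za, zb)
                store += [ua, ub]
        universe = zm.intersect_universe(mat_a.gene_universe, mat_b.gene_universe)
        return lists_a, lists_b, universe, truth

    def test_family_size_is_twelve(self):
        lists_a, lists_b, universe, _ = self.study_lists()
        results = zm.all_pairs_correspondence(lists_a, lists_b, universe)
        assert len(results) == 12

    def test_planted_correspondences_flagged(self):
        lists_a, lists_b, universe, truth = self.study_lists(rho=0.8)
        results = zm.all_pairs_correspondence(lists_a, lists_b, universe)
        by_id = {(r.list_a_id, r.list_b_id): r for r in results}
        # every deliberately shared planted pair must come out enriched
        for (ka, kb) in truth.shared_pairs:
            ta, (za, zb), ua = ka
            tb, (zc, zd), ub = kb
            key = (f"{ta}:{ua}>({za}-{zb})", f"{tb}:{ub}>({zc}-{zd})")
            assert by_id[key].direction == "more_than_chance"

    def test_all_empty_lists_are_degenerate(self):
        empty = [DirectionalGeneList("A", ("x", "y"), "x", ()),
                 DirectionalGeneList("A", ("x", "y"), "y", ())]
        results = zm.all_pairs_correspondence(empty, empty, universe_of(50))
        assert len(results) == 4
        assert all(r.degenerate for r in results)

    def test_adjustment_never_reduces_p(self):
        lists_a, lists_b, universe, _ = self.study_lists()
        raw = zm.all_pairs_correspondence(lists_a, lists_b, universe,
                                          family_correction=False)
        adj = adjust_family(raw)
        for r0, r1 in zip(raw, adj):
            assert r1.p_adj >= r0.p_raw - 1e-12


class TestMarkerLocalization:
    def test_counting_contract(self):
        uni = universe_of(100)
        markers = zm.MarkerSet("pz_markers", "PZ", frozenset(uni[:6]))
        up = DirectionalGeneList("A", ("SZ", "IDZ"), "SZ",
                                 tuple(uni[3:23]))  # 3 of 6 markers inside
        (loc,) = zm.marker_localization(markers, [up], uni)
        assert (loc.K, loc.k_up) == (6, 3)

    def test_empty_uplist_gives_zero(self):
        uni = universe_of(50)
        markers = zm.MarkerSet("m", "Z", frozenset(uni[:5]))
        up = DirectionalGeneList("A", ("x", "y"), "x", ())
        (loc,) = zm.marker_localization(markers, [up], uni)
        assert loc.k_up == 0 and loc.overlap.degenerate

    def test_maximal_overlap_enriched(self):
        uni = universe_of(200)
        markers = zm.MarkerSet("m", "Z", frozenset(uni[:10]))
        up = DirectionalGeneList("A", ("x", "y"), "x", tuple(uni[:10]))
        (loc,) = zm.marker_localization(markers, [up], uni)
        assert loc.k_up == loc.K == 10
        assert loc.overlap.direction == "more_than_chance"

    def test_markers_outside_universe_error(self):
        markers = zm.MarkerSet("m", "Z", frozenset({"x1", "x2"}))
        with pytest.raises(ValueError, match="no genes in the universe"):
            zm.marker_localization(markers, [], universe_of(10))

    def test_results_table_has_marker_columns(self):
        uni = universe_of(100)
        markers = zm.MarkerSet("m", "Z", frozenset(uni[:6]))
        up = DirectionalGeneList("A", ("x", "y"), "x", tuple(uni[:10]))
        table = results_table(zm.marker_localization(markers, [up], uni))
        assert {"marker_set", "K", "k_up", "chi2", "direction"} <= set(table.columns)
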