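"""Scan engine: zones, expectations, LLR, maximisation, Monte Carlo."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scanwatch as sw
from scanwatch.scan import ParameterError
from _oracles import brute_best_cluster, brute_llr, brute_zones
from conftest import make_series

# frozen from an independent evaluation of
# c*ln(c/mu) + (C-c)*ln((C-c)/(C-mu)) at c=8, mu=0.5, C=1400
LLR_8_05_1400 = 14.700842236806867


def line_geometry(n, spacing=1.0, pops=None):
    ids = [f"A{k:02d}" for k in range(n)]
    cents = np.array([[k * spacing, 0.0] for k in range(n)])
    pops = np.full(n, 100) if pops is None else np.asarray(pops)
    return ids, cents, pops


class TestZones:
    def test_single_area_single_zone(self):
        ids, cents, pops = line_geometry(1)
        zones = sw.enumerate_zones(ids, cents, pops, sw.ScanParams())
        assert len(zones) == 1
        assert zones[0].member_area_ids == ("A00",)

    def test_line_matches_brute_force(self):
        rng = np.random.default_rng(7)
        ids, cents, _ = line_geometry(5, spacing=2.0)
        pops = rng.integers(50, 200, size=5)
        params = sw.ScanParams(max_radius_km=5.0, max_pop_fraction=0.6)
        zones = sw.enumerate_zones(ids, cents, pops, params)
        got = {frozenset(z.member_area_ids) for z in zones}
        brute, detail = brute_zones(ids, cents.tolist(), pops.tolist(), 5.0, 0.6)
        want = {frozenset(ids[j] for j in key) for key in brute}
        assert got == want

    def test_caps_removed_zone_covers_everything(self):
        ids, cents, pops = line_geometry(6)
        params = sw.ScanParams(max_radius_km=1e9, max_pop_fraction=1.0)
        zones = sw.enumerate_zones(ids, cents, pops, params)
        assert max(len(z.member_area_ids) for z in zones) == 6

    def test_cap_breaching_singleton_retained(self):
        ids, cents, _ = line_geometry(3)
        pops = np.array([900, 50, 50])  # center 0 alone breaches a 10% cap
        params = sw.ScanParams(max_pop_fraction=0.10)
        zones = sw.enumerate_zones(ids, cents, pops, params)
        assert frozenset(["A00"]) in {frozenset(z.member_area_ids) for z in zones}

    def test_all_zero_population_rejected(self):
        ids, cents, _ = line_geometry(3)
        with pytest.raises(ParameterError):
            sw.enumerate_zones(ids, cents, np.zeros(3, int), sw.ScanParams())

    def test_zone_radius_is_distance_to_farthest_member(self):
        ids, cents, pops = line_geometry(4, spacing=3.0)
        params = sw.ScanParams(max_radius_km=100, max_pop_fraction=1.0)
        zones = sw.enumerate_zones(ids, cents, pops, params)
        for z in zones:
            if z.center_area_id == "A00" and len(z.member_area_ids) == 3:
                assert z.radius_km == pytest.approx(6.0)


class TestExpectedCount:
    def test_whole_study_window_gives_C(self):
        assert sw.expected_count(1000, 24, 240, 1000, 24) == 240

    def test_closed_form_example(self):
        # 1% of the population for half of a 24-month epoch, C = 1400
        assert sw.expected_count(10, 12, 1400, 1000, 24) == pytest.approx(7.0)

    def test_empty_zone_zero(self):
        assert sw.expected_count(0, 12, 1400, 1000, 24) == 0.0


class TestLLR:
    def test_null_case_zero(self):
        assert sw.llr(5, 5.0, 100) == 0.0

    def test_frozen_two_term_value(self):
        assert sw.llr(8, 0.5, 1400) == pytest.approx(LLR_8_05_1400, rel=1e-12)

    def test_all_cases_in_window_increases_as_mu_shrinks(self):
        vals = [sw.llr(50, mu, 50) for mu in (40.0, 10.0, 1.0)]
        assert vals[0] > 0
        assert vals[0] < vals[1] < vals[2]

    def test_low_rate_window_scores_zero_by_default(self):
        assert sw.llr(1, 10.0, 100) == 0.0
        assert sw.llr(1, 10.0, 100, high_rate_only=False) > 0.0

    def test_observed_above_total_rejected(self):
        with pytest.raises(ValueError):
            sw.llr(101, 1.0, 100)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        c=st.integers(0, 200),
        mu=st.floats(0.0, 200.0, allow_nan=False),
        C=st.integers(1, 200),
    )
    def test_nonnegative_zero_iff_not_elevated(self, c, mu, C):
        if c > C or mu > C:
            return
        v = sw.llr(c, mu, C)
        assert v >= 0.0
        if c <= mu:
            assert v == 0.0
        elif mu > 0 and c > mu:
            assert v == pytest.approx(brute_llr(c, mu, C), rel=1e-10)


class TestScan:
    def test_concentrated_cases_found_exactly(self):
        counts = np.zeros((6, 6), int)
        counts[3, 2] = 9
        series = make_series(counts, pops=np.full(6, 100))
        ids, cents, pops = line_geometry(6, spacing=2.0)
        params = sw.ScanParams(max_pop_fraction=0.5, n_replicates=19)
        model = sw.PoissonScan(series, cents, params)
        best = model.fit(seed=0).most_likely
        assert best.zone.member_area_ids == ("A03",)
        assert (best.start_month, best.end_month) == (2, 2)
        assert best.observed == 9

    @pytest.mark.parametrize("seed", range(6))
    def test_best_cluster_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, T = rng.integers(4, 9), rng.integers(4, 9)
        cents = rng.uniform(0, 10, size=(n, 2))
        pops = rng.integers(50, 300, size=n)
        counts = rng.poisson(1.0, size=(n, T))
        if counts.sum() == 0:
            counts[0, 0] = 3
        ids = [f"A{k:02d}" for k in range(n)]
        params = sw.ScanParams(max_radius_km=8.0, max_pop_fraction=0.5,
                               max_duration_months=5, n_replicates=9)
        series = make_series(counts, pops)
        model = sw.PoissonScan(series, cents, params)
        got = model.fit(seed=0).most_likely
        want = brute_best_cluster(
            counts.tolist(), cents.tolist(), pops.tolist(), ids,
            8.0, 0.5, 5,
        )
        assert want is not None and got is not None
        assert frozenset(got.zone.member_area_ids) == {ids[j] for j in want[0]}
        assert (got.start_month, got.end_month) == want[1]
        assert got.observed == want[2]
        assert got.expected == pytest.approx(want[3], rel=1e-12)
        assert got.llr == pytest.approx(want[4], rel=1e-12)

    def test_uniform_landscape_has_no_cluster(self):
        pops = np.full(5, 100)
        counts = np.full((5, 8), 2, int)  # exactly proportional to population
        series = make_series(counts, pops)
        ids, cents, _ = line_geometry(5)
        params = sw.ScanParams(max_pop_fraction=1.0, n_replicates=9)
        model = sw.PoissonScan(series, cents, params)
        best = model.fit(seed=0).most_likely
        assert best is None or best.llr < 0.3

    def test_doubling_best_window_does_not_decrease_llr(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.0, size=(5, 6))
        counts[2, 3] += 6
        pops = np.full(5, 100)
        ids, cents, _ = line_geometry(5, spacing=2.0)
        params = sw.ScanParams(max_pop_fraction=0.6, n_replicates=9)
        best = sw.PoissonScan(make_series(counts, pops), cents, params).fit(seed=0).most_likely
        boosted = counts.copy()
        boosted[2, 3] *= 2
        best2 = sw.PoissonScan(make_series(boosted, pops), cents, params).fit(seed=0).most_likely
        assert best2.llr >= best.llr

    def test_no_cases_no_clusters(self):
        series = make_series(np.zeros((4, 6), int), np.full(4, 100))
        ids, cents, _ = line_geometry(4)
        model = sw.PoissonScan(series, cents, sw.ScanParams(max_pop_fraction=1.0))
        assert model.fit(seed=0).clusters == []

    def test_secondary_clusters_share_no_areas(self):
        counts = np.zeros((8, 6), int)
        counts[0, 1] = 6
        counts[7, 4] = 5
        pops = np.full(8, 100)
        ids, cents, _ = line_geometry(8, spacing=2.0)
        params = sw.ScanParams(max_pop_fraction=0.5, n_replicates=9)
        res = sw.PoissonScan(make_series(counts, pops), cents, params).fit(seed=0)
        assert len(res.clusters) >= 2
        seen = set()
        for c in res.clusters:
            mem = set(c.zone.member_area_ids)
            assert not (mem & seen)
            seen |= mem


class TestMonteCarlo:
    def test_rank_arithmetic(self):
        # 49 replicate maxima at or above the candidate -> rank 50 of 1,000
        rep = np.concatenate([np.full(49, 10.0), np.full(950, 1.0)])
        assert sw.rank_p_value(5.0, rep) == pytest.approx(0.05)
        assert sw.rank_p_value(20.0, np.ones(999)) == pytest.approx(0.001)
        assert sw.rank_p_value(0.5, np.ones(999)) == pytest.approx(1.0)

    def test_replicates_conserve_total(self, small_series):
        sub = small_series.slice_months(0, 23)
        params = sw.ScanParams(max_pop_fraction=0.2, n_replicates=25)
        model = sw.PoissonScan(sub, None, params,
                               zone_system=sw.ZoneSystem(
                                   sub.area_ids,
                                   np.column_stack([np.arange(len(sub.area_ids)),
                                                    np.zeros(len(sub.area_ids))]),
                                   sub.populations, params))
        draws = model.null_replicates(np.random.default_rng(0))
        assert draws.shape[0] == 25
        assert (draws.sum(axis=(1, 2)) == sub.total_C).all()

    def test_p_values_reproducible_for_fixed_seed(self, small_geo, small_series):
        sub = small_series.slice_months(6, 29)
        params = sw.ScanParams(max_pop_fraction=0.2, n_replicates=99)
        cents = small_geo.centroids("MB")
        p1 = [c.p_value for c in sw.PoissonScan(sub, cents, params).fit(seed=5).clusters]
        p2 = [c.p_value for c in sw.PoissonScan(sub, cents, params).fit(seed=5).clusters]
        assert p1 == p2 and len(p1) > 0

    def test_monte_carlo_function_matches_fit(self, small_geo, small_series):
        sub = small_series.slice_months(6, 29)
        params = sw.ScanParams(max_pop_fraction=0.2, n_replicates=49)
        cents = small_geo.centroids("MB")
        model = sw.PoissonScan(sub, cents, params)
        res = model.fit(seed=5)
        redone = sw.monte_carlo(sub, model.zone_system, params,
                                res.clusters, seed=5)
        assert [c.p_value for c in redone] == [c.p_value for c in res.clusters]

    def test_kernel_agrees_with_numpy_path(self, small_geo, small_series):
        """The jit replicate kernel and the vectorised scorer agree exactly."""
        sub = small_series.slice_months(0, 23)
        params = sw.ScanParams(max_pop_fraction=0.2, n_replicates=10)
        model = sw.PoissonScan(sub, small_geo.centroids("MB"), params)
        draws = model.null_replicates(np.random.default_rng(1))
        fast = model._null_replicate_maxima_from(draws)
        slow = model.max_llr(draws)
        np.testing.assert_allclose(fast, slow, rtol=0, atol=1e-9)
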