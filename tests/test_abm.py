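"""Agent-based model: decision rules, offers, agency selection and the
annual simulation loop."""

import math

import numpy as np
import pytest

from fallowsim import (
    Offer,
    WILLINGNESS_THRESHOLD,
    OWA_ALPHAS,
    build_offer,
    enrollment_density,
    fix_factor,
    fsa_select,
    make_model,
    orness,
    owa_aggregate,
    owa_weights,
    resolve_run_factors,
    run_simulation,
    select_sites,
    willingness,
)
from fallowsim.abm import GOLDEN_FRAC, _agent_attributes
from fallowsim.landscape import LandUse, eligibility_mask


class TestOwa:
    def test_neutral_rule_is_uniform(self):
        np.testing.assert_allclose(owa_weights(8), [0.25] * 4)
        assert orness(owa_weights(8)) == pytest.approx(0.5)

    def test_all_rules_valid_weights(self):
        for i in range(17):
            w = owa_weights(i)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0)

    def test_most_or_like_rule(self):
        assert orness(owa_weights(0)) > 0.8

    def test_orness_strictly_decreasing(self):
        vals = [orness(owa_weights(i)) for i in range(17)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            owa_weights(17)

    @pytest.mark.parametrize(
        "weights,expected",
        [
            ((0, 0, 0, 1), 0.2),  # AND-like: minimum
            ((1, 0, 0, 0), 1.0),  # OR-like: maximum
            ((0.25, 0.25, 0.25, 0.25), 0.625),
        ],
    )
    def test_aggregate(self, weights, expected):
        crit = (0.2, 0.8, 0.5, 1.0)
        assert owa_aggregate(crit, weights) == pytest.approx(expected)

    def test_criteria_range_checked(self):
        with pytest.raises(ValueError):
            owa_aggregate((0.2, 1.4, 0.5, 1.0), owa_weights(8))

    def test_or_dominance(self, rng):
        """A more OR-like rule never lowers any aggregation of the same
        criteria (willingness is monotone in orness)."""
        crits = rng.random((50, 4))
        ws = [owa_weights(i) for i in range(17)]
        for c in crits:
            vals = [owa_aggregate(c, w) for w in ws]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestDensity:
    def test_ratio(self):
        cent = np.zeros((11, 2))
        cent[1:, 0] = 100.0  # 10 neighbors at 100 m
        enrolled = np.zeros(11, dtype=bool)
        enrolled[1:4] = True
        assert enrollment_density(0, cent, enrolled, radius=500) == pytest.approx(0.3)

    def test_no_neighbors(self):
        cent = np.array([[0.0, 0.0], [5000.0, 0.0]])
        assert enrollment_density(0, cent, np.array([False, True]), 500) == 0.0

    def test_large_radius_gives_global_fraction(self, rng):
        cent = rng.random((30, 2)) * 1000
        enrolled = rng.random(30) < 0.4
        d = enrollment_density(3, cent, enrolled, radius=1e9)
        manual = (enrolled.sum() - enrolled[3]) / 29
        assert d == pytest.approx(manual)


class TestWillingness:
    def test_fully_predisposed_agent(self):
        for rule in range(17):
            assert willingness(0, 0.0, 1.0, 1.0, rule) == pytest.approx(1.0)
            assert willingness(0, 0.0, 1.0, 1.0, rule) >= WILLINGNESS_THRESHOLD

    def test_fully_averse_agent(self):
        for rule in range(17):
            assert willingness(1, 1.0, 0.0, 0.0, rule) == 0.0

    def test_threshold_constant(self):
        assert WILLINGNESS_THRESHOLD == 0.87


class TestSelectSites:
    def _toy(self):
        # 3 cells in a flat raster; equal distances, differing slope
        dw = np.array([10.0, 10.0, 10.0])
        df = np.array([20.0, 20.0, 20.0])
        sl = np.array([5.0, 25.0, 15.0])
        return dw, df, sl

    def test_steeper_first(self):
        dw, df, sl = self._toy()
        order = select_sites([0, 1, 2], 1.0, dw, df, sl)
        assert list(order) == [1, 2, 0]

    def test_ceiling_rule(self):
        n = 7
        dw = np.arange(n, dtype=float)
        df = np.arange(n, dtype=float)
        sl = np.zeros(n)
        sel = select_sites(np.arange(n), 0.5, dw, df, sl)
        assert len(sel) == 4  # ceil(0.5 * 7)
        assert list(sel) == [0, 1, 2, 3]

    def test_fraction_one_selects_all(self):
        dw, df, sl = self._toy()
        assert len(select_sites([0, 1, 2], 1.0, dw, df, sl)) == 3

    def test_tie_broken_by_cell_index(self):
        dw = np.zeros(3)
        sel = select_sites([2, 0, 1], 1.0, dw, dw, dw)
        assert list(sel) == [0, 1, 2]

    def test_fraction_domain(self):
        dw, df, sl = self._toy()
        with pytest.raises(ValueError):
            select_sites([0, 1], 0.0, dw, df, sl)

    def test_composite_rank_oracle(self, rng):
        """Order agrees with a direct mean-of-three-ranks computation."""
        n = 12
        dw, df = rng.random(n) * 500, rng.random(n) * 500
        sl = rng.random(n) * 20
        order = select_sites(np.arange(n), 1.0, dw, df, sl)

        def avg_rank(x):
            # mid-rank of each value (average over ties)
            return np.array(
                [(np.sum(x < v) + np.sum(x <= v) + 1) / 2 for v in x]
            )

        comp = (avg_rank(dw) + avg_rank(df) + avg_rank(-sl)) / 3
        expected = np.lexsort((np.arange(n), comp))
        np.testing.assert_array_equal(order, expected)


class TestOffers:
    def test_build_offer_pricing(self):
        srr = np.array([100.0, 120.0, 80.0])
        ebi = np.array([200.0, 260.0, 140.0])
        o = build_offer(5, [0, 1], srr, ebi, bid=0.10, cell_acres=0.25)
        assert o.annual_payment == pytest.approx((100 + 120) * 0.25)
        assert o.dap == pytest.approx(o.annual_payment * 0.9)
        assert o.ebi_score == pytest.approx(230.0)
        assert o.area_units == 2

    def test_zero_bid(self):
        srr = np.full(4, 100.0)
        o = build_offer(0, [2], srr, srr, bid=0.0, cell_acres=0.2224)
        assert o.dap == o.annual_payment

    def test_bid_range(self):
        srr = np.full(2, 1.0)
        with pytest.raises(ValueError):
            build_offer(0, [0], srr, srr, bid=0.3, cell_acres=0.2)

    def test_offer_consistency_enforced(self):
        with pytest.raises(ValueError):
            Offer(0, [1, 2], 2, 100.0, 0.1, 95.0, 200.0)  # dap mismatch


class TestFsaSelect:
    def _offer(self, aid, ebi=200.0, payment=100.0, bid=0.0):
        return Offer(aid, [aid], 1, payment, bid, payment * (1 - bid), ebi)

    def test_accept_all_when_n_large(self):
        offers = [self._offer(i) for i in range(3)]
        assert len(fsa_select(offers, 10)) == 3

    def test_none_when_n_zero(self):
        assert fsa_select([self._offer(0)], 0) == []

    def test_higher_bid_wins(self):
        low = self._offer(0, bid=0.02)
        high = self._offer(1, bid=0.10)
        assert fsa_select([low, high], 1)[0].agent_id == 1

    def test_higher_benefit_wins(self):
        a = self._offer(0, ebi=150.0)
        b = self._offer(1, ebi=300.0)
        assert fsa_select([a, b], 1)[0].agent_id == 1

    def test_cheaper_wins_cost_adjustment(self):
        a = self._offer(0, payment=500.0)
        b = self._offer(1, payment=100.0)
        assert fsa_select([a, b], 1)[0].agent_id == 1

    def test_tie_by_agent_id(self):
        a, b = self._offer(1), self._offer(0)
        assert fsa_select([a, b], 1)[0].agent_id == 0


class TestRunFactors:
    def test_resolution_and_fixing(self, specs):
        rf = resolve_run_factors(specs, [0.5] * 9)
        assert rf.n == 23 and rf.de_radius == 1000
        fixed = fix_factor(specs, "n", 23)
        rf2 = resolve_run_factors(fixed, [0.5] * 8)
        assert rf2.n == 23

    def test_incomplete_vector(self, specs):
        with pytest.raises(ValueError):
            resolve_run_factors(specs, [0.5] * 5)

    def test_demographic_fix_keeps_population_heterogeneous(self, specs):
        fixed = fix_factor(specs, "PRODUCTION", 1.0)
        rf = resolve_run_factors(fixed, [0.5] * 8)
        attrs = _agent_attributes(rf, 300, master_seed=1)
        assert len(np.unique(attrs["PRODUCTION"])) > 1

    def test_demographic_marginals(self, specs):
        """Golden-ratio quantile stratification reproduces the reference
        demographic marginals closely even at a few hundred agents."""
        rf = resolve_run_factors(specs, [0.3] * 9)
        attrs = _agent_attributes(rf, 300, master_seed=5)
        retired_frac = np.mean(attrs["RETIREMENT"] == 0)
        assert abs(retired_frac - 0.06) < 0.03
        top_prod = np.mean(attrs["PRODUCTION"] == 1.0)
        assert abs(top_prod - 0.62) < 0.06

    def test_demographics_deterministic(self, specs):
        rf = resolve_run_factors(specs, [0.3] * 9)
        a = _agent_attributes(rf, 100, master_seed=9)
        b = _agent_attributes(rf, 100, master_seed=9)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])


def _rf(specs, **over):
    """Run factors at mid coordinates with named value overrides."""
    u = {"RETIREMENT": 0.5, "PRODUCTION": 0.5, "TENURE": 0.5, "DE": 0.5,
         "OWA": 0.5, "LAND": 0.5, "BID": 0.5, "EBI": 0.5, "n": 0.5}
    names = [s.name for s in specs]
    rf = resolve_run_factors(specs, [u[n] for n in names])
    for k, v in over.items():
        setattr(rf, k, v)
    return rf


class TestSimulation:
    def test_deterministic(self, small_prepared, specs):
        rf = _rf(specs, owa_rule=0, land_fraction=0.6)
        a = run_simulation(small_prepared, rf, master_seed=4)
        b = run_simulation(small_prepared, rf, master_seed=4)
        assert a.area_units == b.area_units
        np.testing.assert_array_equal(a.landuse, b.landuse)
        assert a.accepted_per_year == b.accepted_per_year

    def test_no_acceptances_when_cap_zero(self, small_prepared, specs):
        rf = _rf(specs, owa_rule=0, n=0)
        res = run_simulation(small_prepared, rf, master_seed=4)
        assert res.area_units == 0
        assert not np.any(res.landuse == LandUse.FALLOW)

    def test_area_equals_fallow_count(self, small_prepared, specs):
        rf = _rf(specs, owa_rule=0, land_fraction=0.8)
        res = run_simulation(small_prepared, rf, master_seed=4)
        assert res.area_units == int(np.sum(res.landuse == LandUse.FALLOW))
        assert res.area_acres == pytest.approx(res.area_units * 900 / 4046.8564)

    def test_conversion_conserves_other_classes(self, small_landscape,
                                                small_prepared, specs):
        rf = _rf(specs, owa_rule=0, land_fraction=0.9)
        res = run_simulation(small_prepared, rf, master_seed=4)
        before = small_landscape.landuse
        changed = res.landuse != before
        assert res.area_units > 0
        # only crop/pasture cells may change, and only into fallow
        assert np.all(np.isin(before[changed], [LandUse.CROP, LandUse.PASTURE]))
        assert np.all(res.landuse[changed] == LandUse.FALLOW)
        elig_total = int(eligibility_mask(before).sum())
        assert res.area_units <= elig_total

    def test_yearly_caps_and_monotonicity(self, desk_prepared, specs):
        rf = _rf(specs, owa_rule=0, land_fraction=0.5)
        res = run_simulation(desk_prepared, rf, master_seed=4)
        assert all(a <= rf.n for a in res.accepted_per_year)
        assert all(c >= 0 for c in res.converted_units_per_year)
        assert sum(res.accepted_per_year) <= 10 * rf.n

    def test_area_monotone_in_offer_cap(self, desk_prepared, specs):
        """Raising the annual acceptance cap never lowers the final fallow
        area (paired common-seed sweep)."""
        areas = []
        for n in (18, 23, 28):
            rf = _rf(specs, owa_rule=0, land_fraction=0.5, n=n)
            areas.append(
                run_simulation(desk_prepared, rf, master_seed=4).area_units
            )
        assert areas == sorted(areas)

    def test_model_wrapper_pure(self, small_prepared, specs):
        model = make_model(small_prepared, specs, master_seed=3)
        u = np.full(9, 0.21)
        assert model(u) == model(u)
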