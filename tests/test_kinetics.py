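"""Analytic nonterminal-model layer: drift law, composition, inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from ppekinetics import (
    MonomerSpec,
    RateSet,
    composition_curve,
    conversion_state,
    drift,
    feed_for_final_composition,
    rateset_from_ratio_table,
    ratios_from_delta,
    survival_from_conversion,
)

from conftest import binary_rates, pair_species


class TestDrift:
    @pytest.mark.parametrize(
        "r, a, expected",
        [
            (7.3, 1.0, 1.0),          # nothing consumed
            (1.0, 0.37, 0.37),        # equal rates drift identically
            (2.0, 0.25, 0.5),         # 0.25 ** (1/2)
        ],
    )
    def test_known_values(self, r, a, expected):
        assert drift(r, a) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("r", [0.0, -1.0, math.inf, math.nan])
    def test_bad_ratio_rejected(self, r):
        with pytest.raises(ValueError):
            drift(r, 0.5)

    @pytest.mark.parametrize("a", [0.0, -0.1, 1.5])
    def test_bad_survival_rejected(self, a):
        with pytest.raises(ValueError):
            drift(2.0, a)

    @settings(derandomize=True, max_examples=200)
    @given(
        r=st.floats(min_value=0.02, max_value=44.0),
        a=st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_involution_under_role_swap(self, r, a):
        # drifting B from A and then A from B must return the start
        assert drift(1.0 / r, drift(r, a)) == pytest.approx(a, abs=1e-12)


class TestRatiosFromDelta:
    @pytest.mark.parametrize(
        "delta, r1",
        [
            (0.0, 1.0),
            (24.0, 24.041594578792296),   # (24 + sqrt(580)) / 2
            (5.0, 5.192582403567252),     # (5 + sqrt(29)) / 2
        ],
    )
    def test_quadratic_solution(self, delta, r1):
        got1, got2 = ratios_from_delta(delta)
        assert got1 == pytest.approx(r1, rel=1e-12)
        assert got1 * got2 == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(delta=st.floats(min_value=0.0, max_value=100.0))
    def test_reproduces_delta(self, delta):
        r1, r2 = ratios_from_delta(delta)
        assert r1 - r2 == pytest.approx(delta, abs=1e-12)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            ratios_from_delta(-0.5)


class TestRateSet:
    def test_pairwise_ratios_transitive(self):
        species = tuple(MonomerSpec(n, 100.0) for n in "ABC")
        rs = RateSet(species, (4.9, 2.3, 1.0))
        assert rs.ratio("A", "C") == rs.ratio("A", "B") * rs.ratio("B", "C")
        assert rs.ratio("A", "B") * rs.ratio("B", "A") == pytest.approx(1.0, abs=1e-15)

    def test_from_adjacent_ratios(self):
        species = tuple(MonomerSpec(n, 100.0) for n in "ABC")
        rs = RateSet.from_ratios(species, [2.0, 3.0])
        assert rs.k == (6.0, 3.0, 1.0)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ValueError):
            RateSet(pair_species(), (1.0, 0.0))

    def test_rejects_duplicate_names(self):
        sp = (MonomerSpec("A", 1.0), MonomerSpec("A", 2.0))
        with pytest.raises(ValueError):
            RateSet(sp, (1.0, 1.0))


class TestConversionState:
    def test_symmetric_midpoint(self):
        st_ = conversion_state(binary_rates(1.0), (0.5, 0.5), 0.5)
        assert st_.X == pytest.approx(0.5, abs=1e-15)
        assert st_.f == pytest.approx((0.5, 0.5), abs=1e-15)
        assert st_.F == pytest.approx((0.5, 0.5), abs=1e-15)

    def test_start_point_is_feed(self):
        st_ = conversion_state(binary_rates(4.9), (0.55, 0.45), 1.0)
        assert st_.X == 0.0
        assert st_.f == pytest.approx((0.55, 0.45), abs=1e-15)
        assert st_.F == pytest.approx((0.55, 0.45), abs=1e-15)  # continuous limit

    def test_hand_computed_state(self):
        # k=(2,1), a_ref=0.25: a_B = 0.5, X = 1 - .5*.25 - .5*.5 = 0.625,
        # F_A = .5*.75/.625 = 0.6
        st_ = conversion_state(binary_rates(2.0), (0.5, 0.5), 0.25)
        assert st_.X == pytest.approx(0.625, abs=1e-14)
        assert st_.F[0] == pytest.approx(0.6, abs=1e-14)

    @settings(derandomize=True, max_examples=100)
    @given(
        r=st.floats(min_value=0.05, max_value=20.0),
        f0a=st.floats(min_value=0.05, max_value=0.95),
        a=st.floats(min_value=1e-4, max_value=1.0),
    )
    def test_mass_balance(self, r, f0a, a):
        f0 = (f0a, 1.0 - f0a)
        st_ = conversion_state(binary_rates(r), f0, a)
        consumed = sum(fi * (1.0 - ai) for fi, ai in zip(f0, st_.survival))
        assert consumed == pytest.approx(st_.X, abs=1e-12)


def _ode_cumulative_fraction(r: float, f0, X_targets):
    """Independent oracle: integrate dA/dt = -r A, dB/dt = -B numerically."""

    def rhs(_, y):
        return [-r * y[0], -y[1]]

    sol = solve_ivp(
        rhs, (0.0, 50.0), [f0[0], f0[1]], dense_output=True,
        rtol=1e-12, atol=1e-14, max_step=0.05,
    )
    out = []
    for X in X_targets:
        lo, hi = 0.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            a, b = sol.sol(mid)
            if 1.0 - a - b < X:
                lo = mid
            else:
                hi = mid
        a, b = sol.sol(0.5 * (lo + hi))
        out.append((f0[0] - a) / X)
    return np.array(out)


class TestCompositionCurve:
    def test_equal_rates_curve_is_flat(self):
        curve = composition_curve(binary_rates(1.0), (0.5, 0.5), 51)
        assert np.allclose(curve.f[:, 0], 0.5, atol=1e-12)
        assert np.allclose(curve.F[:, 0], 0.5, atol=1e-12)

    def test_ternary_symmetric_curve_is_flat(self):
        species = tuple(MonomerSpec(n, 100.0) for n in "ABC")
        rs = RateSet(species, (1.0, 1.0, 1.0))
        curve = composition_curve(rs, (1 / 3, 1 / 3, 1 / 3), 31)
        assert np.allclose(curve.f, 1 / 3, atol=1e-12)

    def test_row_sums_and_monotone_incorporation(self):
        curve = composition_curve(binary_rates(5.19), (0.4, 0.6), 101)
        assert np.max(np.abs(curve.f.sum(axis=1) - 1)) < 1e-10
        assert np.max(np.abs(curve.F.sum(axis=1) - 1)) < 1e-10
        incorporated = curve.F * curve.X[:, None]
        assert np.all(np.diff(incorporated, axis=0) >= -1e-12)

    @pytest.mark.parametrize("r", [0.1, 0.5, 2.0, 5.0, 20.0])
    def test_agrees_with_ode_oracle(self, r):
        f0 = (0.5, 0.5)
        X_grid = np.linspace(0.1, 0.9, 9)
        oracle = _ode_cumulative_fraction(r, f0, X_grid)
        a_ref = survival_from_conversion(binary_rates(r), f0, X_grid)
        ours = np.array(
            [conversion_state(binary_rates(r), f0, a).F[0] for a in a_ref]
        )
        assert np.max(np.abs(ours - oracle)) < 1e-6

    def test_golden_ratio_midpoint_matches_ode(self):
        # r solving r - 1/r = 5 at the X = 0.5 midpoint
        r = (5.0 + math.sqrt(29.0)) / 2.0
        oracle = _ode_cumulative_fraction(r, (0.5, 0.5), [0.5])[0]
        a = survival_from_conversion(binary_rates(r), (0.5, 0.5), 0.5)
        ours = conversion_state(binary_rates(r), (0.5, 0.5), a).F[0]
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_requires_two_grid_points(self):
        with pytest.raises(ValueError):
            composition_curve(binary_rates(2.0), (0.5, 0.5), 1)


class TestInversions:
    @pytest.mark.parametrize("r", [0.1, 1.0, 5.19, 24.04])
    def test_survival_inversion_round_trip(self, r):
        rs = binary_rates(r)
        f0 = (0.45, 0.55)
        for X in [0.0, 0.2, 0.6, 0.93]:
            a = survival_from_conversion(rs, f0, X)
            assert conversion_state(rs, f0, a).X == pytest.approx(X, abs=1e-10)

    def test_feed_inversion_hits_target_composition(self):
        rs = binary_rates(5.192582403567252)
        F_target = np.array([48.0, 41.0]) / 89.0
        f0 = feed_for_final_composition(rs, F_target, 0.93)
        a = survival_from_conversion(rs, f0, 0.93)
        st_ = conversion_state(rs, f0, a)
        assert np.asarray(st_.F) == pytest.approx(F_target, abs=1e-9)

    def test_feed_inversion_ternary(self):
        species = tuple(MonomerSpec(n, 100.0) for n in "ABC")
        rs = RateSet(species, (184.0, 13.1, 1.0))
        F_target = np.array([51.0, 29.0, 13.0]) / 93.0
        f0 = feed_for_final_composition(rs, F_target, 0.73)
        a = survival_from_conversion(rs, f0, 0.73)
        st_ = conversion_state(rs, f0, a)
        assert np.asarray(st_.F) == pytest.approx(F_target, abs=1e-9)


class TestRatioProjection:
    def test_consistent_table_recovered_exactly(self):
        species = tuple(MonomerSpec(n, 100.0) for n in "ABC")
        truth = RateSet(species, (6.0, 3.0, 1.0))
        table = {
            (x, y): truth.ratio(x, y)
            for x in "ABC" for y in "ABC" if x != y
        }
        rs = rateset_from_ratio_table(species, table)
        assert np.allclose(rs.k, truth.k, rtol=1e-12)

    def test_inconsistent_table_projects_to_geometric_mean(self):
        species = tuple(MonomerSpec(n, 100.0) for n in "ABC")
        # perturb r_AC away from transitive consistency
        table = {("A", "B"): 2.0, ("B", "C"): 2.0, ("A", "C"): 8.0}
        rs = rateset_from_ratio_table(species, table)
        # log-LS projection splits the inconsistency evenly
        assert rs.ratio("A", "B") == pytest.approx(rs.ratio("B", "C"), rel=1e-9)
        assert rs.ratio("A", "C") == pytest.approx(
            rs.ratio("A", "B") * rs.ratio("B", "C"), rel=1e-12
        )
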