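"""Lea-Catcheside protraction, BED and equivalent-dose calculators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from sirtlq.protraction import (
    EquivalenceParams,
    ProtractionParams,
    bed_fractionated,
    bed_y90,
    eqd,
    eqd_curve,
    equivalent_y90_dose,
    g_factor,
    g_infinity,
    rbe_max,
    solve_trep,
)

T_PHYS = 64.1
DLD1 = EquivalenceParams(rbe_max=0.388, g_inf=0.0377, ab_ebrt=14.4, d=2.0)
HT29 = EquivalenceParams(rbe_max=1.800, g_inf=0.0033, ab_ebrt=1.81, d=2.0)


def g_double_quadrature(t_rep: float, t_phys: float, T: float) -> float:
    """Independent oracle: numerical double integral of the Lea-Catcheside
    definition for dose rate proportional to exp(-lambda t)."""
    lam = math.log(2) / t_phys
    mu = math.log(2) / t_rep
    inner = lambda t: quad(
        lambda s: math.exp(-lam * s - mu * (t - s)), 0.0, t,
        epsabs=1e-14, epsrel=1e-13, limit=200,
    )[0]
    total_dose = quad(lambda t: math.exp(-lam * t), 0.0, T, epsabs=1e-14, epsrel=1e-13)[0]
    interaction = quad(
        lambda t: math.exp(-lam * t) * inner(t), 0.0, T,
        epsabs=1e-15, epsrel=1e-12, limit=200,
    )[0]
    return 2.0 * interaction / total_dose**2


class TestGFactor:
    @pytest.mark.parametrize(
        "t_rep, expected",
        [(2.51, 0.0577), (0.21, 0.0051)],
    )
    def test_published_six_day_values(self, t_rep, expected):
        # T_rep inputs are printed to two decimals; G is near-linear in
        # T_rep, so the forward evaluation inherits that rounding (~2%)
        assert g_factor(t_rep, T_PHYS, 144.0) == pytest.approx(expected, rel=0.02)

    def test_matches_double_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(12):
            t_rep = math.exp(rng.uniform(math.log(0.05), math.log(50.0)))
            T = math.exp(rng.uniform(0.0, math.log(500.0)))
            oracle = g_double_quadrature(t_rep, T_PHYS, T)
            assert g_factor(t_rep, T_PHYS, T) == pytest.approx(oracle, rel=1e-8)

    def test_acute_limit_is_one(self):
        assert g_factor(2.51, T_PHYS, 1e-3) == pytest.approx(1.0, rel=1e-4)

    def test_no_repair_limit_is_one(self):
        assert g_factor(1e7, T_PHYS, 144.0) == pytest.approx(1.0, rel=1e-5)

    def test_converges_to_g_infinity(self):
        g_lim = g_factor(2.51, T_PHYS, 1e4)
        assert g_lim == pytest.approx(g_infinity(2.51, T_PHYS), rel=1e-4)
        assert g_factor(2.51, T_PHYS, math.inf) == g_infinity(2.51, T_PHYS)

    def test_equal_rates_branch_is_continuous(self):
        g_mid = g_factor(T_PHYS, T_PHYS, 144.0)
        g_lo = g_factor(T_PHYS * (1 - 1e-6), T_PHYS, 144.0)
        g_hi = g_factor(T_PHYS * (1 + 1e-6), T_PHYS, 144.0)
        assert g_lo < g_mid < g_hi
        assert g_hi - g_lo == pytest.approx(0.0, abs=1e-5)
        oracle = g_double_quadrature(T_PHYS, T_PHYS, 144.0)
        assert g_mid == pytest.approx(oracle, rel=1e-8)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        t_rep=st.floats(0.05, 50.0),
        factor=st.floats(1.01, 5.0),
        T=st.floats(1.0, 500.0),
    )
    def test_bounded_and_increasing_in_repair_half_time(self, t_rep, factor, T):
        g1 = g_factor(t_rep, T_PHYS, T)
        g2 = g_factor(t_rep * factor, T_PHYS, T)
        assert 0.0 < g1 <= 1.0
        assert g2 > g1  # slower repair -> more interaction -> larger G

    def test_domain_errors(self):
        for bad in [(0.0, T_PHYS, 144.0), (2.51, -1.0, 144.0), (2.51, T_PHYS, 0.0)]:
            with pytest.raises(ValueError):
                g_factor(*bad)


class TestGInfinity:
    @pytest.mark.parametrize("t_rep, expected", [(2.51, 0.0377), (0.21, 0.0033)])
    def test_published_values(self, t_rep, expected):
        assert g_infinity(t_rep, T_PHYS) == pytest.approx(expected, abs=5e-5)

    def test_equal_half_lives_give_half(self):
        assert g_infinity(10.0, 10.0) == pytest.approx(0.5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            g_infinity(-1.0, T_PHYS)

    def test_params_container_consistency(self):
        p = ProtractionParams(T_rep=2.51, T_exposure=144.0)
        assert p.g == pytest.approx(g_factor(2.51, T_PHYS, 144.0))
        assert p.g_inf == pytest.approx(g_infinity(2.51, T_PHYS))
        assert p.mu == pytest.approx(math.log(2) / 2.51)


class TestSolveTrep:
    @pytest.mark.parametrize(
        "beta_rnt, beta_ebrt, expected_h",
        [(0.00109, 0.0189, 2.51), (0.000141, 0.0276, 0.21)],
    )
    def test_published_repair_half_times(self, beta_rnt, beta_ebrt, expected_h):
        t_rep = solve_trep(beta_rnt / beta_ebrt, T_phys=T_PHYS, T=144.0)
        assert round(t_rep, 2) == pytest.approx(expected_h)

    @pytest.mark.parametrize("t_rep", [0.1, 1.0, 5.0, 20.0])
    def test_roundtrip_inverse_identity(self, t_rep):
        g = g_factor(t_rep, T_PHYS, 144.0)
        assert solve_trep(g, T_PHYS, 144.0) == pytest.approx(t_rep, rel=1e-6)

    @pytest.mark.parametrize("g", [0.0, 1.0, -0.2, 1.5])
    def test_unattainable_targets_rejected(self, g):
        with pytest.raises(ValueError):
            solve_trep(g, T_PHYS, 144.0)


class TestBedAndEqd:
    def test_rbe_max(self):
        assert rbe_max(0.106, 0.273) == pytest.approx(0.388, abs=5e-4)
        assert rbe_max(0.090, 0.050) == pytest.approx(1.800)
        assert rbe_max(0.2, 0.2) == 1.0
        with pytest.raises(ValueError):
            rbe_max(0.1, 0.0)

    def test_bed_fractionated(self):
        assert bed_fractionated(30, 0.0, 14.4) == 0.0
        assert bed_fractionated(30, 2.0, 14.4) == pytest.approx(60 * (1 + 2 / 14.4))
        assert bed_fractionated(30, 2.0, 1e9) == pytest.approx(60.0, rel=1e-6)

    def test_bed_y90(self):
        assert bed_y90(0.0, DLD1) == 0.0
        assert bed_y90(60.0, DLD1) == pytest.approx(60 * (0.388 + 0.0377 * 60 / 14.4), rel=1e-12)
        assert bed_y90(60.0, DLD1) == pytest.approx(32.705, abs=1e-3)
        pure_linear = EquivalenceParams(rbe_max=0.5, g_inf=0.0, ab_ebrt=10.0)
        assert bed_y90(40.0, pure_linear) == pytest.approx(20.0)

    def test_eqd_published_values(self):
        assert eqd(60.0, DLD1) == pytest.approx(28.7, abs=0.05)
        h29_10 = EquivalenceParams(rbe_max=1.800, g_inf=0.0033, ab_ebrt=1.81, d=10.0)
        assert eqd(60.0, h29_10) == pytest.approx(17.6, abs=0.05)

    def test_single_fraction_self_equivalence(self):
        p = EquivalenceParams(rbe_max=1.0, g_inf=1.0, ab_ebrt=10.0, d=5.0)
        assert eqd(5.0, p) == pytest.approx(5.0)

    def test_zero_fraction_size_reduces_to_bed(self):
        p = EquivalenceParams(rbe_max=0.388, g_inf=0.0377, ab_ebrt=14.4, d=0.0)
        assert eqd(60.0, p) == pytest.approx(bed_y90(60.0, p))


class TestEquivalentY90Dose:
    def test_zero_effect(self):
        assert equivalent_y90_dose(0.0, 0.129, 0.0) == 0.0

    def test_linear_case(self):
        assert equivalent_y90_dose(2.58, 0.129, 0.0) == pytest.approx(20.0)

    def test_quadratic_root_oracle(self):
        # effect of a single 8 Gy acute fraction on HT-29, mapped to Y-90 dose
        effect = 0.050 * 8 + 0.0276 * 64
        d = equivalent_y90_dose(effect, 0.090, 0.000141)
        roots = np.roots([0.000141, 0.090, -effect])
        positive = roots[roots > 0]
        assert d == pytest.approx(float(positive[0]), rel=1e-10)
        assert 0.000141 * d**2 + 0.090 * d == pytest.approx(effect, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            equivalent_y90_dose(-1.0, 0.1, 0.0)
        with pytest.raises(ValueError):
            equivalent_y90_dose(1.0, 0.0, 0.0)


class TestEqdCurve:
    def test_empty_grid(self):
        assert len(eqd_curve([], DLD1)) == 0

    def test_matches_scalar_eqd_and_flags_extrapolation(self):
        grid = [0.0, 10.0, 32.0, 60.0]
        curve = eqd_curve(grid, DLD1)
        for _, row in curve.iterrows():
            assert row["eqd_Gy"] == pytest.approx(eqd(row["dose_Gy"], DLD1))
        assert list(curve["extrapolated"]) == [False, False, False, True]

    def test_strictly_increasing(self):
        grid = np.linspace(0.0, 100.0, 51)
        curve = eqd_curve(grid, HT29)
        assert np.all(np.diff(curve["eqd_Gy"]) > 0)
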