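"""Unit and property tests for the isotopologue mixing model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import fsolve

from n15flux import constants as c
from n15flux.errors import (
    BelowDetectionError,
    DomainError,
    InconsistentInputError,
    InvalidRecordError,
)
from n15flux.isotope import (
    DeltaRatios,
    IonCurrentRecord,
    IsotopologueFractions,
    RatioPair,
    delta_ratios,
    estimate_pool_enrichment,
    estimate_pool_fraction,
    fractions_from_atom_fraction,
    fractions_from_ratio_pair,
    invert_mixing,
    mix_pools,
    n2o_isotopologue_fractions,
    n2o_mixture_fractions,
    natural_ratio_pair,
    nitrogen_ratio_pair,
    oxygen_corrected_deltas,
    ratio_pair_from_fractions,
    ratios_from_currents,
)


def brute_force_invert(deltas, background):
    """Independent 2D numerical inversion of the forward mixing model.

    Solves the two delta equations for (a, d) with fsolve, using only
    the forward arithmetic written out longhand.
    """
    bl = 1.0 / (1.0 + background.r_mid + background.r_heavy)
    bm, bh = background.r_mid * bl, background.r_heavy * bl

    def equations(x):
        a, d = x
        fl = (1 - d) * bl + d * (1 - a) ** 2
        fm = (1 - d) * bm + d * 2 * a * (1 - a)
        fh = (1 - d) * bh + d * a * a
        return (
            fm / fl - background.r_mid - deltas.delta_mid,
            fh / fl - background.r_heavy - deltas.delta_heavy,
        )

    for d0 in (1e-3, 0.1, 0.5, 0.9):
        (a, d), info, ier, _ = fsolve(
            equations, x0=(0.5, d0), full_output=True, xtol=1e-13
        )
        if ier == 1:
            return a, d
    raise AssertionError("fsolve oracle did not converge")


class TestRatiosFromCurrents:
    @pytest.mark.parametrize(
        "currents, expected",
        [
            ((1.0, 0.007293, 1.34e-5), (0.007293, 1.34e-5)),
            ((2.0, 0.0, 0.0), (0.0, 0.0)),
            ((4.0, 2.0, 1.0), (0.5, 0.25)),
        ],
    )
    def test_ratio_definition(self, currents, expected):
        rec = IonCurrentRecord("CH1", "N2O", *currents)
        rp = ratios_from_currents(rec)
        assert rp.r_mid == pytest.approx(expected[0])
        assert rp.r_heavy == pytest.approx(expected[1])

    def test_zero_major_beam_names_source(self):
        rec = IonCurrentRecord("CH7", "N2", 0.0, 1.0, 1.0)
        with pytest.raises(InvalidRecordError, match="CH7"):
            ratios_from_currents(rec)

    def test_negative_minor_current_rejected_at_construction(self):
        with pytest.raises(InvalidRecordError):
            IonCurrentRecord("CH1", "N2", 1.0, -0.1, 0.0)


class TestBinomialPairing:
    @pytest.mark.parametrize(
        "a, expected",
        [
            (0.0, (1.0, 0.0, 0.0)),
            (0.5, (0.25, 0.5, 0.25)),
            (1.0, (0.0, 0.0, 1.0)),
            # natural abundance, straight binomial arithmetic
            (0.0036630, (0.9926874, 0.0072992, 1.3418e-5)),
        ],
    )
    def test_fractions(self, a, expected):
        f = fractions_from_atom_fraction(a)
        assert f.f_light == pytest.approx(expected[0], rel=1e-4)
        assert f.f_mid == pytest.approx(expected[1], rel=1e-4)
        assert f.f_heavy == pytest.approx(expected[2], rel=1e-3, abs=1e-15)

    @pytest.mark.parametrize("a", [-0.01, 1.01])
    def test_domain(self, a):
        with pytest.raises(DomainError):
            fractions_from_atom_fraction(a)

    @given(st.floats(0.0, 1.0))
    def test_conservation(self, a):
        f = fractions_from_atom_fraction(a)
        assert f.f_light + f.f_mid + f.f_heavy == pytest.approx(1.0, abs=1e-12)


class TestMixing:
    def test_endpoints_and_mean(self):
        bg = IsotopologueFractions(1.0, 0.0, 0.0)
        pool = fractions_from_atom_fraction(0.5)
        assert mix_pools(bg, pool, 0.0) == bg
        assert mix_pools(bg, pool, 1.0) == pool
        mid = mix_pools(bg, pool, 0.5)
        assert (mid.f_light, mid.f_mid, mid.f_heavy) == (0.625, 0.25, 0.125)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.05, 0.95))
    def test_linearity_in_d(self, d1, d2, a):
        bg = fractions_from_atom_fraction(c.NAT_15N)
        pool = fractions_from_atom_fraction(a)
        mid_d = (d1 + d2) / 2
        direct = mix_pools(bg, pool, mid_d)
        m1, m2 = mix_pools(bg, pool, d1), mix_pools(bg, pool, d2)
        assert direct.f_heavy == pytest.approx(
            (m1.f_heavy + m2.f_heavy) / 2, abs=1e-12
        )

    def test_domain(self):
        bg = fractions_from_atom_fraction(0.0)
        with pytest.raises(DomainError):
            mix_pools(bg, bg, 1.5)


class TestDeltaRatios:
    def test_ambient_sample_gives_zero(self, natural_bg):
        dd = delta_ratios(natural_bg, natural_bg)
        assert dd.delta_mid == 0.0 and dd.delta_heavy == 0.0

    def test_component_subtraction(self):
        dd = delta_ratios(
            RatioPair(0.00735 + 1e-6, 1.34e-5 + 2e-6), RatioPair(0.00735, 1.34e-5)
        )
        assert dd.delta_mid == pytest.approx(1e-6)
        assert dd.delta_heavy == pytest.approx(2e-6)

    def test_forward_model_deltas_match_brute_force(self, natural_bg):
        # mixture arithmetic written out longhand as the oracle
        a, d = 0.6, 0.01
        bg = fractions_from_atom_fraction(c.NAT_15N)
        fl = (1 - d) * bg.f_light + d * (1 - a) ** 2
        fm = (1 - d) * bg.f_mid + d * 2 * a * (1 - a)
        fh = (1 - d) * bg.f_heavy + d * a * a
        expected = (fm / fl - natural_bg.r_mid, fh / fl - natural_bg.r_heavy)
        mix = mix_pools(bg, fractions_from_atom_fraction(a), d)
        dd = delta_ratios(ratio_pair_from_fractions(mix), natural_bg)
        assert dd.delta_mid == pytest.approx(expected[0], rel=1e-12)
        assert dd.delta_heavy == pytest.approx(expected[1], rel=1e-12)


class TestPoolEnrichment:
    def test_equal_deltas_plain_form(self):
        # x = 1 in the unlabelled-background closed form
        a = estimate_pool_enrichment(
            DeltaRatios(1e-5, 1e-5), background_enrichment=0.0
        )
        assert a == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("a_true, d", [(0.6, 0.01), (0.5, 1e-4)])
    def test_recovery_within_one_percent(self, a_true, d, forward_deltas):
        a = estimate_pool_enrichment(forward_deltas(a_true, d))
        assert a == pytest.approx(a_true, rel=0.01)

    @pytest.mark.parametrize(
        "deltas",
        [DeltaRatios(0.0, 1e-6), DeltaRatios(1e-6, 0.0), DeltaRatios(-1e-6, -1e-6)],
    )
    def test_non_positive_deltas_flagged(self, deltas):
        with pytest.raises(BelowDetectionError):
            estimate_pool_enrichment(deltas)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    def test_monotone_in_x(self, x1, x2):
        base = 1e-5
        a1 = estimate_pool_enrichment(DeltaRatios(base, base * x1))
        a2 = estimate_pool_enrichment(DeltaRatios(base, base * x2))
        if x1 < x2:
            assert a1 < a2
        elif x1 > x2:
            assert a1 > a2


class TestPoolFraction:
    def test_detection_limit_working_point(self):
        # ΔR / a² at the 30R detection limit with 50% enrichment
        d = estimate_pool_fraction(DeltaRatios(1e-6, 1.41e-6), 0.5)
        assert d == pytest.approx(5.64e-6)

    def test_zero_excess(self):
        assert estimate_pool_fraction(DeltaRatios(0.0, 0.0), 0.5) == 0.0

    def test_exact_variant_recovers_d(self, forward_deltas, natural_bg):
        dd = forward_deltas(0.6, 0.02)
        d = estimate_pool_fraction(dd, 0.6, background=natural_bg, method="exact")
        assert d == pytest.approx(0.02, rel=1e-9)

    def test_simple_variant_within_one_percent_at_small_d(self, forward_deltas):
        dd = forward_deltas(0.6, 0.001)
        assert estimate_pool_fraction(dd, 0.6) == pytest.approx(0.001, rel=0.04)

    def test_inconsistent_d_above_one(self):
        with pytest.raises(InconsistentInputError):
            estimate_pool_fraction(DeltaRatios(1.0, 1.0), 0.5)

    def test_zero_enrichment_is_domain_error(self):
        with pytest.raises(DomainError):
            estimate_pool_fraction(DeltaRatios(1e-6, 1e-6), 0.0)


class TestInversion:
    @pytest.mark.parametrize(
        "a, d", [(0.6, 0.01), (0.5, 1e-4), (0.05, 0.05), (0.95, 1e-6), (0.48, 0.9)]
    )
    def test_against_independent_fsolve_oracle(
        self, a, d, forward_deltas, natural_bg
    ):
        dd = forward_deltas(a, d)
        a_est, d_est = invert_mixing(dd, natural_bg)
        a_ref, d_ref = brute_force_invert(dd, natural_bg)
        assert a_est == pytest.approx(a_ref, rel=1e-6)
        assert d_est == pytest.approx(d_ref, rel=1e-4, abs=1e-12)
        assert a_est == pytest.approx(a, rel=1e-7)
        assert d_est == pytest.approx(d, rel=1e-6)

    @given(st.floats(0.05, 0.95), st.floats(1e-6, 0.05))
    def test_round_trip_closed_form_vs_exact(self, forward_deltas, natural_bg, a, d):
        """Closed-form and numerical inversion agree within 1% relative."""
        dd = forward_deltas(a, d)
        a_cf = estimate_pool_enrichment(dd)
        a_ex, d_ex = invert_mixing(dd, natural_bg)
        assert a_cf == pytest.approx(a, rel=0.01)
        assert a_ex == pytest.approx(a, rel=0.01)
        assert a_cf == pytest.approx(a_ex, rel=0.01)
        d_cf = estimate_pool_fraction(dd, a_cf, background=natural_bg, method="exact")
        assert d_cf == pytest.approx(d, rel=0.01)
        assert d_ex == pytest.approx(d, rel=0.01)


class TestN2OIsotopologues:
    def test_distribution_against_enumeration(self):
        """Brute-force enumeration over (N,N,O) isotope combinations."""
        a15, a17, a18 = 0.5, c.NAT_17O, c.NAT_18O
        pn = {14: 1 - a15, 15: a15}
        po = {16: 1 - a17 - a18, 17: a17, 18: a18}
        masses = {}
        for m1, p1 in pn.items():
            for m2, p2 in pn.items():
                for mo, p3 in po.items():
                    key = m1 + m2 + mo
                    masses[key] = masses.get(key, 0.0) + p1 * p2 * p3
        f = n2o_isotopologue_fractions(a15)
        for i, mass in enumerate(range(44, 49)):
            assert f[i] == pytest.approx(masses[mass], rel=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_oxygen_correction_recovers_nitrogen_deltas(self):
        """With O stripped, measured N2O deltas equal the pure N-pair deltas."""
        a_pool, d = 0.48, 0.3
        f_bg = n2o_mixture_fractions(a_pool, 0.0)
        f_mix = n2o_mixture_fractions(a_pool, d)
        measured_bg = RatioPair(f_bg[1] / f_bg[0], f_bg[2] / f_bg[0])
        measured = RatioPair(f_mix[1] / f_mix[0], f_mix[2] / f_mix[0])
        dd = oxygen_corrected_deltas(delta_ratios(measured, measured_bg))
        # nitrogen-only oracle
        bgn = fractions_from_atom_fraction(c.NAT_15N)
        mixn = mix_pools(bgn, fractions_from_atom_fraction(a_pool), d)
        dd_n = delta_ratios(
            ratio_pair_from_fractions(mixn), ratio_pair_from_fractions(bgn)
        )
        assert dd.delta_mid == pytest.approx(dd_n.delta_mid, rel=1e-9)
        assert dd.delta_heavy == pytest.approx(dd_n.delta_heavy, rel=1e-9)
        # and the stripped background matches the binomial N background
        bg_n_est = nitrogen_ratio_pair(measured_bg)
        assert bg_n_est.r_mid == pytest.approx(natural_ratio_pair().r_mid, rel=1e-9)
        assert bg_n_est.r_heavy == pytest.approx(
            natural_ratio_pair().r_heavy, rel=1e-6
        )

    def test_fractions_ratio_round_trip(self):
        f = fractions_from_atom_fraction(0.3)
        rt = fractions_from_ratio_pair(ratio_pair_from_fractions(f))
        assert rt.f_light == pytest.approx(f.f_light, rel=1e-12)
        assert rt.f_mid == pytest.approx(f.f_mid, rel=1e-12)
        assert rt.f_heavy == pytest.approx(f.f_heavy, rel=1e-12)
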