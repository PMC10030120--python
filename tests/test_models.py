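"""Unit and property tests of the closed-form assay models."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from fpnbind import models as m

conc = st.floats(1e-2, 1e6)
pos = st.floats(1e-3, 1e6)


class TestPolarization:
    @pytest.mark.parametrize(
        "f_para,f_perp,expected",
        [(300.0, 100.0, 500.0), (123.4, 123.4, 0.0), (200.0, 0.0, 1000.0)],
    )
    def test_known_values(self, f_para, f_perp, expected):
        pair = m.FPIntensityPair(f_para, f_perp)
        assert m.fp_from_intensities(pair) == pytest.approx(expected)

    def test_zero_total_intensity_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate well"):
            m.FPIntensityPair(0.0, 0.0)

    def test_negative_intensity_is_invalid(self):
        with pytest.raises(ValueError, match="invalid read"):
            m.FPIntensityPair(-1.0, 10.0)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    def test_bounded_and_antisymmetric(self, a, b):
        if a + b <= 0:
            return
        fp = m.fp_from_intensities(m.FPIntensityPair(a, b))
        assert -1000.0 <= fp <= 1000.0
        assert m.fp_from_intensities(m.FPIntensityPair(b, a)) == pytest.approx(
            -fp, abs=1e-9
        )


class TestDirectBinding:
    def test_zero_input_gives_background(self):
        p = m.DirectBindingParams(b_max=150, k_d=100, ns_slope=0.01, background=150)
        assert m.direct_binding_fp(0.0, p) == 150.0

    def test_half_saturation_identity(self):
        p = m.DirectBindingParams(b_max=150, k_d=100, ns_slope=0.0, background=150)
        assert m.direct_binding_fp(100.0, p) == pytest.approx(150 + 75)

    def test_direct_substitution(self):
        p = m.DirectBindingParams(b_max=150, k_d=100, ns_slope=0.01, background=150)
        assert m.direct_binding_fp(100.0, p) == pytest.approx(226.0)

    def test_monotone_for_nonnegative_ns(self):
        p = m.DirectBindingParams(b_max=100, k_d=50, ns_slope=0.02, background=10)
        x = np.geomspace(0.1, 1e5, 200)
        y = m.direct_binding_fp(x, p)
        assert np.all(np.diff(y) > 0)

    def test_negative_concentration_rejected(self):
        p = m.DirectBindingParams(b_max=100, k_d=50)
        with pytest.raises(ValueError, match="invalid concentration"):
            m.direct_binding_fp(-1.0, p)


class TestHill:
    def test_midpoint_with_study_plateaus(self):
        # shared displacement plateaus 225 and 307 mP: midpoint = 266 mP
        p = m.HillParams(bottom=225, top=307, log_ic50=2.1, hill_n=-1)
        assert m.hill_fp(10**2.1, p) == pytest.approx(266.0)

    def test_printed_form_value(self):
        p = m.HillParams(bottom=0, top=100, log_ic50=2, hill_n=1)
        assert m.hill_fp(1000.0, p) == pytest.approx(100 / 1.1)

    def test_negative_slope_gives_decreasing_displacement_curve(self):
        # convention check: hill_n < 0 runs top -> bottom with increasing dose
        p = m.HillParams(bottom=225, top=307, log_ic50=2, hill_n=-1)
        x = np.geomspace(0.1, 1e6, 100)
        y = m.hill_fp(x, p)
        assert np.all(np.diff(y) < 0)
        assert y[0] == pytest.approx(307, abs=0.5)
        assert y[-1] == pytest.approx(225, abs=0.5)

    def test_zero_dose_excluded(self):
        p = m.HillParams(bottom=0, top=1, log_ic50=1, hill_n=-1)
        with pytest.raises(ValueError, match="excluded from log-scale"):
            m.hill_fp(0.0, p)


class TestCompetition:
    def test_zero_competitor_saturation(self):
        p = m.CompetitionParams(l_dis=400, k_d_dis=100, k_d_x=25)
        assert m.competition_saturation(0.0, p) == pytest.approx(0.8)

    def test_half_displacement_at_closed_form_ic50(self):
        p = m.CompetitionParams(l_dis=400, k_d_dis=100, k_d_x=25)
        x_half = p.k_d_x * (1 + p.l_dis / p.k_d_dis)
        y0 = m.competition_saturation(0.0, p)
        assert m.competition_saturation(x_half, p) == pytest.approx(y0 / 2)

    def test_huge_competitor_kd_means_no_displacement(self):
        p = m.CompetitionParams(l_dis=400, k_d_dis=100, k_d_x=1e12)
        assert m.competition_saturation(500.0, p) == pytest.approx(0.8, rel=1e-6)

    @given(pos, pos, pos, conc, conc)
    def test_monotonicity_in_all_arguments(self, l, kdis, kx, x1, x2):
        lo, hi = sorted((x1, x2))
        if hi <= lo:
            return
        p = m.CompetitionParams(l_dis=l, k_d_dis=kdis, k_d_x=kx)
        assert m.competition_saturation(hi, p) <= m.competition_saturation(lo, p)
        # increasing in l_dis and k_d_x, decreasing in k_d_dis
        x = 10.0
        up_l = m.CompetitionParams(l_dis=l * 2, k_d_dis=kdis, k_d_x=kx)
        up_kx = m.CompetitionParams(l_dis=l, k_d_dis=kdis, k_d_x=kx * 2)
        up_kdis = m.CompetitionParams(l_dis=l, k_d_dis=kdis * 2, k_d_x=kx)
        y = m.competition_saturation(x, p)
        assert m.competition_saturation(x, up_l) >= y
        assert m.competition_saturation(x, up_kx) >= y
        assert m.competition_saturation(x, up_kdis) <= y


def _bisection_ic50(p: m.CompetitionParams) -> float:
    """Independent root-finding oracle for the half-displacement dose."""
    y0 = m.competition_saturation(0.0, p)
    f = lambda x: m.competition_saturation(x, p) - y0 / 2
    hi = 10.0
    while f(hi) > 0:
        hi *= 10
    return brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-15)


class TestImpliedIC50:
    @pytest.mark.parametrize(
        "l,kdis,kx,expected",
        [(400, 100, 25, 125.0), (400, 100, 150, 750.0)],
    )
    def test_study_parameter_values(self, l, kdis, kx, expected):
        p = m.CompetitionParams(l_dis=l, k_d_dis=kdis, k_d_x=kx)
        assert m.implied_ic50(p) == pytest.approx(expected, rel=1e-12)
        assert _bisection_ic50(p) == pytest.approx(expected, rel=1e-9)

    def test_vanishing_protein_limit(self):
        p = m.CompetitionParams(l_dis=1e-9, k_d_dis=100, k_d_x=25)
        assert m.implied_ic50(p) == pytest.approx(25.0, rel=1e-6)

    @given(pos, pos, pos)
    def test_kd_ic50_round_trip(self, l, kdis, kx):
        p = m.CompetitionParams(l_dis=l, k_d_dis=kdis, k_d_x=kx)
        ic50 = m.implied_ic50(p)
        assert m.kd_from_ic50(ic50, l, kdis) == pytest.approx(kx, rel=1e-9)

    @pytest.mark.parametrize("args", [(125, 400, 100, 25), (750, 400, 100, 150)])
    def test_kd_from_ic50_known_values(self, args):
        ic50, l, kdis, kx = args
        assert m.kd_from_ic50(ic50, l, kdis) == pytest.approx(kx)


class TestFractionalSaturation:
    def test_offset_maps_to_zero(self, wt_direct):
        fp0 = wt_direct.background + wt_direct.ns_slope * 400
        assert m.fractional_saturation_from_fp(fp0, wt_direct, 400) == pytest.approx(0.0)

    def test_inversion(self, wt_direct):
        fp = wt_direct.background + wt_direct.ns_slope * 400 + wt_direct.b_max * 0.8
        assert m.fractional_saturation_from_fp(fp, wt_direct, 400) == pytest.approx(0.8)

    def test_out_of_range_warns_but_keeps_raw(self, wt_direct):
        fp = wt_direct.background + wt_direct.ns_slope * 400 + wt_direct.b_max * 1.2
        with pytest.warns(UserWarning, match="outside"):
            y = m.fractional_saturation_from_fp(fp, wt_direct, 400)
        assert y == pytest.approx(1.2)

    def test_degenerate_conversion(self):
        p = m.DirectBindingParams(b_max=0.0, k_d=100.0)
        with pytest.raises(ValueError, match="degenerate conversion"):
            m.fractional_saturation_from_fp(1.0, p, 400)


class TestKineticsAndMelt:
    def test_mm_rate_identities(self):
        p = m.MichaelisParams(v_max=0.004, k_m=5.0)
        assert m.mm_rate(0.0, p) == 0.0
        assert m.mm_rate(5.0, p) == pytest.approx(0.002)
        assert m.mm_rate(45.0, p) == pytest.approx(0.9 * 0.004)

    def test_melt_midpoint_and_limits(self):
        p = m.MeltParams(t_m=47.0, slope=0.5, top=100.0, bottom=0.0)
        assert m.melt_fraction(47.0, p) == pytest.approx(50.0)
        assert m.melt_fraction(-200.0, p) == pytest.approx(100.0)
        assert m.melt_fraction(300.0, p) == pytest.approx(0.0)

    def test_spr_steady_state_and_half_life(self):
        p = m.SPRParams(k_on=1e5, k_off=0.05, r_max=100.0)
        kd = p.k_d  # 500 nM in M
        assert kd == pytest.approx(5e-7)
        r_inf = m.spr_response(1e6, kd, "association", p)
        assert r_inf == pytest.approx(50.0, rel=1e-6)
        t_half = np.log(2) / p.k_off
        assert m.spr_response(t_half, 0.0, "dissociation", p, r0=80.0) == pytest.approx(40.0)

    def test_spr_invalid_analyte(self):
        p = m.SPRParams(k_on=1e5, k_off=0.05, r_max=100.0)
        with pytest.raises(ValueError, match="invalid analyte"):
            m.spr_response(1.0, 0.0, "association", p)
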