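"""Tests of the melting, transport and SPR analyses."""

import numpy as np
import pytest

from fpnbind import models as m
from fpnbind import simulate
from fpnbind.assays import (
    MeltSeries,
    delta_tm,
    extract_initial_rate,
    fit_km,
    fit_melt,
    fit_spr,
)


class TestMelt:
    def test_noiseless_recovery(self):
        truth = m.MeltParams(t_m=47.0, slope=0.35, top=100.0, bottom=0.0)
        series = simulate.gen_melt(
            simulate.MeltDesign(truth=truth, noise_sd_pct=0.0), seed=1
        )
        res = fit_melt(series)
        assert res.params.t_m == pytest.approx(47.0, rel=1e-6)
        assert not res.extrapolated

    def test_apo_holo_shift(self):
        apo = fit_melt(simulate.gen_melt(
            simulate.MeltDesign(m.MeltParams(t_m=47.0, slope=0.35)), seed=2))
        holo = fit_melt(simulate.gen_melt(
            simulate.MeltDesign(m.MeltParams(t_m=52.0, slope=0.35),
                                condition="vamifeport"), seed=3))
        d, d_se = delta_tm(apo, holo)
        assert d == pytest.approx(5.0, abs=3 * d_se)
        # antisymmetry and SE propagation
        d_rev, d_rev_se = delta_tm(holo, apo)
        assert d_rev == pytest.approx(-d)
        assert d_se == pytest.approx(np.hypot(apo.t_m_se, holo.t_m_se))

    def test_identical_inputs_give_zero_shift(self):
        res = fit_melt(simulate.gen_melt(
            simulate.MeltDesign(m.MeltParams(t_m=47.0, slope=0.35)), seed=2))
        d, _ = delta_tm(res, res)
        assert d == 0.0

    def test_rising_series_has_no_transition(self):
        t = np.linspace(4, 75, 10)
        with pytest.raises(ValueError, match="no transition detected"):
            fit_melt(MeltSeries(t, np.linspace(50, 100, 10)))

    def test_too_few_temperatures(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_melt(MeltSeries(np.array([4, 40, 60, 75.0]),
                                np.array([100, 80, 20, 0.0])))


class TestTransportRate:
    truth = m.MichaelisParams(v_max=0.002, k_m=5.0)

    def _trace(self, conc, seed=1, noise=0.0):
        return simulate.gen_transport_trace(
            simulate.TransportDesign(truth=self.truth, co_conc_um=conc,
                                     noise_sd_au=noise), seed=seed
        )

    def test_zero_substrate_trace_is_flat(self):
        rate, normalized = extract_initial_rate(self._trace(0.0))
        assert normalized
        assert abs(rate) < 1e-6

    def test_rate_extraction_within_5pct(self):
        for conc in (1.0, 10.0, 50.0, 200.0):
            rate, _ = extract_initial_rate(self._trace(conc), window_s=30.0)
            expect = m.mm_rate(conc, self.truth)
            assert rate == pytest.approx(expect, rel=0.05)

    def test_invariant_to_affine_rescaling(self):
        trace = self._trace(50.0, noise=0.0)
        rate, _ = extract_initial_rate(trace)
        trace.fluorescence_au[:] = 3.7 * trace.fluorescence_au + 12345.0
        rate2, _ = extract_initial_rate(trace)
        assert rate2 == pytest.approx(rate, rel=1e-9)

    def test_event_order_enforced(self):
        with pytest.raises(ValueError, match="out of order"):
            simulate.gen_transport_trace(
                simulate.TransportDesign(truth=self.truth, co_conc_um=10.0,
                                         t_valinomycin_s=300.0), seed=1
            )


class TestKm:
    def test_noiseless_exact_recovery(self):
        truth = m.MichaelisParams(v_max=0.004, k_m=5.0)
        conc = np.array([1.0, 10.0, 50.0, 200.0])
        res = fit_km(m.mm_rate(conc, truth), conc)
        assert res.params.k_m == pytest.approx(5.0, rel=1e-6)
        assert res.params.v_max == pytest.approx(0.004, rel=1e-6)
        assert res.flags == []

    def test_end_to_end_from_traces_within_3se(self):
        truth = m.MichaelisParams(v_max=0.002, k_m=5.0)
        concs = np.array([0.0, 1.0, 10.0, 50.0, 200.0])
        rates = []
        for i, c in enumerate(concs):
            trace = simulate.gen_transport_trace(
                simulate.TransportDesign(truth=truth, co_conc_um=c), seed=40 + i
            )
            rates.append(extract_initial_rate(trace)[0])
        res = fit_km(np.array(rates), concs)
        assert abs(res.params.k_m - 5.0) <= max(3 * res.stderr["k_m"], 0.15 * 5.0)

    def test_blank_subtraction_uses_zero_substrate_rate(self):
        truth = m.MichaelisParams(v_max=0.004, k_m=5.0)
        conc = np.array([0.0, 1.0, 10.0, 50.0, 200.0])
        rates = np.concatenate([[0.0003], m.mm_rate(conc[1:], truth) + 0.0003])
        res = fit_km(rates, conc)
        assert res.params.k_m == pytest.approx(5.0, rel=1e-6)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="no transport"):
            fit_km(np.zeros(5), np.array([0.0, 1, 10, 50, 200]))

    def test_nonsaturating_data_flagged(self):
        truth = m.MichaelisParams(v_max=1.0, k_m=500.0)
        conc = np.array([1.0, 5.0, 20.0, 100.0])
        res = fit_km(m.mm_rate(conc, truth), conc)
        assert any("poorly constrained" in f for f in res.flags)


class TestSPR:
    def test_noiseless_exact_recovery_kd_500(self):
        truth = m.SPRParams(k_on=1e5, k_off=0.05, r_max=100.0)
        sgs = simulate.gen_spr(simulate.SPRDesign(truth=truth, noise_sd_ru=0.0),
                               seed=1)
        res = fit_spr(sgs)
        assert res.params.k_on == pytest.approx(1e5, rel=1e-6)
        assert res.params.k_off == pytest.approx(0.05, rel=1e-6)
        assert res.k_d_nm == pytest.approx(500.0, rel=1e-6)

    def test_noisy_recovery_within_3se(self):
        truth = m.SPRParams(k_on=1e5, k_off=0.05, r_max=100.0)
        sgs = simulate.gen_spr(simulate.SPRDesign(truth=truth), seed=2)
        res = fit_spr(sgs)
        assert abs(res.params.k_on - 1e5) <= 3 * res.stderr["k_on"]
        assert abs(res.params.k_off - 0.05) <= 3 * res.stderr["k_off"]
        assert abs(res.k_d_nm - 500.0) <= 3 * res.k_d_nm_se

    def test_steady_states_lie_on_binding_isotherm(self):
        # internal consistency: fitted end-of-association responses
        # follow r_max*c/(c + K_D)
        truth = m.SPRParams(k_on=2e5, k_off=0.0616, r_max=80.0)
        sgs = simulate.gen_spr(
            simulate.SPRDesign(truth=truth, t_assoc_s=600.0, noise_sd_ru=0.0),
            seed=3)
        res = fit_spr(sgs)
        p = res.params
        for sg, curve in zip(sgs, res.fit.curves):
            c = sg.conc_nm * 1e-9
            r_end = curve[sg.time_s < sg.t_assoc_end][-1]
            r_eq = p.r_max * c / (c + p.k_d)
            assert r_end == pytest.approx(r_eq, rel=1e-2)

    def test_short_dissociation_flagged(self):
        truth = m.SPRParams(k_on=1e5, k_off=1e-4, r_max=100.0)
        sgs = simulate.gen_spr(
            simulate.SPRDesign(truth=truth, t_diss_s=100.0, noise_sd_ru=0.0),
            seed=4)
        res = fit_spr(sgs)
        assert any("dissociation too short" in f for f in res.flags)

    def test_too_few_concentrations_rejected(self):
        truth = m.SPRParams(k_on=1e5, k_off=0.05, r_max=100.0)
        sgs = simulate.gen_spr(simulate.SPRDesign(truth=truth), seed=1)
        with pytest.raises(ValueError, match=">= 3"):
            fit_spr(sgs[:2])
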