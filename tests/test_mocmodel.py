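"""Conductance-based MOC model: stability, calibration contract, protocols."""

import numpy as np
import pytest
from dataclasses import replace

from mocsyn import mocmodel as M
from mocsyn.timing import detect_aps


class TestBuildModel:
    def test_rest_is_stable_without_input(self):
        model = M.build_model(M.NeuronModelSpec())
        t, v = model.run([], [], 300.0)
        assert abs(v[-1] - v[len(v) // 2]) < 0.1
        assert v[-1] < -55.0
        assert M._ap_peaks(t, v).size == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            M.NeuronModelSpec(g_na=-1.0)

    def test_spontaneously_active_spec_rejected(self):
        # no potassium, no leak to speak of: the cell cannot hold a rest
        bad = M.NeuronModelSpec(g_kht=0.0, g_klt=0.0, g_ahp=0.0,
                                g_leak=0.005, g_na=800.0, e_leak_mv=-50.0)
        with pytest.raises(RuntimeError):
            M.build_model(bad)

    def test_strong_current_step_sustains_fast_firing(self):
        model = M.build_model(M.NeuronModelSpec())
        rates = []
        for inj in (200.0, 400.0):
            t, v = model.run([], [], 350.0, inj_pa=inj,
                             inj_window_ms=(50.0, 350.0))
            rates.append(detect_aps(t, v).size / 0.3)
        assert max(rates) >= 150.0

    def test_dt_halving_preserves_counts_and_timing(self):
        """AP count is invariant under dt halving; AP times shift by far less
        than a stimulus interval (near-threshold late-train spikes are the
        most sensitive and set the bound)."""
        model = M.build_model(M.NeuronModelSpec())
        res_a = M.simulate_protocol(model, M.ProtocolSpec(include_i=False, dt_ms=0.02))
        res_b = M.simulate_protocol(model, M.ProtocolSpec(include_i=False, dt_ms=0.01))
        assert res_a.n_aps == res_b.n_aps
        shifts = np.abs(res_a.ap_times_ms - res_b.ap_times_ms)
        # first-AP latency is the quantity of record; 0.1 ms is the trace
        # recording resolution at the default stride
        assert shifts[0] <= 0.15
        assert shifts.max() < 0.5

    def test_determinism(self):
        model = M.build_model(M.NeuronModelSpec())
        r1 = M.simulate_protocol(model, M.ProtocolSpec())
        r2 = M.simulate_protocol(model, M.ProtocolSpec())
        np.testing.assert_array_equal(r1.v_soma_mv, r2.v_soma_mv)


class TestCalibration:
    def test_mpsp_peaks_match_templates_within_10pct(self, calibrated_model):
        _, rep = calibrated_model
        assert rep.mepsp_peak_mv == pytest.approx(rep.mepsp_target_mv, rel=0.10)
        assert rep.mipsp_peak_mv == pytest.approx(rep.mipsp_target_mv, rel=0.10)

    def test_within_tolerance_flag(self, calibrated_model):
        _, rep = calibrated_model
        assert rep.within_tolerance

    def test_control_train_first_ap_near_contract(self, calibrated_model):
        model, rep = calibrated_model
        res = M.simulate_protocol(model, M.ProtocolSpec())
        assert res.first_ap_latency_ms == pytest.approx(38.5, rel=0.10)

    def test_self_consistency_recalibration_is_stable(self, calibrated_model):
        """Calibrating a calibrated model leaves its endpoints unchanged."""
        model, _ = calibrated_model
        again, rep2 = M.calibrate(model)
        res1 = M.simulate_protocol(model, M.ProtocolSpec(include_i=False))
        res2 = M.simulate_protocol(again, M.ProtocolSpec(include_i=False))
        assert res1.n_aps == res2.n_aps
        assert res1.first_ap_latency_ms == pytest.approx(
            res2.first_ap_latency_ms, abs=0.5)


class TestProtocols:
    def test_dt_guard(self):
        with pytest.raises(ValueError):
            M.ProtocolSpec(dt_ms=0.05)

    def test_grid_guard(self):
        with pytest.raises(ValueError):
            M.ProtocolSpec(ei_latency_difference_ms=12.0)
        model = M.build_model(M.NeuronModelSpec())
        with pytest.raises(ValueError):
            M.sweep_ei_latency(model, grid=[-12.0])

    def test_ipsp_only_no_aps_hyperpolarising_only(self, calibrated_model):
        model, _ = calibrated_model
        res = M.simulate_protocol(model, M.ProtocolSpec(include_e=False))
        assert res.n_aps == 0
        assert res.psp_peak_mv < 0.5  # no depolarising deflection

    def test_e_only_faster_than_control(self, calibrated_model):
        model, _ = calibrated_model
        ctrl = M.simulate_protocol(model, M.ProtocolSpec())
        eonly = M.simulate_protocol(model, M.ProtocolSpec(include_i=False))
        assert eonly.first_ap_latency_ms < ctrl.first_ap_latency_ms
        assert eonly.first_ap_latency_ms == pytest.approx(24.4, rel=0.10)
        assert eonly.ap_rate_hz == pytest.approx(31.5, rel=0.10)

    def test_single_psp_subthreshold(self, calibrated_model):
        model, _ = calibrated_model
        res = M.simulate_protocol(model, M.ProtocolSpec(mode="single_psp"))
        assert res.n_aps == 0
        assert 0.5 < res.psp_peak_mv < 25.0

    def test_inverted_chloride_reversal_turns_ipsp_depolarising(self):
        spec = M.NeuronModelSpec()
        model = M.MOCModel(spec, i_syn=replace(M.DEFAULT_I_SYNAPSE,
                                               reversal_mv=0.0))
        res = M.simulate_protocol(model, M.ProtocolSpec(include_e=False,
                                                        mode="single_psp"))
        assert res.psp_peak_mv > 0.5  # now behaves like excitation


class TestEISweep:
    def test_sweep_has_21_sorted_rows(self, ei_sweep):
        full, _ = ei_sweep
        assert len(full) == 21
        assert list(full.ei_diff_ms) == sorted(full.ei_diff_ms)

    def test_inhibition_reduces_rate_at_every_grid_point(self, calibrated_model, ei_sweep):
        model, _ = calibrated_model
        full, _ = ei_sweep
        eonly = M.simulate_protocol(model, M.ProtocolSpec(include_i=False))
        assert (full.ap_rate_hz < eonly.ap_rate_hz).all()

    def test_rate_extrema_near_printed_grid_locations(self, ei_sweep):
        """Most effective inhibition near -10/-1/+9 ms, least near -6/+4 ms."""
        full, _ = ei_sweep
        at_min = set(full.ei_diff_ms[full.n_aps == full.n_aps.min()].astype(int))
        at_max = set(full.ei_diff_ms[full.n_aps == full.n_aps.max()].astype(int))
        assert any(any(abs(g - ref) <= 1 for g in at_min) for ref in (-10, -1, 9))
        assert any(any(abs(g - ref) <= 1 for g in at_max) for ref in (-6, 4))

    def test_depressed_ipsp_weakens_suppression_pointwise(self, ei_sweep):
        full, weak = ei_sweep
        assert (weak.n_aps.values >= full.n_aps.values).all()

    def test_dt_halving_preserves_ap_counts_across_sweep(self, calibrated_model, ei_sweep):
        model, _ = calibrated_model
        full, _ = ei_sweep
        fine = M.sweep_ei_latency(model, dt_ms=0.01)
        np.testing.assert_array_equal(full.n_aps.values, fine.n_aps.values)
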