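import numpy as np
import pytest

import gonadotrace as gt
from gonadotrace.params import UnknownGroupError, default_group_params
from gonadotrace.preprocess import detrend_bleach, normalize_dff
from gonadotrace.protocol import Epoch, extended_window, response_window
from gonadotrace.synth import (
    CellEvents,
    RecordingSpec,
    _draw_spike_count,
    apply_intervention,
    draw_ground_truth,
    render_cell,
    synth_recording,
    write_recording,
)


class TestGroupParams:
    def test_control_calibration_values(self):
        p = default_group_params("control")
        assert p.frac_responder == 0.27
        assert p.frac_spontaneous == 0.428
        assert p.mif_mean == 1.31
        assert p.auc_target == 14.03

    def test_cd21_biphasic_dominates(self):
        p = default_group_params("Cd21")
        assert p.pattern_mix[1] == pytest.approx(0.9972, abs=1e-3)

    @pytest.mark.parametrize("group", ["control", "Cd21", "Cd35", "Cd56"])
    def test_pattern_mix_is_simplex(self, group):
        p = default_group_params(group)
        assert sum(p.pattern_mix) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_group_lists_valid(self):
        with pytest.raises(UnknownGroupError, match="Cd35"):
            default_group_params("Cd70")

    def test_long_lasting_only_in_late_groups(self):
        assert default_group_params("control").frac_long_lasting == 0.0
        assert default_group_params("Cd21").frac_long_lasting == 0.0
        assert default_group_params("Cd35").frac_long_lasting > 0.0
        assert default_group_params("Cd56").frac_long_lasting > 0.0


class TestDeterminism:
    def test_same_seed_bit_identical(self, protocol):
        a, _ = synth_recording("control", 40, seed=1, protocol=protocol)
        b, _ = synth_recording("control", 40, seed=1, protocol=protocol)
        np.testing.assert_array_equal(a.F, b.F)

    def test_different_seed_differs(self, protocol):
        a, _ = synth_recording("control", 10, seed=1, protocol=protocol)
        b, _ = synth_recording("control", 10, seed=2, protocol=protocol)
        assert not np.array_equal(a.F, b.F)

    def test_cell_streams_stable_under_n_cells(self, protocol):
        """Growing n_cells must not reshuffle earlier cells."""
        a, _ = synth_recording("Cd35", 10, seed=3, protocol=protocol)
        b, _ = synth_recording("Cd35", 25, seed=3, protocol=protocol)
        np.testing.assert_array_equal(a.F, b.F[:, :10])


class TestLabelProportions:
    def test_gonadotroph_fraction_within_binomial_ci(self):
        p = default_group_params("control")
        truth, _ = draw_ground_truth(p, 10_000, seed=5)
        viable = truth.viable
        frac = truth.is_gonadotroph[viable].mean()
        n = viable.sum()
        se = np.sqrt(0.27 * 0.73 / n)
        assert abs(frac - 0.27) < 3 * se

    def test_cd21_oscillatory_fraction_rare(self):
        p = default_group_params("Cd21")
        truth, _ = draw_ground_truth(p, 10_000, seed=5)
        pats = np.array([x if x else "" for x in truth.pattern])
        responders = truth.is_gonadotroph
        frac_osc = (pats[responders] == "oscillatory").mean()
        target = p.pattern_mix[0]
        se = np.sqrt(target * (1 - target) / responders.sum())
        assert abs(frac_osc - target) < max(3 * se, 0.005)

    def test_pattern_defined_iff_gonadotroph(self):
        truth, _ = draw_ground_truth(default_group_params("Cd56"), 500, seed=8)
        for i in range(len(truth)):
            assert (truth.pattern[i] is not None) == bool(truth.is_gonadotroph[i])

    def test_long_lasting_only_oscillatory(self):
        truth, _ = draw_ground_truth(default_group_params("Cd56"), 2000, seed=9)
        for i in np.where(truth.long_lasting)[0]:
            assert truth.pattern[i] == "oscillatory"


class TestSpikeCounts:
    def test_truncated_negative_binomial_moments(self):
        p = default_group_params("control")
        rng = np.random.default_rng(0)
        draws = np.array([_draw_spike_count(p, rng) for _ in range(20_000)])
        assert draws.min() >= 2
        assert abs(draws.mean() - 17.6) < 0.3
        assert abs(draws.std() - 9.06) < 0.4

    def test_cd21_rounded_normal_fallback(self):
        p = default_group_params("Cd21")  # sd < mean: NB does not exist
        rng = np.random.default_rng(0)
        draws = np.array([_draw_spike_count(p, rng) for _ in range(5_000)])
        assert draws.min() >= 2
        assert abs(draws.mean() - 5.5) < 0.2


class TestWaveforms:
    def test_flat_cell_is_constant(self, protocol, noise_free_control):
        ev = CellEvents()  # no events at all
        F = render_cell(ev, noise_free_control, protocol, np.random.default_rng(0))
        assert np.allclose(F, F[0])

    def test_nongonadotroph_has_single_kcl_event(self, protocol, noise_free_control):
        from gonadotrace.events import detect_transients

        ev = CellEvents(kcl_time=protocol.kcl.start + 0.6, kcl_amp=0.6)
        F = render_cell(ev, noise_free_control, protocol, np.random.default_rng(0))
        dff = normalize_dff(F)
        det = detect_transients(dff, (0.0, protocol.total_time), protocol.dt)
        assert len(det) == 1
        assert protocol.kcl.contains(det.times[0])

    def test_oscillatory_round_trip_17_spikes(self, protocol, noise_free_control):
        """A noise-free 17-spike cell yields exactly 17 detected events."""
        from gonadotrace.events import detect_transients

        p = noise_free_control
        truth, programs = draw_ground_truth(p.with_(pattern_mix=(1, 0, 0)), 30, seed=2)
        for i, ev in enumerate(programs):
            if truth.n_spikes_true[i] == 17:
                F = render_cell(ev, p, protocol, np.random.default_rng(0))
                dff = normalize_dff(detrend_bleach(F, protocol))
                det = detect_transients(dff, response_window(protocol), protocol.dt)
                assert len(det) == 17
                break
        else:
            pytest.skip("no 17-spike draw in this sample")

    def test_fluorescence_strictly_positive(self, protocol):
        rec, _ = synth_recording("Cd56", 50, seed=4, protocol=protocol)
        assert (rec.F > 0).all()


@pytest.fixture(scope="module")
def control_metrics(protocol):
    from gonadotrace.pipeline import analyze_recording

    p = default_group_params("control").with_(frac_responder=1.0, frac_nonviable=0.0)
    summaries = []
    for a in range(6):
        rec, truth = synth_recording("control", 60, [77, a], protocol=protocol, params=p)
        _, s, _ = analyze_recording(rec, truth)
        summaries.append(s)
    return summaries


class TestAmplitudeCalibration:
    """Downstream MIF/AUC of simulated control responders match calibration."""

    def test_mif_within_3se(self, control_metrics):
        vals = np.array([s["mif"] for s in control_metrics])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.31) < 3 * se

    def test_auc_within_3se(self, control_metrics):
        vals = np.array([s["auc"] for s in control_metrics])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 14.03) < 3 * se


class TestInterventions:
    def test_nifedipine_factor_one_is_identity(self, protocol):
        spec = RecordingSpec("control", 20, 6, protocol)
        base, _ = synth_recording("control", 20, 6, protocol)
        same, _ = apply_intervention(
            spec,
            "nifedipine",
            Epoch(270.0, 470.0),
            nif_amp_factor=1.0,
            nif_rate_factor=1.0,
            nif_ll_amp_factor=1.0,
            nif_ll_rate_factor=1.0,
        )
        np.testing.assert_array_equal(base.F, same.F)

    def test_nifedipine_reduces_auc(self, protocol):
        from gonadotrace.events import compute_auc
        from gonadotrace.protocol import metric_window

        spec = RecordingSpec("control", 40, 6, protocol)
        base, truth = synth_recording("control", 40, 6, protocol)
        nif, _ = apply_intervention(spec, "nifedipine", Epoch(240.0, 470.0))
        win = metric_window(protocol)
        resp = np.where(truth.is_gonadotroph)[0]
        auc0 = np.mean([
            compute_auc(normalize_dff(detrend_bleach(base.F[:, j], protocol)), win, protocol.dt)
            for j in resp
        ])
        auc1 = np.mean([
            compute_auc(normalize_dff(detrend_bleach(nif.F[:, j], protocol)), win, protocol.dt)
            for j in resp
        ])
        assert auc1 < auc0

    def test_ca_free_abolishes_kcl_response_in_control(self, protocol):
        spec = RecordingSpec("control", 30, 7, protocol)
        rec, truth = apply_intervention(spec, "ca_free", Epoch(400.0, 480.0))
        sl = protocol.slice(protocol.kcl.start, protocol.kcl.end)
        for j in np.where(truth.viable & ~truth.is_gonadotroph)[0]:
            dff = normalize_dff(detrend_bleach(rec.F[:, j], protocol))
            assert dff[sl].max() - 1.0 < 0.10  # would fail the viability gate

    def test_ca_free_long_lasting_recovers_after_window(self, protocol):
        """Spike rate after a mid-recording Ca2+-free window exceeds the rate
        inside it (oscillations recover when Ca2+ returns)."""
        from gonadotrace.events import detect_transients

        p = default_group_params("Cd56").with_(
            frac_responder=1.0, pattern_mix=(1, 0, 0), frac_long_lasting=1.0,
            frac_nonviable=0.0, ca_free_residual=0.0,
        )
        win = Epoch(280.0, 360.0)
        spec = RecordingSpec("Cd56", 12, 8, protocol, p)
        rec, truth = apply_intervention(spec, "ca_free", win)
        rates_in, rates_after = [], []
        for j in range(rec.F.shape[1]):
            dff = normalize_dff(detrend_bleach(rec.F[:, j], protocol))
            det = detect_transients(dff, extended_window(protocol), protocol.dt)
            rates_in.append(np.sum((det.times >= win.start) & (det.times < win.end)) / win.duration)
            rates_after.append(np.sum(det.times >= win.end) / (protocol.total_time - win.end))
        assert np.mean(rates_after) > np.mean(rates_in)

    def test_unknown_kind_rejected(self, protocol):
        spec = RecordingSpec("control", 5, 1, protocol)
        with pytest.raises(ValueError, match="unknown intervention"):
            apply_intervention(spec, "gadolinium", Epoch(300.0, 400.0))


class TestDiskRoundTrip:
    def test_write_read_identical(self, tmp_path, protocol):
        from gonadotrace.preprocess import read_trace_matrix

        rec, truth = synth_recording("control", 8, seed=12, protocol=protocol)
        path = write_recording(rec, truth, tmp_path)
        back = read_trace_matrix(path)
        np.testing.assert_allclose(back.F, rec.F, atol=5e-6)
        assert back.roi_ids == rec.roi_ids
        assert back.protocol == protocol
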