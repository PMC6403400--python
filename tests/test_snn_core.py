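"""LIF dynamics, the five-neuron circuit, and the array simulator."""

import time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikedff as sdf
from spikedff.snn_core import (CircuitConstraintError, CircuitParams,
                               LIFParams, LIFState, build_network,
                               build_pixel_circuit, lif_step, run,
                               run_snn_engine, validate_circuit)

DT_US = int(CircuitParams().dt * 1e6)


class TestLifStep:
    def test_rest_is_stable(self):
        p = LIFParams()
        st_ = LIFState.zeros(p, (3,))
        for _ in range(100):
            lif_step(st_, 0.0, 50e-6)
        np.testing.assert_allclose(st_.v, p.v_rest)
        assert not st_.spiked.any()

    def test_suprathreshold_pulse_spikes_once_and_resets(self):
        p = LIFParams()
        st_ = LIFState.zeros(p, (1,))
        lif_step(st_, p.gap + 0.1, 50e-6)
        assert st_.spiked.all() and st_.v[0] == p.v_reset
        lif_step(st_, 0.0, 50e-6)
        assert not st_.spiked.any()

    def test_subthreshold_pulse_decays_exponentially(self):
        # v(t) - v_rest = w * exp(-t / tau_m), checked against closed form
        p = LIFParams(tau_m=0.002)
        st_ = LIFState.zeros(p, (1,))
        dt = 50e-6
        lif_step(st_, 0.5, dt)
        for k in range(1, 60):
            lif_step(st_, 0.0, dt)
            expect = 0.5 * np.exp(-k * dt / p.tau_m)
            assert st_.v[0] == pytest.approx(expect, abs=1e-9)

    def test_refractory_holds_at_rest(self):
        p = LIFParams(t_refractory=200e-6)
        st_ = LIFState.zeros(p, (1,))
        lif_step(st_, 2.0, 50e-6)
        assert st_.spiked.all()
        lif_step(st_, 2.0, 50e-6)
        assert not st_.spiked.any() and st_.v[0] == p.v_rest


class TestCircuitConstruction:
    def test_default_parameters_satisfy_constraints(self):
        validate_circuit(CircuitParams())

    @pytest.mark.parametrize("bad,constraint", [
        (dict(w_input_out=1.2), "single-input-subthreshold"),
        (dict(w_input_out=0.3), "polarity-inversion-fires"),
        (dict(w_input_blocker=1.5), "blocker-needs-two-spikes"),
        (dict(lif_blocker=LIFParams(tau_m=0.006, v_reset=0.0)),
         "blocker-refires-each-run-spike"),
        (dict(w_blocker_out=0.1), "blocker-silences-blocked-polarity"),
        (dict(lif_blocker=LIFParams(tau_m=0.0015, v_reset=0.9)),
         "blocker-covers-subthreshold-memory"),
        (dict(w_self=0.5), "self-excitation-sustains-train"),
        (dict(w_sync=0.0), "sync-silences"),
    ])
    def test_violations_name_the_failed_constraint(self, bad, constraint):
        with pytest.raises(CircuitConstraintError, match=constraint):
            validate_circuit(CircuitParams(**bad))

    def test_pixel_circuit_wiring(self):
        pc = build_pixel_circuit(CircuitParams(), base_id=10, sync_id=99)
        assert pc.neuron_ids == (10, 11, 12, 13, 14)
        assert len(pc.synapses) == 8
        # self-excitation and a sync synapse are present
        assert any(s.pre == s.post == pc.out and s.weight > 0
                   for s in pc.synapses)
        assert any(s.pre == 99 and s.weight < 0 for s in pc.synapses)


class TestNetworkSizing:
    def test_five_neurons_per_pixel_shared_sync_excluded(self):
        assert build_network((64, 64), ((0, 1), (0, 1))).neuron_count == 5
        assert build_network((64, 64), ((0, 2), (0, 3))).neuron_count == 30

    def test_full_sensor_region_count(self):
        t0 = time.time()
        net = build_network((480, 640), roi=((0, 447), (0, 447)))
        assert net.neuron_count == 999_045
        assert time.time() - t0 < 1.0

    def test_empty_or_outside_roi_rejected(self):
        with pytest.raises(ValueError):
            build_network((64, 64), ((0, 0), (0, 10)))
        with pytest.raises(ValueError):
            build_network((64, 64), ((0, 65), (0, 10)))

    def test_edge_list_export(self):
        net = build_network((8, 8), ((0, 2), (0, 2)))
        edges = net.edge_list()
        assert len(edges) == 8 * 4
        assert all(s.delay > 0 for s in edges)


def run_one(pixel_stream, times, pols, sync_us=6_000, params=None):
    stream = pixel_stream(times, pols)
    net = build_network(stream.sensor_shape, params=params)
    rec = run(net, stream, [sync_us], record_trains=True)
    return rec


class TestCircuitBehaviour:
    def test_on_on_off_fires_out_at_the_polarity_inversion(self, pixel_stream):
        rec = run_one(pixel_stream, [500, 800, 1_200], [1, 1, -1])
        onset = rec.out_onset_us()[2, 1]
        # OUT fires two synaptic steps after the OFF event's bin
        assert onset == pytest.approx(1_200 + 2 * DT_US, abs=DT_US)

    @pytest.mark.parametrize("pol", [1, -1])
    def test_single_polarity_runs_never_fire(self, pixel_stream, pol):
        times = np.arange(200, 4_600, 137)
        rec = run_one(pixel_stream, times, [pol] * len(times))
        assert rec.first_out_step[0].max() < 0
        assert not rec.spike_steps("OUT").any()

    def test_out_train_sustained_until_sync_then_silent(self, pixel_stream):
        sync = 4_000
        rec = run_one(pixel_stream, [500, 800, 1_200, 1_500, 2_000],
                      [1, 1, -1, -1, -1], sync_us=sync)
        out = rec.spike_steps("OUT")[:, 2, 1]
        steps = np.nonzero(out)[0]
        assert len(steps) > 0
        # contiguous self-driven train from onset...
        np.testing.assert_array_equal(steps,
                                      np.arange(steps[0], steps[-1] + 1))
        # ...terminated by sync: nothing after sync + one synaptic delay
        assert steps[-1] <= sync // DT_US + 1
        assert steps[-1] >= sync // DT_US - 1

    def test_post_inversion_spikes_do_not_retrigger_after_sync(
            self, pixel_stream):
        # events continue past the sweep end; OUT must stay silent after
        # the sync reset even though late OFF->ON pairs arrive
        stream = pixel_stream([500, 800, 1_200, 4_300, 4_400],
                              [1, 1, -1, -1, 1])
        net = build_network(stream.sensor_shape)
        rec = run(net, stream, [4_000], record_trains=True)
        out_steps = np.nonzero(rec.spike_steps("OUT")[:, 2, 1])[0]
        assert out_steps.size and out_steps[-1] <= 4_000 // DT_US + 1

    def test_blockers_fire_from_second_same_polarity_spike(self, pixel_stream):
        rec = run_one(pixel_stream, [500, 900, 1_300], [1, 1, 1])
        bon = np.nonzero(rec.spike_steps("B_on")[:, 2, 1])[0]
        # one blocker spike per ON spike from the second onward
        assert len(bon) == 2
        assert not rec.spike_steps("B_off")[:, 2, 1].any()

    def test_empty_stream_is_silent(self, pixel_stream):
        rec = run_one(pixel_stream, [], [])
        assert rec.first_out_step[0].max() < 0

    def test_focus_time_is_midpoint_of_straddling_pair(self, pixel_stream):
        rec = run_one(pixel_stream, [500, 900, 1_300], [1, 1, -1])
        tf = rec.focus_time_map()[2, 1]
        # midpoint of last ON bin (900) and OFF bin (1300), in step units
        expect = 0.5 * (900 // DT_US + 1_300 // DT_US) * DT_US
        assert tf == pytest.approx(expect, abs=DT_US)

    def test_wide_inversion_outside_coincidence_window_ignored(
            self, pixel_stream):
        window_us = CircuitParams().coincidence_window * 1e6
        rec = run_one(pixel_stream, [500, 900, 900 + int(2 * window_us)],
                      [1, 1, -1])
        assert rec.first_out_step[0].max() < 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(gaps=st.lists(st.integers(30, 2_500), min_size=1, max_size=12))
    def test_same_polarity_trains_never_fire_for_any_gap_pattern(self, gaps):
        times = np.cumsum([200] + gaps)
        stream = _pixel(times, [1] * len(times))
        net = build_network(stream.sensor_shape)
        rec = run(net, stream, [int(times[-1]) + 1_000])
        assert rec.first_out_step[0].max() < 0


def _pixel(times_us, polarities, x=1, y=2):
    times_us = np.asarray(times_us, dtype=np.int64)
    n = len(times_us)
    return sdf.EventStream(times_us, np.full(n, x), np.full(n, y),
                           np.asarray(polarities, dtype=np.int8),
                           sensor_shape=(4, 4))


class TestRunSemantics:
    def test_time_translation_by_whole_steps(self, pixel_stream):
        shift = 20 * DT_US
        a = run_one(pixel_stream, [500, 800, 1_200], [1, 1, -1])
        b = run_one(pixel_stream, [500 + shift, 800 + shift, 1_200 + shift],
                    [1, 1, -1], sync_us=6_000 + shift)
        assert b.out_onset_us()[2, 1] == a.out_onset_us()[2, 1] + shift
        assert b.focus_time_map()[2, 1] == a.focus_time_map()[2, 1] + shift

    def test_pixels_are_independent(self, multi_stream):
        # onsets computed on the full array equal onsets from per-pixel runs
        tf_full, rec = run_snn_engine(multi_stream)
        ys, xs = np.nonzero(np.isfinite(tf_full))
        assert len(ys) > 20
        rng = np.random.default_rng(1)
        sync = rec.sync_steps[0] * rec.dt_us
        for i in rng.choice(len(ys), 8, replace=False):
            y, x = int(ys[i]), int(xs[i])
            t, p = multi_stream.pixel_train(x, y)
            solo = sdf.EventStream(t, np.full(len(t), x), np.full(len(t), y),
                                   p, sensor_shape=multi_stream.sensor_shape)
            net = build_network(multi_stream.sensor_shape,
                                roi=((y, y + 1), (x, x + 1)))
            rec_solo = run(net, solo, [sync])
            assert rec_solo.focus_time_map()[0, 0] == tf_full[y, x]

    def test_events_outside_roi_are_counted_not_crashed(self, pixel_stream):
        stream = pixel_stream([100, 400], [1, -1], x=3, y=3)
        net = build_network((4, 4), roi=((0, 2), (0, 2)))
        rec = run(net, stream, [2_000])
        assert rec.ignored_events == 2
        assert rec.first_out_step[0].max() < 0

    def test_unsorted_sync_times_rejected(self, pixel_stream):
        stream = pixel_stream([100], [1])
        net = build_network((4, 4))
        with pytest.raises(ValueError):
            run(net, stream, [2_000, 1_000])

    def test_spike_record_export(self, pixel_stream, tmp_path):
        rec = run_one(pixel_stream, [500, 800, 1_200], [1, 1, -1])
        csv = tmp_path / "spikes.csv"
        rec.to_csv(csv)
        header = csv.read_text().splitlines()[0]
        assert header == "neuron_id,t_us"
        png = tmp_path / "raster.png"
        rec.raster_png(png, 2, 1)
        assert png.stat().st_size > 0
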