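"""Leaky integrate-and-fire engine and the per-pixel focus-detection circuit.

Every pixel owns five neurons: two input relays (ON, OFF) forwarding the
camera's events, two blockers (B_on, B_off) and an output neuron (OUT).
Inputs excite OUT sub-threshold on their own; a run of same-polarity spikes
drives the matching blocker, whose shunting inhibition clamps OUT back to
rest so the run can never accumulate to threshold.  The first spike of the
*opposite* polarity — the polarity inversion at the time of focus — sums
with the residual excitation of the last same-polarity spike and fires OUT.
Because that residual decays with the membrane time constant, the circuit
only responds when the opposite-polarity pair is close in time: the leak is
a built-in temporal-contrast gate selecting the *smallest* ON/OFF interval.
OUT is self-excitatory, so it keeps firing until a single shared Sync
neuron (driven by the lens at sweep end) strongly inhibits it and resets
the circuit; the depth is encoded in the OUT->Sync interval.

Simulation is fixed-step with delta-current synapses (instantaneous
potential increments) and exact exponential decay between steps.  Synaptic
delays are structural: input->OUT takes two steps while input->blocker and
blocker->OUT take one step each, so a blocker spike always reaches OUT in
the same step as the input EPSP that triggered it.  The blocker synapse is
shunting: it resets OUT's membrane to rest *before* that step's inputs
integrate, erasing the previous residual while letting the newest EPSP
stand — OUT therefore always carries exactly the last same-polarity spike's
(decaying) excitation.  Camera events of one polarity falling into a single
step collapse to one relay spike (a one-step refractory on the relays).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .scene_simulator import EventStream

__all__ = [
    "LIFParams", "LIFState", "Synapse", "CircuitParams", "PixelCircuit",
    "SpikeRecord", "CircuitConstraintError", "lif_step",
    "build_pixel_circuit", "build_network", "Network", "run",
    "run_snn_engine",
]

# neuron slots within a pixel circuit
ON, OFF, B_ON, B_OFF, OUT = range(5)
_SLOT_NAMES = ("ON", "OFF", "B_on", "B_off", "OUT")

# structural synaptic delays, in simulation steps
DELAY_INPUT_OUT = 2
DELAY_INPUT_BLOCKER = 1
DELAY_BLOCKER_OUT = 1
DELAY_SELF = 1
DELAY_SYNC = 1


class CircuitConstraintError(ValueError):
    """A circuit parameter set violates a named behavioural constraint."""


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron parameters (potentials are in
    arbitrary units; only differences to threshold matter)."""

    tau_m: float = 0.002
    v_rest: float = 0.0
    v_reset: float = 0.0
    v_threshold: float = 1.0
    t_refractory: float = 0.0

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.v_threshold <= self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")

    @property
    def gap(self) -> float:
        return self.v_threshold - self.v_rest


@dataclass
class LIFState:
    """Vectorised membrane state for a population of identical neurons."""

    params: LIFParams
    v: np.ndarray
    refrac: np.ndarray  # remaining refractory steps
    spiked: np.ndarray

    @classmethod
    def zeros(cls, params: LIFParams, shape) -> "LIFState":
        return cls(params, np.full(shape, params.v_rest, dtype=float),
                   np.zeros(shape, dtype=np.int32),
                   np.zeros(shape, dtype=bool))

    def reset(self) -> None:
        self.v.fill(self.params.v_rest)
        self.refrac.fill(0)
        self.spiked.fill(False)


def lif_step(state: LIFState, input_current, dt: float) -> LIFState:
    """Advance a LIF population by one step of length ``dt``.

    Exact exponential leak toward rest, then the (delta-synapse) input
    increment; a threshold crossing spikes, resets to ``v_reset`` and starts
    the refractory period.  Mutates and returns ``state``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    decay = np.exp(-dt / p.tau_m)
    state.v = p.v_rest + (state.v - p.v_rest) * decay + input_current
    blocked = state.refrac > 0
    state.spiked = (state.v >= p.v_threshold) & ~blocked
    state.v = np.where(state.spiked, p.v_reset, state.v)
    state.v = np.where(blocked, p.v_rest, state.v)
    state.refrac = np.where(blocked, state.refrac - 1, state.refrac)
    if p.t_refractory > 0:
        state.refrac = np.where(
            state.spiked, int(np.ceil(p.t_refractory / dt)), state.refrac)
    return state


@dataclass(frozen=True)
class Synapse:
    """Directed connection with a signed delta-current weight."""

    pre: int
    post: int
    weight: float
    delay: float

    def __post_init__(self):
        if self.delay <= 0:
            raise ValueError("synaptic delay must be at least one step")


@dataclass(frozen=True)
class CircuitParams:
    """Weights and neuron parameters of the five-neuron pixel circuit.

    The defaults satisfy the behavioural constraints validated by
    :func:`build_pixel_circuit`; ``check_interval`` is the reference
    inter-event interval over which the leak is evaluated when checking the
    "within tau_m" constraints.
    """

    lif_out: LIFParams = field(default_factory=LIFParams)
    # blockers integrate over a slower membrane than OUT so that any spike
    # pair able to leave a dangerous sub-threshold residue in OUT is
    # guaranteed to have fired (and hence shunted) the matching blocker
    lif_blocker: LIFParams = field(
        default_factory=lambda: LIFParams(tau_m=0.006, v_reset=0.9))
    w_input_out: float = 0.6       # ON->OUT, OFF->OUT (excitatory)
    w_input_blocker: float = 0.6   # ON->B_on, OFF->B_off (excitatory)
    w_blocker_out: float = 0.6     # B_*->OUT magnitude (shunting to rest;
    # the signed weight only appears in the exported edge list)
    w_self: float = 2.0            # OUT->OUT (self-excitatory)
    w_sync: float = -1000.0        # Sync->OUT (strong inhibition)
    dt: float = 50e-6
    check_interval: float = 0.5e-3

    @property
    def coincidence_window(self) -> float:
        """Largest lead->trail interval (s) that still fires OUT.

        The opposite-polarity EPSP sums with the residual of the last
        same-polarity EPSP; with delta synapses that succeeds for intervals
        up to ``tau_m * ln(w / (threshold - w))``.  The membrane leak is
        thus the circuit's temporal-contrast gate: it is what restricts
        detection to the *smallest* opposite-polarity intervals.
        """
        out = self.lif_out
        return out.tau_m * np.log(self.w_input_out /
                                  (out.gap - self.w_input_out))

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 100e-6:
            raise ValueError("simulation step must be positive and <= 100 µs")


def validate_circuit(params: CircuitParams) -> None:
    """Check the named behavioural constraints; raise on the first failure."""
    out, blk = params.lif_out, params.lif_blocker
    beta_out = np.exp(-params.check_interval / out.tau_m)
    beta_blk = np.exp(-params.check_interval / blk.tau_m)
    checks = [
        ("single-input-subthreshold",
         params.w_input_out < out.gap),
        ("polarity-inversion-fires",
         params.w_input_out * beta_out + params.w_input_out >= out.gap),
        ("blocker-needs-two-spikes",
         params.w_input_blocker < blk.gap <= params.w_input_blocker * beta_blk
         + params.w_input_blocker),
        ("blocker-refires-each-run-spike",
         (blk.v_reset - blk.v_rest) * beta_blk + params.w_input_blocker
         >= blk.gap),
        ("blocker-silences-blocked-polarity",
         params.w_blocker_out >= params.w_input_out),
        # first-fire window of a blocker must cover the whole interval over
        # which OUT can still hold a near-threshold residue, otherwise two
        # sub-threshold EPSPs separated by a mid-range gap could stack
        ("blocker-covers-subthreshold-memory",
         blk.tau_m * np.log(params.w_input_blocker /
                            max(blk.gap - params.w_input_blocker, 1e-12))
         >= out.tau_m * np.log(out.gap /
                               max(out.gap - params.w_input_out, 1e-12))),
        ("self-excitation-sustains-train",
         (out.v_reset - out.v_rest) + params.w_self >= out.gap),
        ("sync-silences",
         params.w_sync + params.w_self + params.w_input_out < out.gap),
    ]
    for name, ok in checks:
        if not ok:
            raise CircuitConstraintError(f"constraint violated: {name}")


@dataclass(frozen=True)
class PixelCircuit:
    """Neuron ids of one pixel's circuit plus the shared Sync reference."""

    on: int
    off: int
    b_on: int
    b_off: int
    out: int
    sync: int
    synapses: Tuple[Synapse, ...] = ()

    @property
    def neuron_ids(self) -> Tuple[int, ...]:
        return (self.on, self.off, self.b_on, self.b_off, self.out)


def build_pixel_circuit(params: CircuitParams,
                        base_id: int = 0, sync_id: int = 5) -> PixelCircuit:
    """Wire one pixel's five-neuron motif (validates the constraints)."""
    validate_circuit(params)
    on, off, b_on, b_off, out = (base_id + s for s in range(5))
    dt = params.dt
    syn = (
        Synapse(on, out, params.w_input_out, DELAY_INPUT_OUT * dt),
        Synapse(off, out, params.w_input_out, DELAY_INPUT_OUT * dt),
        Synapse(on, b_on, params.w_input_blocker, DELAY_INPUT_BLOCKER * dt),
        Synapse(off, b_off, params.w_input_blocker, DELAY_INPUT_BLOCKER * dt),
        Synapse(b_on, out, -params.w_blocker_out, DELAY_BLOCKER_OUT * dt),
        Synapse(b_off, out, -params.w_blocker_out, DELAY_BLOCKER_OUT * dt),
        Synapse(out, out, params.w_self, DELAY_SELF * dt),
        Synapse(sync_id, out, params.w_sync, DELAY_SYNC * dt),
    )
    return PixelCircuit(on, off, b_on, b_off, out, sync_id, syn)


@dataclass(frozen=True)
class Network:
    """One pixel circuit per region-of-interest pixel plus one shared Sync."""

    sensor_shape: Tuple[int, int]
    roi: Tuple[Tuple[int, int], Tuple[int, int]]
    params: CircuitParams

    @property
    def roi_shape(self) -> Tuple[int, int]:
        (r0, r1), (c0, c1) = self.roi
        return (r1 - r0, c1 - c0)

    @property
    def n_pixels(self) -> int:
        h, w = self.roi_shape
        return h * w

    @property
    def neuron_count(self) -> int:
        """Per-pixel neurons only (5 per pixel); Sync is shared, not counted."""
        return 5 * self.n_pixels

    @property
    def sync_id(self) -> int:
        return self.neuron_count

    def pixel_circuit(self, row: int, col: int) -> PixelCircuit:
        (r0, r1), (c0, c1) = self.roi
        if not (r0 <= row < r1 and c0 <= col < c1):
            raise ValueError("pixel outside roi")
        idx = (row - r0) * (c1 - c0) + (col - c0)
        return build_pixel_circuit(self.params, base_id=5 * idx,
                                   sync_id=self.sync_id)

    def edge_list(self) -> List[Synapse]:
        """Full network as a flat synapse list (external-simulator export)."""
        edges: List[Synapse] = []
        (r0, r1), (c0, c1) = self.roi
        for row in range(r0, r1):
            for col in range(c0, c1):
                edges.extend(self.pixel_circuit(row, col).synapses)
        return edges


def build_network(sensor_shape: Tuple[int, int],
                  roi: Tuple[Tuple[int, int], Tuple[int, int]] | None = None,
                  params: CircuitParams | None = None) -> Network:
    """Build the whole-array network for a region of interest.

    ``roi`` is ``((row0, row1), (col0, col1))``, defaulting to the full
    sensor.  Neuron count is exactly ``5 * rows * cols`` (the shared Sync is
    excluded from the per-pixel count).
    """
    params = params or CircuitParams()
    validate_circuit(params)
    rows, cols = sensor_shape
    if roi is None:
        roi = ((0, rows), (0, cols))
    (r0, r1), (c0, c1) = roi
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError("roi must be a non-empty region inside the sensor")
    return Network(tuple(sensor_shape), ((r0, r1), (c0, c1)), params)


@dataclass
class SpikeRecord:
    """Spike times of the simulated array, plus the focus-time readouts.

    Everything is stored per roi pixel in step units; accessors convert to
    microseconds.  ``first_out_step`` is -1 where OUT never fired within the
    sweep window.  ``lead_last_step`` is the bin of the last relay spike of
    the lead polarity (opposite to the one that fired OUT) before onset
    (-1 when OUT never fired).
    """

    network: Network
    dt_us: int
    sync_steps: np.ndarray            # (n_windows,)
    first_out_step: np.ndarray        # (n_windows, H, W)
    lead_last_step: np.ndarray        # (n_windows, H, W)
    trail_is_on: np.ndarray           # (n_windows, H, W) bool
    ignored_events: int
    trains: dict = field(default_factory=dict)  # slot name -> bool (T, H, W)

    @property
    def n_windows(self) -> int:
        return len(self.sync_steps)

    def out_onset_us(self, window: int = 0) -> np.ndarray:
        """Raw first-OUT-spike time (µs), NaN where OUT stayed silent."""
        first = self.first_out_step[window]
        t = first.astype(float) * self.dt_us
        t[first < 0] = np.nan
        return t

    def out_sync_interval_us(self, window: int = 0) -> np.ndarray:
        """The depth-encoding interval between OUT onset and the Sync spike."""
        return self.sync_steps[window] * self.dt_us - self.out_onset_us(window)

    def focus_time_map(self, window: int = 0) -> np.ndarray:
        """Per-pixel focus-time estimate (µs from sweep start).

        The OUT onset marks the trailing event of the polarity inversion
        (two synaptic steps late); the last relay spike of the opposite
        polarity marks the leading event.  The focus time is the midpoint
        of the two marks — the average timing of the consecutive ON and OFF
        events straddling focus, read off the circuit's own spike record.
        """
        first = self.first_out_step[window]
        lead = self.lead_last_step[window]
        trail_step = first.astype(float) - DELAY_INPUT_OUT
        tf = np.where(lead >= 0, 0.5 * (lead + trail_step), trail_step)
        tf = tf * self.dt_us
        tf[first < 0] = np.nan
        return tf

    def spike_steps(self, slot: str) -> np.ndarray:
        """Boolean (steps, H, W) raster for slot in {ON, OFF, B_on, B_off,
        OUT, Sync} (requires record_trains=True at run time)."""
        if slot not in self.trains:
            raise KeyError(f"no recorded train for {slot!r}")
        return self.trains[slot]

    def neuron_spike_times_us(self, slot: str, row: int, col: int):
        (r0, _), (c0, _) = self.network.roi
        raster = self.spike_steps(slot)
        steps = np.nonzero(raster[:, row - r0, col - c0])[0]
        return steps * self.dt_us

    def to_csv(self, path, window: int = 0) -> None:
        """Write ``neuron_id,t_us`` rows for all recorded spikes."""
        h, w = self.network.roi_shape
        rows = []
        for slot_idx, slot in enumerate(_SLOT_NAMES):
            if slot not in self.trains:
                continue
            t_steps, ys, xs = np.nonzero(self.trains[slot])
            ids = (ys * w + xs) * 5 + slot_idx
            rows.append(np.column_stack([ids, t_steps * self.dt_us]))
        if "Sync" in self.trains:
            t_steps = np.nonzero(self.trains["Sync"])[0]
            ids = np.full(len(t_steps), self.network.sync_id)
            rows.append(np.column_stack([ids, t_steps * self.dt_us]))
        data = np.vstack(rows) if rows else np.empty((0, 2), dtype=int)
        data = data[np.lexsort((data[:, 0], data[:, 1]))]
        import pandas as pd
        pd.DataFrame(data, columns=["neuron_id", "t_us"]).to_csv(
            path, index=False)

    def raster_png(self, path, row: int, col: int) -> None:
        """Raster plot of one pixel's circuit (inputs, OUT, Sync)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 2.5))
        lanes = ["ON", "OFF", "OUT", "Sync"]
        for lane_idx, slot in enumerate(lanes):
            if slot not in self.trains:
                continue
            if slot == "Sync":
                times = np.nonzero(self.trains["Sync"])[0] * self.dt_us
            else:
                times = self.neuron_spike_times_us(slot, row, col)
            ax.eventplot(times, lineoffsets=len(lanes) - lane_idx,
                         linelengths=0.8)
        ax.set_yticks(range(1, len(lanes) + 1), lanes[::-1])
        ax.set_xlabel("time (µs)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def run(network: Network, stream: EventStream,
        sync_times: Sequence[float] | np.ndarray,
        record_trains: bool = False) -> SpikeRecord:
    """Simulate the array on an event stream.

    ``sync_times`` are the sweep-end times in µs (one per sweep window,
    strictly increasing); each window is simulated with fresh state — the
    Sync spike both strongly inhibits OUT and resets the circuit.  Events
    outside the roi are ignored (counted in ``ignored_events``); an unsorted
    stream raises.
    """
    sync_times = np.asarray(sync_times, dtype=float)
    if sync_times.size == 0:
        raise ValueError("at least one sync time is required")
    if np.any(np.diff(sync_times) <= 0):
        raise ValueError("sync_times must be strictly increasing")
    if len(stream) and np.any(np.diff(stream.t) < 0):
        raise ValueError("event stream must be time-sorted")
    p = network.params
    dt_us = int(round(p.dt * 1e6))
    (r0, r1), (c0, c1) = network.roi
    H, W = network.roi_shape

    inside = ((stream.y >= r0) & (stream.y < r1) &
              (stream.x >= c0) & (stream.x < c1))
    ignored = int(len(stream) - inside.sum())
    ev_step = (stream.t[inside] // dt_us).astype(np.int64)
    ev_y = (stream.y[inside] - r0).astype(np.int64)
    ev_x = (stream.x[inside] - c0).astype(np.int64)
    ev_on = stream.p[inside] > 0

    sync_steps = np.ceil(sync_times / dt_us).astype(np.int64)
    n_steps = int(sync_steps[-1]) + DELAY_SYNC + 1

    # binary per-step input relay rasters (one-step refractory collapse)
    on_r = np.zeros((n_steps, H, W), dtype=bool)
    off_r = np.zeros((n_steps, H, W), dtype=bool)
    ok = ev_step < n_steps
    on_r[ev_step[ok & ev_on], ev_y[ok & ev_on], ev_x[ok & ev_on]] = True
    off_r[ev_step[ok & ~ev_on], ev_y[ok & ~ev_on], ev_x[ok & ~ev_on]] = True

    n_win = len(sync_steps)
    first_out = np.full((n_win, H, W), -1, dtype=np.int64)
    lead_last = np.full((n_win, H, W), -1, dtype=np.int64)
    trail_on = np.zeros((n_win, H, W), dtype=bool)
    trains = {}
    if record_trains:
        for slot in ("B_on", "B_off", "OUT"):
            trains[slot] = np.zeros((n_steps, H, W), dtype=bool)
        trains["ON"], trains["OFF"] = on_r, off_r
        trains["Sync"] = np.zeros(n_steps, dtype=bool)
        trains["Sync"][sync_steps[sync_steps < n_steps]] = True

    win_starts = np.concatenate([[0], sync_steps[:-1] + DELAY_SYNC + 1])
    for w_idx, (k0, k_sync) in enumerate(zip(win_starts, sync_steps)):
        st_out = LIFState.zeros(p.lif_out, (H, W))
        st_bon = LIFState.zeros(p.lif_blocker, (H, W))
        st_boff = LIFState.zeros(p.lif_blocker, (H, W))
        bon_hist = np.zeros((2, H, W), dtype=bool)   # fired at k-1, k-2
        boff_hist = np.zeros((2, H, W), dtype=bool)
        out_prev = np.zeros((H, W), dtype=bool)
        last_on_in = np.full((H, W), -1, dtype=np.int64)   # relay spike bins
        last_off_in = np.full((H, W), -1, dtype=np.int64)
        k_end = min(int(k_sync) + DELAY_SYNC, n_steps - 1)
        for k in range(int(k0), k_end + 1):
            in_on_1 = on_r[k - 1] if k - 1 >= k0 else 0
            in_off_1 = off_r[k - 1] if k - 1 >= k0 else 0
            in_on_2 = on_r[k - 2] if k - 2 >= k0 else 0
            in_off_2 = off_r[k - 2] if k - 2 >= k0 else 0
            lif_step(st_bon, p.w_input_blocker * in_on_1, p.dt)
            lif_step(st_boff, p.w_input_blocker * in_off_1, p.dt)
            sync_in = p.w_sync if k == k_sync + DELAY_SYNC else 0.0
            clamp = bon_hist[0] | boff_hist[0]   # shunting inhibition
            st_out.v = np.where(clamp, p.lif_out.v_rest, st_out.v)
            i_out = (p.w_input_out * (np.asarray(in_on_2, dtype=float)
                                      + in_off_2)
                     + p.w_self * out_prev + sync_in)
            lif_step(st_out, i_out, p.dt)
            # relay spike bins seen so far by OUT (inputs up to bin k-2)
            silent = first_out[w_idx] < 0
            t_on2 = np.asarray(in_on_2, dtype=bool)
            t_off2 = np.asarray(in_off_2, dtype=bool)
            if t_on2.ndim:
                last_on_in = np.where(t_on2 & silent, k - DELAY_INPUT_OUT,
                                      last_on_in)
                last_off_in = np.where(t_off2 & silent, k - DELAY_INPUT_OUT,
                                       last_off_in)
            new_onset = st_out.spiked & silent
            if new_onset.any():
                first_out[w_idx][new_onset] = k
                trail_on[w_idx][new_onset] = t_on2[new_onset] if t_on2.ndim \
                    else bool(t_on2)
                lead = np.where(trail_on[w_idx], last_off_in, last_on_in)
                lead_last[w_idx][new_onset] = lead[new_onset]
            if record_trains:
                trains["B_on"][k] = st_bon.spiked
                trains["B_off"][k] = st_boff.spiked
                trains["OUT"][k] = st_out.spiked
            bon_hist = np.stack([st_bon.spiked, bon_hist[0]])
            boff_hist = np.stack([st_boff.spiked, boff_hist[0]])
            out_prev = st_out.spiked

    return SpikeRecord(network=network, dt_us=dt_us, sync_steps=sync_steps,
                       first_out_step=first_out, lead_last_step=lead_last,
                       trail_is_on=trail_on, ignored_events=ignored,
                       trains=trains)


def run_snn_engine(stream: EventStream, sync_time_us: float | None = None,
                   params: CircuitParams | None = None,
                   roi=None, record_trains: bool = False):
    """Convenience wrapper: build the array network for the stream's sensor,
    simulate one sweep, and return ``(tf_map_us, SpikeRecord)``."""
    params = params or CircuitParams()
    if sync_time_us is None:
        t_end = stream.meta.get("t_end", None)
        t_start = stream.meta.get("t_start", 0.0)
        if t_end is None:
            if len(stream) == 0:
                raise ValueError("cannot infer sync time from an empty stream")
            sync_time_us = float(stream.t.max())
        else:
            sync_time_us = (t_end - t_start) * 1e6
    net = build_network(stream.sensor_shape, roi=roi, params=params)
    rec = run(net, stream, [sync_time_us], record_trains=record_trains)
    return rec.focus_time_map(0), rec
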