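"""Reference (non-spiking) focus detection.

During a focal sweep a pixel first emits events of one polarity while its
blur shrinks, then the opposite polarity once focus has passed; the moment
of best focus ``t_f`` sits between the last event of the leading run and the
first event of the trailing run.  ``t_f`` is estimated as the average timing
of that straddling pair.  This module is the brute-force oracle the spiking
circuit is cross-validated against, plus the closed-form predictor of
individual event times for a known Gaussian-source intensity model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .scene_simulator import EventStream

__all__ = ["FocusDetection", "detect_tf", "detect_tf_map",
           "predict_event_time"]


@dataclass(frozen=True)
class FocusDetection:
    """Result of polarity-inversion detection on one pixel's train.

    ``t_f`` is the midpoint (µs) of the smallest-gap pair of consecutive
    opposite-polarity events; ``t_lead``/``t_trail`` are that pair's
    timestamps.  ``ambiguous`` is set when more than one inversion exists
    (the overlapping-edges failure mode).  ``valid`` is False when the train
    contains no inversion at all.
    """

    valid: bool
    t_f: float = np.nan
    t_lead: float = np.nan
    t_trail: float = np.nan
    ambiguous: bool = False
    n_inversions: int = 0


def default_max_gap_us() -> float:
    """Widest lead->trail interval accepted as a focus signature (µs).

    Matches the spiking circuit's coincidence window (membrane leak gate)
    so that oracle and SNN implement the same detection rule.
    """
    from .snn_core import CircuitParams
    return CircuitParams().coincidence_window * 1e6


def detect_tf(t, p, max_gap_us: float | None = None) -> FocusDetection:
    """Detect the time of focus in one pixel's event train.

    ``t`` (µs) must be sorted; ``p`` in {+1, -1}.  Scans consecutive pairs
    of opposite polarity no farther apart than ``max_gap_us`` (default: the
    circuit's coincidence window), picks the pair with the smallest time
    gap (earliest wins ties) and returns the pair midpoint.  A train with a
    single polarity, or whose opposite-polarity pairs are all wider than
    the gate, is invalid.  The ambiguity flag counts *all* polarity
    inversions in the train, gated or not: more than one means the pixel
    saw superimposed event streams from different edges (the
    overlapping-edges failure condition) and its focus time is unreliable.
    """
    if max_gap_us is None:
        max_gap_us = default_max_gap_us()
    t = np.asarray(t, dtype=float)
    p = np.asarray(p)
    if len(t) != len(p):
        raise ValueError("t and p must have equal length")
    if len(t) < 2:
        return FocusDetection(valid=False)
    if np.any(np.diff(t) < 0):
        raise ValueError("event train must be time-sorted")
    all_flips = np.nonzero(p[1:] != p[:-1])[0]
    gaps = t[all_flips + 1] - t[all_flips]
    keep = gaps <= max_gap_us
    flips, gaps = all_flips[keep], gaps[keep]
    if flips.size == 0:
        return FocusDetection(valid=False,
                              ambiguous=all_flips.size > 1,
                              n_inversions=int(all_flips.size))
    best = flips[np.argmin(gaps)]
    return FocusDetection(valid=True,
                          t_f=0.5 * (t[best] + t[best + 1]),
                          t_lead=float(t[best]),
                          t_trail=float(t[best + 1]),
                          ambiguous=all_flips.size > 1,
                          n_inversions=int(all_flips.size))


def detect_tf_map(stream: EventStream, max_gap_us: float | None = None):
    """Vectorised per-pixel focus detection over a whole stream.

    Returns ``(tf_map, ambiguity_mask, trail_map)``: the midpoint estimate,
    the multiple-inversion flag and the trailing-event time of the chosen
    pair, each as a (rows, cols) array (NaN / False where no inversion).
    """
    if max_gap_us is None:
        max_gap_us = default_max_gap_us()
    rows, cols = stream.sensor_shape
    tf_map = np.full((rows, cols), np.nan)
    trail_map = np.full((rows, cols), np.nan)
    amb = np.zeros((rows, cols), dtype=bool)
    if len(stream) == 0:
        return tf_map, amb, trail_map
    pid = stream.y.astype(np.int64) * cols + stream.x
    order = np.lexsort((stream.t, pid))
    t = stream.t[order].astype(float)
    p = stream.p[order]
    q = pid[order]
    same = q[1:] == q[:-1]
    flip = same & (p[1:] != p[:-1])
    all_idx = np.nonzero(flip)[0]
    # ambiguity counts all inversions, gated or not
    uq, counts = np.unique(q[all_idx], return_counts=True)
    my, mx = np.divmod(uq[counts > 1], cols)
    amb[my, mx] = True
    gap = t[all_idx + 1] - t[all_idx]
    keep = gap <= max_gap_us
    idx, gap = all_idx[keep], gap[keep]
    if idx.size == 0:
        return tf_map, amb, trail_map
    # smallest gap per pixel, earliest wins ties: stable sort by (pixel, gap)
    sel = np.lexsort((idx, gap, q[idx]))
    pix_sorted = q[idx][sel]
    first = np.ones(len(sel), dtype=bool)
    first[1:] = pix_sorted[1:] != pix_sorted[:-1]
    chosen = idx[sel[first]]
    py, px = np.divmod(q[chosen], cols)
    tf_map[py, px] = 0.5 * (t[chosen] + t[chosen + 1])
    trail_map[py, px] = t[chosen + 1]
    return tf_map, amb, trail_map


def predict_event_time(level_index: int, pixel_r: float, A: float, I0: float,
                       n: float, sigma_inverse: Callable[[float], float],
                       polarity: int = -1) -> float:
    """Closed-form time of the k-th threshold crossing at a Gaussian source.

    For intensity ``I(r, t) = A * exp(-r^2 / (2 sigma(t)^2))`` at a pixel a
    distance ``pixel_r`` from the source centre, the k-th event after a
    reference intensity ``I0`` occurs at log-level ``log I0 + polarity*k*n``
    and hence at

        t_k = sigma_inverse( sqrt( r^2 / (2 (log A - log I_k)) ) )

    ``sigma_inverse`` must invert sigma(t) on a monotone sweep segment.  The
    polarity follows the sign of dI/dt (-1 while the blur shrinks at a fixed
    off-centre pixel under this unnormalised profile).  As ``n -> 0+`` the
    prediction tends to the time at which I = I0.
    """
    if level_index < 0:
        raise ValueError("level_index must be non-negative")
    if pixel_r < 0:
        raise ValueError("pixel_r must be non-negative")
    if A <= 0 or I0 <= 0 or I0 > A:
        raise ValueError("need 0 < I0 <= A")
    if n <= 0:
        raise ValueError("threshold n must be positive")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    log_level = np.log(I0) + polarity * level_index * n
    denom = 2.0 * (np.log(A) - log_level)
    if denom <= 0:
        raise ValueError("crossing level at or above the source amplitude")
    return float(sigma_inverse(np.sqrt(pixel_r ** 2 / denom)))
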