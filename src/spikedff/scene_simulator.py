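"""Render depth-labelled scenes through a swept Gaussian blur and emit
address-events from per-pixel log-intensity threshold crossings.

The scene is a reflectance map with a per-pixel depth label (NaN marks
background with no ground truth: it renders as a uniform field and produces
no events of its own).  Each frame is composited far-to-near, every depth
layer convolved with the Gaussian PSF of its current blur diameter.  A
contrast-detector model then turns the per-pixel log-intensity trajectory
into signed events: whenever log I moves by the threshold ``n`` away from
the per-pixel reference level, an event is emitted, the reference steps by
``+/-n``, and the polarity follows the sign of dI/dt (ON = +1 for rising
intensity).  Timestamps are interpolated linearly inside the render step and
quantised to 1 microsecond in the public stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
import h5py
from scipy.ndimage import gaussian_filter

from .optics import (OpticalConfig, SweepProfile, blur_diameter, psf_sigma,
                     sweep_focus_at, sweep_time_of)

__all__ = [
    "Scene", "Event", "EventStream",
    "render_frame", "events_from_frames", "generate_events", "make_fixture",
    "fixture_optics", "default_sweep", "save_frame_png",
]

_LOG_FLOOR = 1e-6          # clamp for the log-intensity domain
_SIGMA_PX_CAP = 64.0       # kernel-size cap (in pixels), warns when hit


@dataclass
class Scene:
    """Depth-labelled reflectance map.

    ``reflectance`` in [0, 1]; ``depth`` per-pixel object depth in metres,
    NaN where no object is defined (uniform background at
    ``background_level``); both arrays share one shape.
    """

    reflectance: np.ndarray
    depth: np.ndarray
    background_level: float = 0.4

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.reflectance.shape != self.depth.shape:
            raise ValueError("reflectance and depth must have identical shape")
        if np.nanmin(self.reflectance, initial=0.0) < 0 or \
           np.nanmax(self.reflectance, initial=0.0) > 1:
            raise ValueError("reflectance must lie in [0, 1]")
        finite = self.depth[np.isfinite(self.depth)]
        if finite.size and finite.min() <= 0:
            raise ValueError("all defined depths must be positive")
        if not 0 <= self.background_level <= 1:
            raise ValueError("background_level must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.reflectance.shape

    @property
    def object_mask(self) -> np.ndarray:
        return np.isfinite(self.depth)

    def layer_depths(self) -> np.ndarray:
        """Unique finite depths, sorted far to near."""
        finite = self.depth[np.isfinite(self.depth)]
        return np.unique(finite)[::-1]


@dataclass(frozen=True)
class Event:
    """One address-event: time (µs), column x, row y, polarity +/-1."""

    t: int
    x: int
    y: int
    p: int

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("event time must be non-negative")
        if self.p not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class EventStream:
    """Time-sorted address-event stream as four parallel arrays.

    Timestamps are integer microseconds measured from the sweep window
    start.  Order is stable for equal timestamps: row-major pixel order,
    then polarity.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    sensor_shape: Tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int32)
        self.y = np.asarray(self.y, dtype=np.int32)
        self.p = np.asarray(self.p, dtype=np.int8)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.p)):
            raise ValueError("t, x, y, p must have equal length")
        if len(self.t) and np.any(np.diff(self.t) < 0):
            raise ValueError("event stream must be time-sorted")
        rows, cols = self.sensor_shape
        if len(self.t) and (self.x.min() < 0 or self.x.max() >= cols or
                            self.y.min() < 0 or self.y.max() >= rows):
            raise ValueError("event coordinates outside sensor_shape")

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self):
        for t, x, y, p in zip(self.t, self.x, self.y, self.p):
            yield Event(int(t), int(x), int(y), int(p))

    def pixel_train(self, x: int, y: int):
        """(t, p) arrays of this pixel's events, time-sorted."""
        sel = (self.x == x) & (self.y == y)
        return self.t[sel], self.p[sel]

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"t_us": self.t, "x": self.x, "y": self.y,
                      "p": self.p}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sensor_shape, meta=None) -> "EventStream":
        df = pd.read_csv(path)
        return cls(df["t_us"].to_numpy(), df["x"].to_numpy(),
                   df["y"].to_numpy(), df["p"].to_numpy(),
                   sensor_shape=tuple(sensor_shape), meta=meta or {})

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for name, arr in (("t_us", self.t), ("x", self.x),
                              ("y", self.y), ("p", self.p)):
                fh.create_dataset(name, data=arr)
            fh.attrs["sensor_rows"] = self.sensor_shape[0]
            fh.attrs["sensor_cols"] = self.sensor_shape[1]
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    fh.attrs[f"meta_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "EventStream":
        with h5py.File(path, "r") as fh:
            shape = (int(fh.attrs["sensor_rows"]), int(fh.attrs["sensor_cols"]))
            meta = {k[5:]: fh.attrs[k] for k in fh.attrs if k.startswith("meta_")}
            return cls(fh["t_us"][:], fh["x"][:], fh["y"][:], fh["p"][:],
                       sensor_shape=shape, meta=meta)


# ---------------------------------------------------------------------------
# rendering

def render_frame(scene: Scene, d: float, cfg: OpticalConfig,
                 boundary: str = "nearest") -> np.ndarray:
    """Intensity image of ``scene`` when the in-focus distance is ``d``.

    Each depth layer is convolved with a normalised 2-D Gaussian of spread
    ``sigma(z, d)`` (converted to pixels via the pixel pitch) and composited
    far-to-near over the uniform background; occlusion is resolved by the
    blurred layer mask without inter-layer blur bleeding.  Output in [0, 1].
    """
    img = np.full(scene.shape, scene.background_level, dtype=float)
    for z in scene.layer_depths():
        sigma_px = psf_sigma(blur_diameter(z, d, cfg), cfg) / cfg.pixel_pitch
        if sigma_px > _SIGMA_PX_CAP:
            warnings.warn(
                f"PSF sigma {sigma_px:.1f} px exceeds cap {_SIGMA_PX_CAP}; "
                "clamping", RuntimeWarning, stacklevel=2)
            sigma_px = _SIGMA_PX_CAP
        mask = (scene.depth == z).astype(float)
        layer = scene.reflectance * mask
        if sigma_px > 0:
            mask = gaussian_filter(mask, sigma_px, mode=boundary)
            layer = gaussian_filter(layer, sigma_px, mode=boundary)
        img = img * (1.0 - mask) + layer
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# event generation

def events_from_frames(frames: Iterable[np.ndarray], times, n: float,
                       t0_reset: bool = True):
    """Threshold-crossing engine: signed events from an intensity sequence.

    ``frames`` are intensity images sampled at ``times`` (seconds).  Per
    pixel a log-intensity reference is kept (initialised at the first frame
    when ``t0_reset``); each step emits ``floor(|dlog I|/n)`` events with
    linearly interpolated crossing times and steps the reference by ``n``
    per event.  Returns float-precision ``(t_s, x, y, p)`` arrays sorted by
    (t, y, x, p); quantisation to integer microseconds is left to callers.

    Intensities at or below zero are floor-clamped (with a warning) before
    taking logs.
    """
    if n <= 0:
        raise ValueError("threshold n must be positive")
    times = np.asarray(times, dtype=float)
    ts_out, x_out, y_out, p_out = [], [], [], []
    ref = None
    log_prev = None
    t_prev = None
    warned = False
    for t_cur, frame in zip(times, frames):
        frame = np.asarray(frame, dtype=float)
        if np.any(frame <= 0):
            if not warned:
                warnings.warn("non-positive intensity floor-clamped for log",
                              RuntimeWarning, stacklevel=2)
                warned = True
            frame = np.maximum(frame, _LOG_FLOOR)
        log_cur = np.log(frame)
        if ref is None:
            ref = log_cur.copy() if t0_reset else np.zeros_like(log_cur)
            log_prev, t_prev = log_cur, t_cur
            continue
        delta = log_cur - ref
        sign = np.sign(delta)
        count = np.floor(np.abs(delta) / n).astype(int)
        if count.any():
            rows, cols = np.nonzero(count)
            slope = log_cur - log_prev
            for k in range(1, count.max() + 1):
                sel = count[rows, cols] >= k
                r, c = rows[sel], cols[sel]
                level = ref[r, c] + sign[r, c] * k * n
                sl = slope[r, c]
                frac = np.where(sl != 0, (level - log_prev[r, c]) /
                                np.where(sl != 0, sl, 1.0), 1.0)
                frac = np.clip(frac, 0.0, 1.0)
                ts_out.append(t_prev + frac * (t_cur - t_prev))
                x_out.append(c)
                y_out.append(r)
                p_out.append(sign[r, c].astype(np.int8))
            ref += sign * count * n
        log_prev, t_prev = log_cur, t_cur
    if not ts_out:
        e = np.empty(0)
        return e, e.astype(np.int32), e.astype(np.int32), e.astype(np.int8)
    t = np.concatenate(ts_out)
    x = np.concatenate(x_out).astype(np.int32)
    y = np.concatenate(y_out).astype(np.int32)
    p = np.concatenate(p_out).astype(np.int8)
    order = np.lexsort((p, x, y, t))
    return t[order], x[order], y[order], p[order]


def generate_events(scene: Scene, profile: SweepProfile, cfg: OpticalConfig,
                    dt: float = 25e-6, t0_reset: bool = True,
                    boundary: str = "nearest") -> EventStream:
    """Simulate one focal sweep over ``scene`` and return the event stream.

    Renders the scene every ``dt`` seconds along the sweep and applies the
    threshold-crossing model.  A static scene (or a sweep that never changes
    any pixel's log intensity by ``n``) yields an empty stream.  Timestamps
    are microseconds from ``profile.t_start``, quantised to 1 µs.
    """
    if dt <= 0:
        raise ValueError("render step dt must be positive")
    n_steps = int(round(profile.duration / dt))
    if n_steps < 2:
        raise ValueError("sweep window shorter than two render steps")
    times = profile.t_start + np.arange(n_steps + 1) * dt
    times[-1] = min(times[-1], profile.t_end)
    frames = (render_frame(scene, sweep_focus_at(t, profile), cfg, boundary)
              for t in times)
    t_s, x, y, p = events_from_frames(frames, times, cfg.event_threshold_n,
                                      t0_reset=t0_reset)
    t_us = np.round((t_s - profile.t_start) * 1e6).astype(np.int64)
    order = np.lexsort((p, x, y, t_us))
    meta = {"t_start": profile.t_start, "t_end": profile.t_end,
            "sweep_kind": profile.kind, "d_near": profile.d_near,
            "d_far": profile.d_far, "dt": dt,
            "threshold_n": cfg.event_threshold_n}
    return EventStream(t_us[order], x[order], y[order], p[order],
                       sensor_shape=cfg.sensor_shape, meta=meta)


# ---------------------------------------------------------------------------
# fixtures

def fixture_optics(sensor: int = 64) -> OpticalConfig:
    """Desk-scale optics: a 64x64 region with 3x3-binned 15 µm pixels.

    Keeps the default focal length and aperture but coarsens the pixel pitch
    to 45 µm so that blur kernels stay resolvable on the small array.
    """
    return OpticalConfig(sensor_shape=(sensor, sensor),
                         pixel_pitch=45e-6)


def default_sweep(sweep_ms: float = 5.0) -> SweepProfile:
    """A 5 ms sweep, linear in optical power, from 0.18 m to 3.0 m.

    The far end stays just short of the desk-scale hyperfocal distance
    (~3.5 m for the 45 µm pitch), so the whole sweep stays inside the
    resolvable depth range while leaving room for trailing events from the
    farthest objects.
    """
    return SweepProfile(t_start=0.0, t_end=sweep_ms * 1e-3,
                        d_near=0.18, d_far=3.0)


def _texture(shape, rng, lo=0.35, hi=0.9, scale=1.5):
    """Smooth random reflectance texture in [lo, hi]."""
    noise = gaussian_filter(rng.standard_normal(shape), scale)
    noise -= noise.min()
    peak = noise.max()
    if peak > 0:
        noise /= peak
    return lo + (hi - lo) * noise


def _disc_mask(shape, center, radius):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def make_fixture(kind: str, params: dict | None = None, seed: int = 0,
                 cfg: OpticalConfig | None = None) -> Scene:
    """Deterministic test scenes.

    Kinds: ``sphere`` (uniform disc), ``bar`` (uniform rectangle),
    ``textured_plane`` (full-frame textured plane), ``multi_depth``
    (3 textured discs + 1 textured rectangle at staggered depths),
    ``two_edges_far`` / ``two_edges_near`` (two vertical bars at two depths
    whose inner edges are well separated / close enough for their blur discs
    to overlap during the sweep).
    """
    params = dict(params or {})
    cfg = cfg or fixture_optics()
    shape = params.pop("shape", cfg.sensor_shape)
    rng = np.random.default_rng(seed)
    bg = params.pop("background_level",
                    0.5 if kind.startswith("two_edges") else 0.4)
    refl = np.full(shape, bg, dtype=float)
    depth = np.full(shape, np.nan)

    def place(mask, z, level):
        if not mask.any():
            raise ValueError("fixture geometry exceeds the sensor")
        refl[mask] = level if np.isscalar(level) else level[mask]
        depth[mask] = z

    if kind == "sphere":
        z = params.pop("z", 0.33)
        radius = params.pop("radius", min(shape) // 4)
        center = params.pop("center", (shape[0] // 2, shape[1] // 2))
        level = params.pop("level", 0.85)
        if radius < 1 or radius > min(shape) // 2:
            raise ValueError("fixture geometry exceeds the sensor")
        place(_disc_mask(shape, center, radius), z, level)
    elif kind == "bar":
        z = params.pop("z", 0.5)
        r0, r1, c0, c1 = params.pop("box", (shape[0] // 4, 3 * shape[0] // 4,
                                            shape[1] // 3, 2 * shape[1] // 3))
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ValueError("fixture geometry exceeds the sensor")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        place(mask, z, params.pop("level", 0.85))
    elif kind == "textured_plane":
        z = params.pop("z", 0.5)
        place(np.ones(shape, dtype=bool), z, _texture(shape, rng))
    elif kind == "multi_depth":
        # uniform-reflectance objects: depth cues live at contours, as for
        # the silicon retina, which only sees contrast changes
        depths = params.pop("depths", (0.3, 0.6, 0.9, 1.2))
        if len(depths) < 3:
            raise ValueError("multi_depth needs at least 3 objects")
        levels = [0.85, 0.75, 0.9, 0.8, 0.7]
        q = min(shape) // 4
        centers = [(q, q), (q, 3 * q), (3 * q, q), (3 * q, 3 * q),
                   (2 * q, 2 * q)]
        radius = params.pop("radius", max(3, min(shape) // 7))
        if len(depths) > len(centers):
            raise ValueError("multi_depth supports at most 5 objects")
        for i, (z, center) in enumerate(zip(depths, centers)):
            if i == 3:  # one planar (square) object among the discs
                mask = np.zeros(shape, dtype=bool)
                mask[center[0] - radius:center[0] + radius,
                     center[1] - radius:center[1] + radius] = True
            else:
                mask = _disc_mask(shape, center, radius)
            place(mask, z, levels[i % len(levels)])
    elif kind in ("two_edges_far", "two_edges_near"):
        # a dark near bar and a bright far bar on mid-grey: in the overlap
        # region their blurred edges push intensity in opposite directions
        # at the same time, superimposing ON and OFF streams (the failure
        # precondition); with a wide gap the four edges stay independent
        z1 = params.pop("z1", 0.3)
        z2 = params.pop("z2", 0.6)
        gap = params.pop("gap", 24 if kind == "two_edges_far" else 2)
        width = params.pop("width", 12)
        level1 = params.pop("level1", 0.1)
        level2 = params.pop("level2", 0.9)
        mid = shape[1] // 2
        c1 = mid - gap // 2 - width   # bar 1: [c1, c1+width)
        c2 = mid + (gap + 1) // 2     # bar 2: [c2, c2+width)
        if c1 < 0 or c2 + width > shape[1]:
            raise ValueError("fixture geometry exceeds the sensor")
        m1 = np.zeros(shape, dtype=bool)
        m1[:, c1:c1 + width] = True
        m2 = np.zeros(shape, dtype=bool)
        m2[:, c2:c2 + width] = True
        place(m1, z1, level1)
        place(m2, z2, level2)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if params:
        raise ValueError(f"unused fixture params: {sorted(params)}")
    return Scene(refl, depth, background_level=bg)


def save_frame_png(path, frame: np.ndarray) -> None:
    """Export an intensity frame as 8-bit grayscale PNG."""
    from PIL import Image
    arr = np.clip(np.asarray(frame, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)
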