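"""Geometric optics for a focal-sweep depth-from-focus system.

The imaging model is a compound lens (liquid lens + offset lens + objective)
summarised by a single equivalent focal length ``f_eq`` and working f-number
``N``.  During a sweep the in-focus object distance ``d(t)`` is moved through
the scene; an object at depth ``z`` then casts a defocus blur circle of
diameter

    s = (f_eq**2 / N) * |z - d| / ((d - f_eq) * z)

on the sensor.  Aberrations and diffraction smear the ideal blur circle, so
the point-spread function is modelled as an isotropic Gaussian whose spread is
proportional to the blur diameter, ``sigma = alpha * s``.

All quantities are SI (metres, seconds) unless a name says otherwise.

The blur equation is usually written with the object moving and the focus
fixed; during a sweep the roles invert (``z`` fixed per pixel, ``d(t)``
swept).  The formula is symmetric in usage and is implemented as a plain
function of ``(z, d)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "OpticsDomainError",
    "SingularConfigurationError",
    "OpticalConfig",
    "LensStack",
    "SweepProfile",
    "blur_diameter",
    "psf_sigma",
    "focus_distance",
    "depth_from_focus",
    "hyperfocal",
    "sweep_focus_at",
    "sweep_time_of",
    "combined_focal_length",
    "save_config",
    "load_config",
]


class OpticsDomainError(ValueError):
    """An optical quantity was requested outside its physical domain."""


class SingularConfigurationError(OpticsDomainError):
    """A denominator in the depth inversion is (numerically) zero."""


@dataclass(frozen=True)
class OpticalConfig:
    """Summary parameters of the compound imaging system.

    Parameters
    ----------
    f_eq :
        Equivalent focal length of the full lens stack (m).
    N :
        Working f-number (dimensionless).
    alpha :
        PSF proportionality constant, ``sigma = alpha * s``.  The default
        0.25 second-moment matches a Gaussian to a uniform blur disc of
        diameter ``s`` (a pillbox of radius s/2 has per-axis RMS s/4).
    pixel_pitch :
        Sensor pixel size (m).
    sensor_shape :
        (rows, cols) of the sensor array.
    event_threshold_n :
        Log-intensity contrast threshold of the event camera (> 0).
    """

    f_eq: float = 0.0285
    N: float = 2.0
    alpha: float = 0.25
    pixel_pitch: float = 15e-6
    sensor_shape: Tuple[int, int] = (480, 640)
    event_threshold_n: float = 0.15

    def __post_init__(self):
        if self.f_eq <= 0:
            raise OpticsDomainError("f_eq must be positive")
        if self.N <= 0:
            raise OpticsDomainError("N must be positive")
        if self.alpha <= 0:
            raise OpticsDomainError("alpha must be positive")
        if self.pixel_pitch <= 0:
            raise OpticsDomainError("pixel_pitch must be positive")
        if self.event_threshold_n <= 0:
            raise OpticsDomainError("event_threshold_n must be positive")
        rows, cols = self.sensor_shape
        if rows < 1 or cols < 1:
            raise OpticsDomainError("sensor_shape must be at least 1x1")


@dataclass(frozen=True)
class LensStack:
    """The three-element tunable stack: liquid lens, offset lens, objective.

    ``f_ll_range`` is the focal-length range of the electrically tunable
    liquid lens; ``f_offset`` is the (negative) relay lens; ``f_objective``
    forms the image on the sensor.  ``d_cam_obj`` is the camera-to-object
    distance used by the thin-lens focus equation.
    """

    f_ll_range: Tuple[float, float] = (0.050, 0.120)
    f_offset: float = -0.150
    f_objective: float = 0.035
    d_cam_obj: float = 1.0

    def __post_init__(self):
        lo, hi = self.f_ll_range
        if not lo < hi:
            raise OpticsDomainError("f_ll_range must satisfy min < max")
        if self.f_objective <= 0:
            raise OpticsDomainError("f_objective must be positive")


def combined_focal_length(stack: LensStack, f_ll: float) -> float:
    """Equivalent focal length, thin-lenses-in-contact approximation.

    ``1/f_eq = 1/f_ll + 1/f_o + 1/f_ol``.  This ignores the (unpublished)
    inter-lens spacings and is an approximation only; ``OpticalConfig.f_eq``
    is the authoritative parameter.
    """
    lo, hi = stack.f_ll_range
    if not (lo <= f_ll <= hi):
        raise OpticsDomainError(f"f_ll={f_ll} outside range {stack.f_ll_range}")
    power = 1.0 / f_ll + 1.0 / stack.f_offset + 1.0 / stack.f_objective
    if power <= 0:
        raise OpticsDomainError("combined power is non-positive")
    return 1.0 / power


@dataclass(frozen=True)
class SweepProfile:
    """Monotone mapping from time to in-focus distance during one sweep.

    ``kind='power'`` interpolates linearly in optical power (1/d, dioptres),
    matching the roughly linear current-to-power behaviour of a liquid lens;
    ``kind='distance'`` interpolates linearly in d itself.
    """

    t_start: float = 0.0
    t_end: float = 5e-3
    d_near: float = 0.18
    d_far: float = 1.8
    kind: str = "power"
    period: float | None = None

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise OpticsDomainError("sweep window must have positive duration")
        if self.d_near <= 0 or self.d_far <= 0:
            raise OpticsDomainError("sweep distances must be positive")
        if self.d_near == self.d_far:
            raise OpticsDomainError("sweep must be strictly monotone (d_near != d_far)")
        if self.kind not in ("power", "distance"):
            raise OpticsDomainError(f"unknown sweep kind {self.kind!r}")
        if self.period is not None and self.period < self.duration:
            raise OpticsDomainError("period must cover the sweep window")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def d_of_t(self, t):
        """In-focus distance at time ``t`` (s); strictly monotone in t."""
        return sweep_focus_at(t, self)

    def time_of(self, d):
        """Inverse of :meth:`d_of_t` (s)."""
        return sweep_time_of(d, self)

    def reversed(self) -> "SweepProfile":
        return SweepProfile(self.t_start, self.t_end, self.d_far, self.d_near,
                            self.kind, self.period)


def _check_window(t, profile: SweepProfile, tol: float = 1e-12):
    t = np.asarray(t, dtype=float)
    if np.any(t < profile.t_start - tol) or np.any(t > profile.t_end + tol):
        raise OpticsDomainError(
            f"time outside sweep window [{profile.t_start}, {profile.t_end}]")
    return t


def sweep_focus_at(t, profile: SweepProfile):
    """In-focus distance ``d`` at sweep time ``t``.

    Raises :class:`OpticsDomainError` if ``t`` is outside the sweep window.
    Accepts scalars or arrays.
    """
    t = _check_window(t, profile)
    frac = (t - profile.t_start) / profile.duration
    if profile.kind == "power":
        p0, p1 = 1.0 / profile.d_near, 1.0 / profile.d_far
        d = 1.0 / (p0 + (p1 - p0) * frac)
    else:
        d = profile.d_near + (profile.d_far - profile.d_near) * frac
    return d if d.shape else float(d)

def sweep_time_of(d, profile: SweepProfile):
    """Sweep time at which distance ``d`` is in focus (inverse of d(t))."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise OpticsDomainError("d must be positive")
    if profile.kind == "power":
        p0, p1 = 1.0 / profile.d_near, 1.0 / profile.d_far
        frac = (1.0 / d - p0) / (p1 - p0)
    else:
        frac = (d - profile.d_near) / (profile.d_far - profile.d_near)
    if np.any(frac < -1e-9) or np.any(frac > 1 + 1e-9):
        raise OpticsDomainError("d is not reached within the sweep window")
    t = profile.t_start + np.clip(frac, 0.0, 1.0) * profile.duration
    return t if t.shape else float(t)


def blur_diameter(z, d, cfg: OpticalConfig):
    """Diameter ``s`` (m) of the geometric blur circle.

    ``s = (f_eq^2/N) * |z - d| / ((d - f_eq) * z)`` for an object at depth
    ``z`` when the in-focus distance is ``d``.  Zero iff ``z == d``.
    """
    z = np.asarray(z, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(z <= 0):
        raise OpticsDomainError("object depth z must be positive")
    if np.any(d <= cfg.f_eq):
        raise OpticsDomainError("in-focus distance d must exceed f_eq")
    c = cfg.f_eq ** 2 / cfg.N
    s = c * np.abs(z - d) / ((d - cfg.f_eq) * z)
    return s if s.shape else float(s)


def psf_sigma(s, cfg: OpticalConfig):
    """Gaussian PSF spread (m), ``sigma = alpha * s``."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise OpticsDomainError("blur diameter must be non-negative")
    sig = cfg.alpha * s
    return sig if sig.shape else float(sig)


def focus_distance(f_eq: float, d_cam_obj):
    """Thin-lens position of the in-focus point.

    ``d = f_eq + f_eq^2 / (D_cam/obj - f_eq)``; tends to ``f_eq`` as the
    object recedes to infinity and is strictly decreasing in ``D_cam/obj``.
    """
    if f_eq <= 0:
        raise OpticsDomainError("f_eq must be positive")
    d_cam_obj = np.asarray(d_cam_obj, dtype=float)
    if np.any(d_cam_obj <= f_eq):
        raise OpticsDomainError("D_cam/obj must exceed f_eq")
    d = f_eq + f_eq ** 2 / (d_cam_obj - f_eq)
    return d if d.shape else float(d)


def depth_from_focus(s_tf, d, cfg: OpticalConfig, branch: str = "near",
                     tol: float = 1e-12):
    """Invert the blur equation: depth ``z`` from blur ``s_tf`` at focus
    distance ``d``.

    The absolute value in the blur equation folds two depths onto one blur
    diameter; ``branch`` selects which:

    - ``'near'``: object closer than the focus plane (z < d),
      ``z = c*d / (s*(d - f_eq) + c)`` with ``c = f_eq^2/N``;
    - ``'far'``: object beyond the focus plane (z > d),
      ``z = c*d / (c - s*(d - f_eq))``.

    ``s_tf = 0`` returns ``d`` on either branch.  Exact inverse of
    :func:`blur_diameter` on the matching branch.
    """
    if branch not in ("near", "far"):
        raise ValueError(f"branch must be 'near' or 'far', got {branch!r}")
    s_tf = np.asarray(s_tf, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(s_tf < 0):
        raise OpticsDomainError("blur diameter must be non-negative")
    if np.any(d <= cfg.f_eq):
        raise OpticsDomainError("in-focus distance d must exceed f_eq")
    c = cfg.f_eq ** 2 / cfg.N
    if branch == "near":
        denom = s_tf * (d - cfg.f_eq) + c
    else:
        denom = c - s_tf * (d - cfg.f_eq)
    if np.any(np.abs(denom) <= tol * c):
        raise SingularConfigurationError(
            "depth inversion singular: blur reaches the aperture-limited bound")
    if branch == "far" and np.any(denom < 0):
        raise SingularConfigurationError(
            "far-branch blur exceeds the bound reachable from any finite depth")
    z = c * d / denom
    return z if z.shape else float(z)


def hyperfocal(cfg: OpticalConfig, coc: float | None = None):
    """Hyperfocal distance ``H = f_eq^2/(N*coc) + f_eq`` (m).

    ``coc`` is the acceptable circle-of-confusion diameter; defaults to one
    pixel pitch.  Beyond ``H`` everything appears sharp and depth cannot be
    resolved by the sweep.
    """
    if coc is None:
        coc = cfg.pixel_pitch
    if coc <= 0:
        raise OpticsDomainError("circle of confusion must be positive")
    return cfg.f_eq ** 2 / (cfg.N * coc) + cfg.f_eq


# ---------------------------------------------------------------------------
# flat key-value serialization

def save_config(path, cfg: OpticalConfig, stack: LensStack | None = None,
                profile: SweepProfile | None = None) -> None:
    """Write optics/stack/sweep parameters as a flat JSON object (SI units)."""
    out = {f"optics.{k}": v for k, v in asdict(cfg).items()}
    if stack is not None:
        out.update({f"stack.{k}": v for k, v in asdict(stack).items()})
    if profile is not None:
        out.update({f"sweep.{k}": v for k, v in asdict(profile).items()})
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)


def load_config(path):
    """Inverse of :func:`save_config`.

    Returns ``(OpticalConfig, LensStack | None, SweepProfile | None)``.
    """
    with open(path) as fh:
        flat = json.load(fh)

    def group(prefix):
        g = {k.split(".", 1)[1]: v for k, v in flat.items()
             if k.startswith(prefix + ".")}
        for key, val in g.items():
            if isinstance(val, list):
                g[key] = tuple(val)
        return g

    cfg = OpticalConfig(**group("optics"))
    stack = LensStack(**group("stack")) if group("stack") else None
    profile = SweepProfile(**group("sweep")) if group("sweep") else None
    return cfg, stack, profile
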