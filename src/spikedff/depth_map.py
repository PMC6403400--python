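"""Convert per-pixel focus times to metric depth and score against truth.

At the detected polarity inversion the object sits on the in-focus plane,
so the depth of a pixel with focus time ``t_f`` is simply the sweep's
in-focus distance ``d(t_f)``.  The off-focus inversion (blur diameter ->
depth) is exposed by :mod:`spikedff.optics` and exercised by the test
suite; it is not needed on the focus mark itself where the residual blur is
zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .optics import OpticalConfig, SweepProfile, hyperfocal
from .scene_simulator import Scene

__all__ = ["DepthMap", "ErrorReport", "assemble", "evaluate"]


@dataclass
class DepthMap:
    """Per-pixel metric depth with validity and ambiguity masks.

    ``depth`` is NaN exactly where ``valid_mask`` is False.
    """

    depth: np.ndarray
    valid_mask: np.ndarray
    ambiguity_mask: np.ndarray
    n_outside_window: int = 0
    n_beyond_hyperfocal: int = 0

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.ambiguity_mask = np.asarray(self.ambiguity_mask, dtype=bool)
        if not (self.depth.shape == self.valid_mask.shape
                == self.ambiguity_mask.shape):
            raise ValueError("depth and masks must share one shape")
        if np.any(np.isfinite(self.depth) != self.valid_mask):
            raise ValueError("depth must be finite exactly where valid")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.depth.shape

    # -- writers -----------------------------------------------------------
    def to_csv(self, path) -> None:
        np.savetxt(path, self.depth, delimiter=",", fmt="%.6g")

    def to_png16(self, path) -> None:
        """16-bit grayscale PNG; the metres-per-count scale goes to a
        sidecar ``<path>.scale.txt``."""
        from PIL import Image
        finite = self.depth[self.valid_mask]
        zmax = float(finite.max()) if finite.size else 1.0
        scale = zmax / 65535.0 if zmax > 0 else 1.0
        counts = np.zeros(self.shape, dtype=np.uint16)
        counts[self.valid_mask] = np.round(finite / scale).astype(np.uint16)
        Image.fromarray(counts).save(path)
        with open(str(path) + ".scale.txt", "w") as fh:
            fh.write(f"meters_per_count = {scale!r}\n"
                     f"invalid_value = 0\n")

    def to_color_png(self, path, cmap: str = "viridis_r") -> None:
        """Colour-coded depth (perceptually uniform ramp, near = warm);
        invalid pixels are black."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from PIL import Image
        finite = self.depth[self.valid_mask]
        lo = float(finite.min()) if finite.size else 0.0
        hi = float(finite.max()) if finite.size else 1.0
        norm = (self.depth - lo) / (hi - lo) if hi > lo else self.depth * 0
        rgba = plt.get_cmap(cmap)(np.nan_to_num(norm))
        rgba[~self.valid_mask] = (0, 0, 0, 1)
        Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(path)


@dataclass
class ErrorReport:
    """Relative-error summary over valid, ground-truth-defined pixels."""

    mean_relative_error: float      # percent
    std_relative_error: float       # percent
    relative_error: np.ndarray      # per-pixel |dz|/z, NaN where unscored
    histogram: Tuple[np.ndarray, np.ndarray]
    n_pixels: int

    def as_dict(self) -> dict:
        counts, edges = self.histogram
        return {"mean_relative_error": self.mean_relative_error,
                "std_relative_error": self.std_relative_error,
                "n_pixels": self.n_pixels,
                "histogram_counts": counts.tolist(),
                "histogram_edges": edges.tolist()}


def assemble(tf_map_us: np.ndarray, profile: SweepProfile,
             cfg: OpticalConfig, ambiguity_mask: np.ndarray | None = None,
             coc: float | None = None) -> DepthMap:
    """Depth map from a per-pixel focus-time map (µs from sweep start).

    Pixels whose focus time falls outside the sweep window are invalidated
    (counted), as are depths beyond the hyperfocal distance, where the sweep
    cannot resolve depth.  NaN entries of ``tf_map_us`` stay invalid.
    """
    tf = np.asarray(tf_map_us, dtype=float)
    t_s = profile.t_start + tf * 1e-6
    in_window = np.isfinite(tf) & (t_s >= profile.t_start) & \
        (t_s <= profile.t_end)
    n_outside = int((np.isfinite(tf) & ~in_window).sum())
    depth = np.full(tf.shape, np.nan)
    if in_window.any():
        depth[in_window] = profile.d_of_t(t_s[in_window])
    H = hyperfocal(cfg, coc)
    beyond = in_window & (depth > H)
    n_beyond = int(beyond.sum())
    depth[beyond] = np.nan
    valid = in_window & ~beyond
    amb = (np.zeros(tf.shape, dtype=bool) if ambiguity_mask is None
           else np.asarray(ambiguity_mask, dtype=bool))
    return DepthMap(depth, valid, amb, n_outside_window=n_outside,
                    n_beyond_hyperfocal=n_beyond)


def evaluate(dm: DepthMap, scene: Scene, bins: int = 50) -> ErrorReport:
    """Relative depth error against a scene's ground-truth labels.

    Scored only where the map is valid *and* the scene defines a depth;
    ``|z_est - z_true| / z_true`` per pixel, mean and std in percent.
    Raises when the two masks never overlap.
    """
    if dm.shape != scene.shape:
        raise ValueError("depth map and scene shapes differ")
    mask = dm.valid_mask & np.isfinite(scene.depth)
    if not mask.any():
        raise ValueError("no valid pixel overlaps the ground truth")
    rel = np.full(dm.shape, np.nan)
    rel[mask] = np.abs(dm.depth[mask] - scene.depth[mask]) / scene.depth[mask]
    scored = rel[mask]
    hi = max(float(scored.max()) * 100.0, 1.0)
    counts, edges = np.histogram(scored * 100.0, bins=bins, range=(0.0, hi))
    return ErrorReport(mean_relative_error=float(scored.mean() * 100.0),
                       std_relative_error=float(scored.std() * 100.0),
                       relative_error=rel,
                       histogram=(counts, edges),
                       n_pixels=int(mask.sum()))
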