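"""Attention-map data model and preprocessing.

An attention map is a dense H×W grid of nonnegative gaze intensity
accumulated from eye-tracking fixations over a stimulus image.  The
preprocessing chain implemented here mirrors a standard gaze-analysis
workflow: render fixation streams into heat maps, average within a
participant group, subtract the group's common attention pattern (the
universal eyes/nose/mouth bias), smooth, and finally apply a noise
threshold that zeroes low-intensity pixels.

Coordinate convention, used throughout the package: row-major arrays,
origin at the top-left corner, 0-based integer pixel indices, ``x`` is
the column and ``y`` the row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "STAGES",
    "IntensityGrid",
    "FaceMask",
    "AttentionMap",
    "FixationEvent",
    "ThresholdSpec",
    "render_from_fixations",
    "average_maps",
    "common_attention",
    "subtract_common",
    "smooth",
    "apply_noise_threshold",
]

#: Processing stages in their only legal order.
STAGES = ("raw", "common_subtracted", "smoothed", "thresholded_low", "thresholded_high")

#: Default viewing window per trial, in milliseconds.
VIEWING_WINDOW_MS = 7000.0

#: Default rendering radius for a single fixation, in pixels.
DEFAULT_RADIUS = 25


class IntensityGrid:
    """A dense 2-D grid of nonnegative intensities.

    Negative input values are clipped to zero at construction so that
    nonnegativity is a global invariant of every public operation.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray, dtype=np.float64):
        arr = np.asarray(values, dtype=dtype)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"intensity grid must be 2-D and nonempty, got shape {arr.shape}")
        self.values = np.clip(arr, 0.0, None)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "IntensityGrid":
        return IntensityGrid(self.values.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntensityGrid(shape={self.shape}, max={self.values.max():g})"


def as_values(grid) -> np.ndarray:
    """Return the underlying 2-D array of an IntensityGrid / AttentionMap /
    SaliencyMap / plain array, without copying."""
    if isinstance(grid, IntensityGrid):
        return grid.values
    if hasattr(grid, "grid") and isinstance(grid.grid, IntensityGrid):
        return grid.grid.values
    arr = np.asarray(grid, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class FaceMask:
    """Boolean face-region mask gating coverage computations."""

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("face mask must be 2-D")
        if not m.any():
            raise ValueError("face mask has zero area")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class AttentionMap:
    """One participant's (or a group-average) heat map for one image."""

    grid: IntensityGrid
    participant_id: str
    group: str  # "clinician" | "nonclinician"
    image_id: str
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def advanced(self, new_values: np.ndarray, stage: str, **meta) -> "AttentionMap":
        """Return a new map at a later stage; stage may never move backwards."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage cannot regress from {self.stage!r} to {stage!r}")
        out = replace(self, grid=IntensityGrid(new_values), stage=stage)
        for k, v in meta.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class FixationEvent:
    """A single gaze fixation: where, when, and for how long."""

    participant_id: str
    image_id: str
    x: int
    y: int
    onset_ms: float
    duration_ms: float

    def validate(self, shape: Optional[tuple[int, int]] = None,
                 window_ms: float = VIEWING_WINDOW_MS) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"fixation duration must be positive, got {self.duration_ms}")
        if self.onset_ms < 0 or self.onset_ms + self.duration_ms > window_ms + 1e-9:
            raise ValueError(
                f"fixation [{self.onset_ms}, {self.onset_ms + self.duration_ms}] ms "
                f"outside the {window_ms} ms viewing window")
        if shape is not None:
            h, w = shape
            if not (0 <= self.x < w and 0 <= self.y < h):
                raise ValueError(
                    f"fixation at (x={self.x}, y={self.y}) outside the {h}x{w} grid")


@dataclass(frozen=True)
class ThresholdSpec:
    """How to resolve a noise threshold to an absolute intensity cutoff.

    modes:
      ``absolute``          — ``value`` is the cutoff itself.
      ``fraction_of_max``   — cutoff is ``value`` times the map maximum.
      ``coverage_fraction`` — cutoff chosen by rank selection so that the
                              nonzero in-mask pixel count is as close as
                              possible to ``value`` times the mask area
                              (requires a FaceMask).
    """

    mode: str
    value: float

    def __post_init__(self):
        if self.mode not in ("absolute", "fraction_of_max", "coverage_fraction"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.value < 0:
            raise ValueError("threshold value must be >= 0")
        if self.mode in ("fraction_of_max", "coverage_fraction") and self.value > 1:
            raise ValueError(f"{self.mode} value must be <= 1")


def _gaussian_kernel(radius: int) -> np.ndarray:
    """Truncated Gaussian bump (sigma = radius/2, support radius px, peak 1)."""
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    r2 = ax[None, :] ** 2 + ax[:, None] ** 2
    sigma = radius / 2.0
    k = np.exp(-r2 / (2.0 * sigma * sigma))
    k[r2 > radius * radius] = 0.0
    return k


_KERNEL_CACHE: dict[int, np.ndarray] = {}


def render_from_fixations(fixations: Sequence[FixationEvent],
                          shape: tuple[int, int],
                          radius: int = DEFAULT_RADIUS,
                          *,
                          group: str = "clinician",
                          dtype=np.float64) -> AttentionMap:
    """Render a fixation stream into a raw attention map.

    Each fixation deposits a radially decaying kernel (truncated Gaussian,
    sigma = radius/2) centred at its pixel, scaled by its duration in ms;
    deposits from successive fixations sum, so total map mass is linear in
    total fixation time away from the borders.

    An empty stream yields an all-zero map; fixations must all share one
    participant and image, and lie inside the grid.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    h, w = shape
    out = np.zeros((h, w), dtype=dtype)
    if not fixations:
        return AttentionMap(IntensityGrid(out, dtype=dtype), participant_id="",
                            group=group, image_id="", stage="raw")

    pids = {f.participant_id for f in fixations}
    iids = {f.image_id for f in fixations}
    if len(pids) != 1 or len(iids) != 1:
        raise ValueError(f"fixations mix participants {pids} / images {iids}")

    kern = _KERNEL_CACHE.get(radius)
    if kern is None:
        kern = _gaussian_kernel(radius)
        _KERNEL_CACHE[radius] = kern

    for f in fixations:
        f.validate(shape=shape)
        y, x = int(f.y), int(f.x)
        y0, y1 = max(0, y - radius), min(h, y + radius + 1)
        x0, x1 = max(0, x - radius), min(w, x + radius + 1)
        ky0, kx0 = y0 - (y - radius), x0 - (x - radius)
        out[y0:y1, x0:x1] += f.duration_ms * kern[ky0:ky0 + (y1 - y0), kx0:kx0 + (x1 - x0)]

    return AttentionMap(IntensityGrid(out, dtype=dtype), participant_id=fixations[0].participant_id,
                        group=group, image_id=fixations[0].image_id, stage="raw")


def _check_uniform(maps: Sequence[AttentionMap], attr: str) -> str:
    vals = {getattr(m, attr) for m in maps}
    if len(vals) != 1:
        raise ValueError(f"maps disagree on {attr}: {sorted(vals)}")
    return vals.pop()


def average_maps(maps: Sequence[AttentionMap]) -> AttentionMap:
    """Pixel-wise arithmetic mean of same-image maps → a GROUP_AVG map."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    shape = maps[0].grid.shape
    for m in maps:
        if m.grid.shape != shape:
            raise ValueError(f"shape mismatch: {m.grid.shape} vs {shape}")
    image_id = _check_uniform(maps, "image_id")
    group = _check_uniform(maps, "group")
    stage = maps[0].stage
    mean = np.mean(np.stack([m.values for m in maps]), axis=0)
    return AttentionMap(IntensityGrid(mean), participant_id="GROUP_AVG",
                        group=group, image_id=image_id, stage=stage)


def common_attention(all_maps_of_group: Sequence[AttentionMap]) -> AttentionMap:
    """The group's common attention pattern: the mean over every
    participant×image map of one group, across all images.

    This is the eyes/nose/mouth bias shared by all observers of faces; it
    is subtracted from individual maps to expose condition-specific gaze.
    """
    if not all_maps_of_group:
        raise ValueError("cannot build a common-attention map from no maps")
    group = _check_uniform(all_maps_of_group, "group")
    shape = all_maps_of_group[0].grid.shape
    for m in all_maps_of_group:
        if m.grid.shape != shape:
            raise ValueError(f"shape mismatch: {m.grid.shape} vs {shape}")
    mean = np.mean(np.stack([m.values for m in all_maps_of_group]), axis=0)
    return AttentionMap(IntensityGrid(mean), participant_id="GROUP_AVG",
                        group=group, image_id="COMMON", stage="raw")


def subtract_common(amap: AttentionMap, common: AttentionMap) -> AttentionMap:
    """Subtract the group's common attention, clipping negatives at zero."""
    if amap.group != common.group:
        raise ValueError(f"group mismatch: map is {amap.group!r}, common is {common.group!r}")
    if amap.grid.shape != common.grid.shape:
        raise ValueError("shape mismatch between map and common map")
    diff = np.clip(amap.values - common.values, 0.0, None)
    return amap.advanced(diff, "common_subtracted")


def smooth(amap: AttentionMap, kernel: int = 15) -> AttentionMap:
    """Box-filter smoothing that preserves the pre-smoothing maximum.

    Uses a uniform kernel×kernel mean with shrink-to-valid edge handling
    (border pixels are averaged over the in-bounds part of their window),
    then rescales globally so the maximum equals the input maximum — a
    deterministic 'intensity boost' that keeps the map quantitative.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"smoothing kernel must be odd and >= 1, got {kernel}")
    v = amap.values
    if kernel == 1:
        return amap.advanced(v.copy(), "smoothed")
    num = uniform_filter(v, size=kernel, mode="constant", cval=0.0)
    den = uniform_filter(np.ones_like(v), size=kernel, mode="constant", cval=0.0)
    sm = num / den
    old_max = v.max()
    new_max = sm.max()
    if new_max > 0:
        sm *= old_max / new_max
    return amap.advanced(sm, "smoothed")


def resolve_cutoff(values: np.ndarray, spec: ThresholdSpec,
                   mask: Optional[FaceMask] = None) -> float:
    """Resolve a ThresholdSpec to an absolute intensity cutoff for ``values``."""
    if spec.mode == "absolute":
        return float(spec.value)
    if spec.mode == "fraction_of_max":
        return float(spec.value) * float(values.max())
    # coverage_fraction: rank selection on in-mask values
    if mask is None:
        raise ValueError("coverage_fraction threshold requires a FaceMask")
    from .saliency import coverage_cutoff  # shared rank-selection rule
    return coverage_cutoff(values, mask, spec.value)


def apply_noise_threshold(amap: AttentionMap, spec: ThresholdSpec,
                          mask: Optional[FaceMask] = None,
                          level: str = "low") -> AttentionMap:
    """Zero all pixels strictly below the resolved cutoff.

    ``level`` ("low" | "high") names the resulting stage; the low threshold
    removes spurious gaze signal, the high one keeps only peak attention.
    Pixels at or above the cutoff keep their original values.
    """
    if level not in ("low", "high"):
        raise ValueError(f"level must be 'low' or 'high', got {level!r}")
    t = resolve_cutoff(amap.values, spec, mask=mask)
    out = np.where(amap.values < t, 0.0, amap.values)
    return amap.advanced(out, f"thresholded_{level}")
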