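"""Occlusion saliency and coverage-matched thresholding.

Saliency is computed by the occlusion method: slide a square box over the
image, zero out the covered pixels, and record how much the classifier's
predicted probability for the target label drops.  Regions whose removal
hurts the prediction carry positive saliency; regions the model ignores
score zero.  Because occlusion maps are much denser than human gaze maps,
a coverage threshold is applied afterwards so both maps contribute equal
numbers of active pixels to any overlap metric.

Any classifier can be plugged in through :class:`ClassifierContract`; a
deterministic prototype-distance classifier is bundled for synthetic
studies and tests (:class:`PrototypeClassifier`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.transform import resize

from .maps import AttentionMap, FaceMask, IntensityGrid, as_values

__all__ = [
    "ClassifierContract",
    "SaliencyMap",
    "OcclusionConfig",
    "PrototypeClassifier",
    "UnreliableSaliencyError",
    "occlusion_saliency",
    "ensemble_saliency",
    "coverage_cutoff",
    "coverage_threshold",
    "match_coverage",
    "saliency_at_resolution",
]


@runtime_checkable
class ClassifierContract(Protocol):
    """Anything that maps an image grid to a probability vector.

    ``labels`` is the ordered label list; ``predict`` must return
    nonnegative probabilities summing to one (within 1e-6) and be
    deterministic for a fixed input.
    """

    labels: Sequence[str]

    def predict(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class SaliencyMap:
    """Per-pixel positive contribution of image content to one label."""

    grid: IntensityGrid
    image_id: str
    target_label: str
    box: int
    stride: int

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass(frozen=True)
class OcclusionConfig:
    """Occlusion sweep geometry: box size, stride, and fill value."""

    box: int = 20
    stride: int = 10
    fill_value: float = 0.0

    def __post_init__(self):
        if not (1 <= self.stride <= self.box):
            raise ValueError(f"need 1 <= stride <= box, got stride={self.stride}, box={self.box}")


class UnreliableSaliencyError(ValueError):
    """Raised when the target probability is too close to zero for the
    occlusion drops to be meaningful."""


class PrototypeClassifier:
    """Deterministic toy classifier: softmax over negative mean-squared
    distance to one prototype image per label.

    The probability of a label rises as the input approaches that label's
    prototype, so the discriminative pixels are exactly those where the
    prototypes differ — which makes the truly salient region analytically
    known in synthetic studies.
    """

    def __init__(self, labels: Sequence[str], prototypes: dict[str, np.ndarray],
                 temperature: float = 0.01):
        if set(labels) != set(prototypes):
            raise ValueError("labels and prototype keys differ")
        self.labels = list(labels)
        shape = next(iter(prototypes.values())).shape
        for k, p in prototypes.items():
            if p.shape != shape:
                raise ValueError(f"prototype {k!r} shape {p.shape} != {shape}")
        self._protos = np.stack([np.asarray(prototypes[l], dtype=np.float64) for l in self.labels])
        self.input_shape = shape
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.temperature = float(temperature)

    def predict(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.shape != self.input_shape:
            raise ValueError(f"expected image shape {self.input_shape}, got {img.shape}")
        d2 = np.mean((self._protos - img[None]) ** 2, axis=(1, 2))
        logits = -d2 / self.temperature
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()


def occlusion_offsets(length: int, box: int, stride: int) -> range:
    """Offsets at which a box of size ``box`` fits fully inside ``length``."""
    if box > length:
        return range(0)
    return range(0, length - box + 1, stride)


def occlusion_saliency(image: np.ndarray, clf: ClassifierContract, target: str,
                       cfg: OcclusionConfig = OcclusionConfig(),
                       image_id: str = "") -> SaliencyMap:
    """Occlusion saliency of ``clf`` for ``target`` on ``image``.

    Boxes are placed only fully inside the image, at offsets 0, stride,
    2·stride, … per axis.  Each box's drop = p_target(original) −
    p_target(occluded), clipped at zero; a pixel's saliency is the mean
    drop over all boxes covering it (zero if no box covers it).

    Raises :class:`UnreliableSaliencyError` if the target probability is
    ≤ 1e-4, and warns below 1e-2.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    ti = list(clf.labels).index(target)
    p0 = np.asarray(clf.predict(img))
    if p0[ti] <= 1e-4:
        raise UnreliableSaliencyError(
            f"target {target!r} probability {p0[ti]:.2e} too close to zero; "
            "the occlusion saliency map would not be reliable")
    if p0[ti] < 1e-2:
        warnings.warn(f"target {target!r} probability {p0[ti]:.3g} is low; "
                      "saliency may be noisy", stacklevel=2)

    drop_sum = np.zeros((h, w))
    cover = np.zeros((h, w))
    work = img.copy()
    for y0 in occlusion_offsets(h, cfg.box, cfg.stride):
        for x0 in occlusion_offsets(w, cfg.box, cfg.stride):
            patch = work[y0:y0 + cfg.box, x0:x0 + cfg.box].copy()
            work[y0:y0 + cfg.box, x0:x0 + cfg.box] = cfg.fill_value
            p = np.asarray(clf.predict(work))
            work[y0:y0 + cfg.box, x0:x0 + cfg.box] = patch
            drop = max(float(p0[ti] - p[ti]), 0.0)
            drop_sum[y0:y0 + cfg.box, x0:x0 + cfg.box] += drop
            cover[y0:y0 + cfg.box, x0:x0 + cfg.box] += 1.0
    sal = np.divide(drop_sum, cover, out=np.zeros_like(drop_sum), where=cover > 0)
    return SaliencyMap(IntensityGrid(sal), image_id=image_id, target_label=target,
                       box=cfg.box, stride=cfg.stride)


def ensemble_saliency(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Pixel-wise mean of saliency maps from an ensemble of models."""
    if not maps:
        raise ValueError("cannot average an empty list of saliency maps")
    first = maps[0]
    for m in maps:
        if m.target_label != first.target_label:
            raise ValueError("ensemble members disagree on target label")
        if m.grid.shape != first.grid.shape:
            raise ValueError("ensemble members disagree on shape")
        if m.image_id != first.image_id:
            raise ValueError("ensemble members disagree on image id")
    mean = np.mean(np.stack([m.values for m in maps]), axis=0)
    return SaliencyMap(IntensityGrid(mean), image_id=first.image_id,
                       target_label=first.target_label, box=first.box, stride=first.stride)


def coverage_cutoff(values: np.ndarray, mask: FaceMask, target_fraction: float) -> float:
    """Cutoff t such that #{in-mask pixels ≥ t, > 0} best matches
    round(target_fraction × mask.area).

    Rank selection on the sorted in-mask values — equivalent to a grid
    search over cutoffs.  With ties at the boundary value, all tied pixels
    are kept if that is closer to the target count, else all dropped; at
    an exact tie the sparser map wins.
    """
    if not (0 < target_fraction <= 1):
        raise ValueError("target_fraction must be in (0, 1]")
    if mask.shape != values.shape:
        raise ValueError("mask / map shape mismatch")
    v = values[mask.mask]
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("map has no nonzero pixels inside the face mask")
    k_target = int(round(target_fraction * mask.area))
    if k_target >= pos.size:
        return float(pos.min())  # keep every positive pixel
    if k_target <= 0:
        k_target = 1
    t_lo = float(np.partition(pos, pos.size - k_target)[pos.size - k_target])
    n_keep_all = int((pos >= t_lo).sum())   # keeps all pixels tied at t_lo
    n_drop_ties = int((pos > t_lo).sum())
    if n_drop_ties == 0:
        return float(t_lo)  # dropping the ties would empty the map
    if abs(n_keep_all - k_target) < abs(n_drop_ties - k_target):
        return float(t_lo)
    # drop the ties when closer, or at an exact tie (prefer the sparser map)
    return float(np.nextafter(t_lo, np.inf))


def coverage_threshold(grid, mask: FaceMask, target_fraction: float) -> IntensityGrid:
    """Keep only the in-mask pixels at or above the coverage cutoff.

    Pixels outside the mask are zeroed; surviving pixels keep their
    original magnitudes.
    """
    values = as_values(grid)
    t = coverage_cutoff(values, mask, target_fraction)
    out = np.where(mask.mask & (values >= t) & (values > 0), values, 0.0)
    return IntensityGrid(out)


def match_coverage(sal: SaliencyMap, reference: AttentionMap, mask: FaceMask) -> SaliencyMap:
    """Threshold a saliency map so its in-mask nonzero count matches the
    (already noise-thresholded) reference attention map's."""
    ref_count = int(np.count_nonzero(reference.values[mask.mask]))
    if ref_count == 0:
        raise ValueError("reference map has no nonzero pixels inside the face mask")
    target_fraction = ref_count / mask.area
    thr = coverage_threshold(sal.grid, mask, target_fraction)
    return SaliencyMap(thr, image_id=sal.image_id, target_label=sal.target_label,
                       box=sal.box, stride=sal.stride)


def saliency_at_resolution(image: np.ndarray, clf, target: str,
                           cfg: OcclusionConfig = OcclusionConfig(),
                           out_shape: tuple[int, int] | None = None,
                           image_id: str = "") -> SaliencyMap:
    """Run occlusion saliency at the classifier's native resolution and map
    the result back to ``out_shape`` by nearest-neighbour resampling.

    The stimulus is resampled (anti-aliased) to ``clf.input_shape`` before
    the sweep; study images are analysed at the classifier's resolution
    and compared at map resolution.
    """
    clf_shape = getattr(clf, "input_shape", None) or np.asarray(image).shape
    img = np.asarray(image, dtype=np.float64)
    if img.shape != tuple(clf_shape):
        img = resize(img, clf_shape, anti_aliasing=True, preserve_range=True)
    sal = occlusion_saliency(img, clf, target, cfg, image_id=image_id)
    if out_shape is None or tuple(out_shape) == sal.grid.shape:
        return sal
    up = resize(sal.values, out_shape, order=0, anti_aliasing=False, preserve_range=True)
    return SaliencyMap(IntensityGrid(up), image_id=image_id, target_label=target,
                       box=cfg.box, stride=cfg.stride)
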