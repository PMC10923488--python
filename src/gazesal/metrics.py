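"""Pairwise map-comparison metrics and fixation timing summaries.

Two complementary metrics quantify agreement between a pair of maps:

* **IoU** binarizes both maps (any nonzero pixel → 1) and returns
  |A∩B| / |A∪B|, in [0, 1].
* **Symmetric KL** treats each map as a 2-D probability distribution over
  the union of their supports and returns ½[KL(p‖q) + KL(q‖p)] in nats,
  in [0, ∞).  An epsilon is added inside the support before normalising
  so that disjoint pixels do not produce infinities.

Participant-level uncertainty comes from a bootstrap that resamples
participants (the independent unit), rebuilds the group-average map with
the full preprocessing chain, and recomputes the metric.  Area-of-interest
(AOI) summaries report per-participant fixation dwell time and time to
first fixation inside hand-drawn polygons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import rel_entr
from shapely.geometry import Point, Polygon

from .maps import AttentionMap, FaceMask, FixationEvent, as_values

__all__ = [
    "ComparisonResult",
    "AOIRegion",
    "AOIMetrics",
    "iou",
    "symmetric_kl",
    "bootstrap_sd",
    "bootstrap_sds_both",
    "aoi_metrics",
]


@dataclass
class ComparisonResult:
    """IoU/KL (with bootstrap SDs) for one map pair at one threshold level."""

    image_id: str
    pair: str
    level: str  # "low" | "high"
    iou: float
    kl: float
    iou_sd: float = np.nan
    kl_sd: float = np.nan
    n_pixels_a: int = 0
    n_pixels_b: int = 0


@dataclass(frozen=True)
class AOIRegion:
    """A named polygonal area of interest over one image."""

    image_id: str
    name: str
    polygon: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.polygon) < 3:
            raise ValueError("an AOI polygon needs at least 3 vertices")

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class AOIMetrics:
    """Fixation timing summary for one participant × AOI."""

    participant_id: str
    image_id: str
    aoi: str
    duration_of_fixation_ms: float
    time_to_first_whole_fixation_ms: Optional[float]


def iou(a, b) -> float:
    """Intersection-over-union of the binarized (nonzero) supports.

    Returns NaN — a flagged missing value, never 0 or 1 — when both maps
    are entirely zero, since overlap is then undefined.
    """
    va, vb = as_values(a), as_values(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    sa, sb = va > 0, vb > 0
    union = int(np.count_nonzero(sa | sb))
    if union == 0:
        return float("nan")
    inter = int(np.count_nonzero(sa & sb))
    return inter / union


def symmetric_kl(a, b, eps: Optional[float] = None,
                 mask: Optional[FaceMask] = None) -> float:
    """Symmetric Kullback–Leibler divergence between two maps, in nats.

    Both maps are restricted to the union of their nonzero supports
    (optionally intersected with a face mask), shifted by ``eps`` and
    rescaled to proper probability distributions; the result is the mean
    of the two directed divergences.  ``eps`` defaults to 1e-9 times each
    map's own mean nonzero intensity, which keeps the metric exactly
    invariant under rescaling either map.
    """
    va, vb = as_values(a), as_values(b)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    support = (va > 0) | (vb > 0)
    if mask is not None:
        support &= mask.mask
    if not support.any():
        raise ValueError("both maps are zero on the analysis support")
    pa, pb = va[support], vb[support]
    if eps is None:
        eps_a = 1e-9 * float(pa[pa > 0].mean()) if (pa > 0).any() else 0.0
        eps_b = 1e-9 * float(pb[pb > 0].mean()) if (pb > 0).any() else 0.0
    else:
        eps_a = eps_b = float(eps)
    if eps_a <= 0 or eps_b <= 0:
        if not np.array_equal(pa > 0, pb > 0):
            raise ValueError("eps must be positive when supports differ "
                             "(directed KL would be infinite)")
        eps_a = eps_b = 0.0
    p = pa + eps_a
    q = pb + eps_b
    p = p / p.sum()
    q = q / q.sum()
    kl_pq = float(rel_entr(p, q).sum())
    kl_qp = float(rel_entr(q, p).sum())
    return 0.5 * (kl_pq + kl_qp)


def _metric_fn(metric) -> Callable[[np.ndarray, np.ndarray], float]:
    if callable(metric):
        return metric
    if metric == "iou":
        return iou
    if metric == "symmetric_kl":
        return symmetric_kl
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_sd(participant_maps: Sequence[AttentionMap], other, metric,
                 prep: Callable[[Sequence[AttentionMap]], object],
                 B: int = 1000, seed: int = 0) -> float:
    """Bootstrap SD of a map-comparison metric over participants.

    Each replicate resamples participants with replacement, rebuilds the
    group map through ``prep`` (typically subtract-common → average →
    threshold), and recomputes ``metric`` against the fixed ``other`` map.
    Replicates whose metric is undefined (all-zero map) are dropped with a
    warning.  Deterministic for a fixed seed.
    """
    sds = bootstrap_sds_both(participant_maps, other, [metric], prep, B=B, seed=seed)
    return sds[0]


def bootstrap_sds_both(participant_maps: Sequence[AttentionMap], other,
                       metrics: Sequence, prep, B: int = 1000, seed: int = 0) -> list[float]:
    """Like :func:`bootstrap_sd` but evaluates several metrics on the same
    resampled replicates (one preprocessing pass per replicate)."""
    n = len(participant_maps)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    if B < 100:
        raise ValueError("bootstrap needs B >= 100 replicates")
    fns = [_metric_fn(m) for m in metrics]
    other_v = as_values(other)
    rng = np.random.default_rng(seed)
    vals: list[list[float]] = [[] for _ in fns]
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        rebuilt = prep([participant_maps[i] for i in idx])
        rv = as_values(rebuilt)
        try:
            row = [f(rv, other_v) for f in fns]
        except ValueError:
            dropped += 1
            continue
        if any(np.isnan(x) for x in row):
            dropped += 1
            continue
        for lst, x in zip(vals, row):
            lst.append(x)
    if dropped:
        warnings.warn(f"dropped {dropped} of {B} bootstrap replicates with an "
                      "undefined metric (all-zero resampled map)", stacklevel=2)
    out = []
    for lst in vals:
        if len(lst) < 2:
            raise ValueError("too few valid bootstrap replicates to estimate an SD")
        out.append(float(np.std(lst, ddof=1)))
    return out


def aoi_metrics(fixations: Sequence[FixationEvent],
                aois: Sequence[AOIRegion]) -> list[AOIMetrics]:
    """Dwell time and first-fixation latency per participant × AOI.

    A fixation counts toward an AOI when its point lies inside or on the
    boundary of the polygon.  ``duration_of_fixation_ms`` sums matching
    durations; ``time_to_first_whole_fixation_ms`` is the earliest
    matching onset, or None when no fixation lands inside (in which case
    the dwell time is 0 — the two always agree).
    """
    fixs = sorted(fixations, key=lambda f: (f.participant_id, f.onset_ms))
    out: list[AOIMetrics] = []
    for region in aois:
        poly = region.shapely()
        per: dict[str, AOIMetrics] = {}
        for f in fixs:
            if f.image_id != region.image_id:
                continue
            m = per.get(f.participant_id)
            if m is None:
                m = per[f.participant_id] = AOIMetrics(
                    f.participant_id, region.image_id, region.name, 0.0, None)
            if poly.covers(Point(f.x, f.y)):  # boundary counts as inside
                m.duration_of_fixation_ms += f.duration_ms
                if m.time_to_first_whole_fixation_ms is None:
                    m.time_to_first_whole_fixation_ms = f.onset_ms
        out.extend(per[p] for p in sorted(per))
    return out
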