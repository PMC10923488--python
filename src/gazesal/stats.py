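"""Participant-response statistics and random-effects pooling.

Covers the study-level statistics around the map comparisons: per-image
and overall accuracy of each participant group at calling an image
affected vs unaffected, a 2×2 Pearson chi-square comparing the groups,
and DerSimonian–Laird random-effects pooling of per-image metric
estimates (the "RE Model" of a forest plot).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "ResponseRecord",
    "MetaResult",
    "accuracy_table",
    "chi_square_2x2",
    "random_effects_pool",
]

#: Floor applied to zero variances before inverse-variance weighting.
VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's affected/unaffected call for one image."""

    participant_id: str
    group: str  # "clinician" | "nonclinician"
    image_id: str
    truth_affected: bool
    response_affected: bool
    condition_named_correctly: Optional[bool] = None

    @property
    def correct(self) -> bool:
        return self.truth_affected == self.response_affected


@dataclass
class MetaResult:
    """Random-effects pooled estimate with its uncertainty."""

    pooled: float
    se: float
    ci95: tuple[float, float]
    tau2: float
    k: int


def accuracy_table(records: Sequence[ResponseRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate correct/incorrect counts per image × group and overall.

    Returns ``(per_image, overall)``: ``per_image`` has one row per
    image × group with correct / incorrect / named-condition counts;
    ``overall`` has one row per group with summed counts and the
    percentage correct.  A duplicated participant × image pair is an
    error (each participant answers each image once).
    """
    if not records:
        raise ValueError("no response records")
    seen = set()
    for r in records:
        key = (r.participant_id, r.image_id)
        if key in seen:
            raise ValueError(f"duplicate response for participant {r.participant_id!r} "
                             f"on image {r.image_id!r}")
        seen.add(key)
    df = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "group": [r.group for r in records],
            "correct": [int(r.correct) for r in records],
            "incorrect": [int(not r.correct) for r in records],
            "named_condition": [int(bool(r.condition_named_correctly)) for r in records],
        }
    )
    per_image = (df.groupby(["image_id", "group"], sort=True)[["correct", "incorrect", "named_condition"]]
                 .sum().reset_index())
    overall = per_image.groupby("group", sort=True)[["correct", "incorrect", "named_condition"]].sum()
    overall["pct_correct"] = 100.0 * overall["correct"] / (overall["correct"] + overall["incorrect"])
    return per_image, overall.reset_index()


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2×2
    table [[a, b], [c, d]]; returns (statistic, p_value)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def random_effects_pool(estimates: Sequence[float],
                        variances: Sequence[float]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of per-study estimates.

    With weights wᵢ = 1/vᵢ, Q = Σwᵢ(yᵢ − ȳ_w)² and C = Σwᵢ − Σwᵢ²/Σwᵢ,
    the between-study variance is τ² = max(0, (Q − (k−1))/C); the pooled
    estimate then uses weights 1/(vᵢ + τ²), with se = (Σw*)^(-1/2) and a
    normal 95% interval.  Zero variances are floored at 1e-8 so no study
    receives infinite weight.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D sequences")
    k = y.size
    if k == 0:
        raise ValueError("nothing to pool (k = 0)")
    if (v < 0).any():
        raise ValueError("variances must be nonnegative")
    v = np.maximum(v, VARIANCE_FLOOR)
    w = 1.0 / v
    if k == 1:
        tau2 = 0.0
    else:
        ybar = float((w * y).sum() / w.sum())
        q = float((w * (y - ybar) ** 2).sum())
        c = float(w.sum() - (w ** 2).sum() / w.sum())
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    wstar = 1.0 / (v + tau2)
    pooled = float((wstar * y).sum() / wstar.sum())
    se = float(wstar.sum() ** -0.5)
    ci = (pooled - 1.96 * se, pooled + 1.96 * se)
    return MetaResult(pooled=pooled, se=se, ci95=ci, tau2=tau2, k=k)
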