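"""Non-parametric group comparisons, boxplot summaries, and limb volume.

Nothing here assumes normality: group contrasts use the two-sided
Mann-Whitney U test (exact null distribution for small combined samples,
normal approximation with tie correction otherwise), and distributions are
summarized by median/quartiles as in the standard box-and-whisker plot.
The limb-volume helper turns five evenly spaced circumference measurements
into a volume by stacking two truncated cones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney", "significance_stars", "BoxplotSummary",
           "boxplot_summary", "CircumferenceSeries", "limb_volume", "frustum_volume"]


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p)``.

    The exact null distribution is used when the combined sample size is
    at most 20 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    """Boxplot annotation convention: ``*`` p<0.05, ``**`` p<0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(sample) -> BoxplotSummary:
    """Median, quartiles (linear interpolation), 1.5-IQR whiskers, outliers.

    Whiskers sit on the most extreme data points within 1.5 IQR of the
    quartiles; points beyond are reported as outliers.
    """
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(x[(x < lo_fence) | (x > hi_fence)]))
    return BoxplotSummary(float(med), float(q1), float(q3),
                          float(inside.min()), float(inside.max()), outliers)


@dataclass(frozen=True)
class CircumferenceSeries:
    """Five limb circumferences (cm) at points 0.5 cm apart, the first
    1 cm above the calcaneus.  Points 2 and 4 are measured but unused by
    the two-segment volume scheme; they are retained for reporting."""

    circumferences_cm: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.circumferences_cm)
        if len(c) != 5:
            raise ValueError("exactly five circumference points required")
        if any(not np.isfinite(v) or v <= 0 for v in c):
            raise ValueError("circumferences must be positive and finite")
        object.__setattr__(self, "circumferences_cm", c)


def frustum_volume(r_top: float, r_bottom: float, height: float) -> float:
    """Volume of a truncated cone: ``pi * h * (R^2 + R r + r^2) / 3``."""
    return np.pi * height * (r_top**2 + r_top * r_bottom + r_bottom**2) / 3.0


def limb_volume(series: CircumferenceSeries) -> float:
    """Two-segment truncated-cone limb volume in cm^3.

    Radii come from circumferences at points 1, 3 and 5 (``r = C / 2 pi``);
    each segment spans two 0.5 cm steps, i.e. height 1 cm, and the two
    frustum volumes are added.
    """
    c = series.circumferences_cm
    r1, r3, r5 = (c[0] / (2 * np.pi), c[2] / (2 * np.pi), c[4] / (2 * np.pi))
    return float(frustum_volume(r1, r3, 1.0) + frustum_volume(r3, r5, 1.0))
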