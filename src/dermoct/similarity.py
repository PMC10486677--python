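"""Curve proximity factor: a similarity statistic for depth profiles.

For two non-negative curves X and Y on a common depth grid,

    S = 1 - sum_i |X_i - Y_i| / ( (1/2) * sum_i (X_i + Y_i) )

S = 1 exactly when X = Y, S = -1 when the curves have disjoint support,
and S is symmetric and invariant to scaling both curves jointly.  It is
an affine transform of the Bray-Curtis dissimilarity BC:  S = 1 - 2 BC.
Profiles are normalized to their maximum before comparison by default, so
S measures shape similarity rather than brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ascan import AScan
from .attenuation import normalize_to_max
from .cohort import LabeledProfileSet
from .preprocess import remove_air
from .stats import mann_whitney, significance_stars

__all__ = ["AlignedPair", "align_profiles", "cpf", "group_cpf"]


@dataclass(frozen=True)
class AlignedPair:
    """Two non-negative intensity vectors on one depth grid."""

    x: np.ndarray
    y: np.ndarray
    axial_pitch_um: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or x.size == 0:
            raise ValueError("x and y must be 1-D, equal-length and non-empty")
        if np.any(x < 0) or np.any(y < 0):
            raise ValueError("curves must be non-negative")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


def align_profiles(a: AScan, b: AScan) -> AlignedPair:
    """Put two profiles on a common surface-origin grid.

    Probe-origin inputs have their air gap removed first; the pair is then
    truncated to the shorter length.  Resampling across different pitches
    is out of scope, so mismatched pitches are an error.
    """
    if a.axial_pitch_um != b.axial_pitch_um:
        raise ValueError("profiles have different axial pitches; resampling "
                         "is not supported")
    a = remove_air(a)
    b = remove_air(b)
    n = min(len(a), len(b))
    return AlignedPair(a.intensities[:n], b.intensities[:n], a.axial_pitch_um)


def cpf(pair: AlignedPair) -> float:
    """Curve proximity factor S of an aligned pair; S in [-1, 1]."""
    total = float(np.sum(pair.x + pair.y))
    if total <= 0:
        raise ValueError("CPF undefined: both curves are identically zero")
    return float(1.0 - np.sum(np.abs(pair.x - pair.y)) / (0.5 * total))


def group_cpf(
    profile_set: LabeledProfileSet,
    reference_group: str = "healthy",
    normalize: bool = True,
    max_depth_um: float | None = None,
) -> pd.DataFrame:
    """CPF summary of each group against the reference group.

    Every cross pair (group profile, reference profile) contributes one S
    value; the table reports mean +/- SD per group.  As a significance
    reference the within-reference pair distribution (all unordered pairs
    inside the reference group) is used: the star marks a Mann-Whitney
    difference between cross-pair and within-reference S values, i.e.
    "less similar to healthy than healthy is to itself".
    """
    def prep(scan: AScan) -> AScan:
        s = remove_air(scan)
        if max_depth_um is not None:
            n = int(np.ceil(max_depth_um / s.axial_pitch_um))
            s = s.with_intensities(s.intensities[:max(n, 1)])
        return normalize_to_max(s) if normalize else s

    ref = [prep(p.scan) for p in profile_set if p.group == reference_group]
    if not ref:
        raise ValueError(f"reference group {reference_group!r} is empty")
    within = [cpf(align_profiles(ref[i], ref[j]))
              for i in range(len(ref)) for j in range(i + 1, len(ref))]

    rows = []
    for g in profile_set.groups():
        if g == reference_group:
            continue
        others = [prep(p.scan) for p in profile_set if p.group == g]
        values = np.array([cpf(align_profiles(x, y)) for x in others for y in ref])
        row = {"group": g, "reference": reference_group,
               "n_pairs": values.size, "cpf_mean": values.mean(),
               "cpf_sd": values.std(ddof=1) if values.size > 1 else 0.0,
               "p_vs_within_reference": np.nan, "stars": ""}
        if within and values.size:
            _, p = mann_whitney(values, np.asarray(within))
            row["p_vs_within_reference"] = p
            row["stars"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)
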