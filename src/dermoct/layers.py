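"""Skin-layer landmarks on averaged A-scans, and layer thicknesses.

On an averaged skin A-scan the first intensity maximum sits inside the
stratum corneum, the first local minimum after it marks the stratum-corneum
/ viable-epidermis boundary, and the second maximum marks the start of the
dermis.  The two thicknesses follow directly from the landmark indices and
the axial pitch; dividing by the tissue refractive index (default 1.4)
converts optical depth, which the device reports in air, to physical depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .ascan import AScan
from .cohort import LabeledProfileSet
from .stats import mann_whitney, significance_stars

__all__ = ["LayerLandmarks", "LandmarkError", "find_landmarks",
           "thicknesses_um", "group_thickness_report"]


class LandmarkError(ValueError):
    """Raised when the expected peak/valley/peak structure is absent."""


@dataclass(frozen=True)
class LayerLandmarks:
    """Indices of the three layer landmarks on a surface-origin grid.

    ``surface_idx`` is the start of the stratum corneum (0 for a
    surface-origin profile), ``sc_end_idx`` the local minimum at the
    stratum-corneum / viable-epidermis boundary, ``dermis_start_idx`` the
    second maximum where the dermis begins.  ``sc_peak_idx`` (the first
    maximum) is kept for diagnostics and overlays.
    """

    surface_idx: int
    sc_end_idx: int
    dermis_start_idx: int
    sc_peak_idx: int

    def __post_init__(self) -> None:
        if not self.surface_idx < self.sc_end_idx < self.dermis_start_idx:
            raise ValueError(
                "landmark order violated: need surface < sc_end < dermis_start, "
                f"got {self.surface_idx}, {self.sc_end_idx}, {self.dermis_start_idx}")


def find_landmarks(profile: AScan, prominence_frac: float = 0.02) -> LayerLandmarks:
    """Locate the peak/valley/peak landmark triple.

    Extrema are accepted only with prominence of at least
    ``prominence_frac`` of the profile maximum, which rejects the
    micro-extrema speckle leaves even on averaged profiles.  The profile
    should be surface-origin and noise-filtered.
    """
    if profile.origin != "surface":
        raise ValueError("find_landmarks expects a surface-origin profile")
    y = profile.intensities
    if not 0 < prominence_frac < 1:
        raise ValueError("prominence_frac must lie in (0, 1)")
    prominence = prominence_frac * y.max()
    maxima, _ = find_peaks(y, prominence=prominence)
    if maxima.size < 2:
        raise LandmarkError(
            f"landmarks not found: {maxima.size} prominent maxima, need 2 "
            "(first peak and dermis peak)")
    minima, _ = find_peaks(-y, prominence=prominence)
    sc_peak = int(maxima[0])
    after = minima[minima > sc_peak]
    if after.size == 0:
        raise LandmarkError("landmarks not found: no prominent minimum after "
                            "the first peak (stratum-corneum boundary)")
    sc_end = int(after[0])
    second = maxima[maxima > sc_end]
    if second.size == 0:
        raise LandmarkError("landmarks not found: no prominent maximum after "
                            "the boundary minimum (dermis onset)")
    return LayerLandmarks(surface_idx=0, sc_end_idx=sc_end,
                          dermis_start_idx=int(second[0]), sc_peak_idx=sc_peak)


def landmarks_overlay(landmarks: LayerLandmarks, profile: AScan) -> dict:
    """JSON-serializable overlay coordinates (index, depth_um, intensity)
    for plotting landmark markers on a profile."""
    out = {}
    for name, idx in (("surface", landmarks.surface_idx),
                      ("sc_peak", landmarks.sc_peak_idx),
                      ("sc_end", landmarks.sc_end_idx),
                      ("dermis_start", landmarks.dermis_start_idx)):
        out[name] = {"index": int(idx),
                     "depth_um": float(idx * profile.axial_pitch_um),
                     "intensity": float(profile.intensities[idx])}
    return out


def thicknesses_um(
    landmarks: LayerLandmarks,
    axial_pitch_um: float,
    n_tissue: float = 1.4,
) -> tuple[float, float]:
    """(stratum-corneum, viable-epidermis) thickness in micrometres.

    ``n_tissue=1`` returns optical (air-equivalent) thickness; the default
    1.4 converts to physical thickness in tissue.
    """
    if axial_pitch_um <= 0 or n_tissue <= 0:
        raise ValueError("axial_pitch_um and n_tissue must be positive")
    sc = (landmarks.sc_end_idx - landmarks.surface_idx) * axial_pitch_um / n_tissue
    epi = (landmarks.dermis_start_idx - landmarks.sc_end_idx) * axial_pitch_um / n_tissue
    return float(sc), float(epi)


def profile_thicknesses(
    profile_set: LabeledProfileSet,
    prominence_frac: float = 0.02,
    n_tissue: float = 1.4,
) -> pd.DataFrame:
    """Per-profile thickness table with columns
    subject, group, sc_um, epi_um (profiles without landmarks are dropped
    and counted in ``df.attrs['n_failed']``)."""
    rows, failed = [], 0
    for p in profile_set:
        try:
            lm = find_landmarks(p.scan, prominence_frac)
        except LandmarkError:
            failed += 1
            continue
        sc, epi = thicknesses_um(lm, p.scan.axial_pitch_um, n_tissue)
        rows.append({"subject": p.subject_id, "group": p.group,
                     "sc_um": sc, "epi_um": epi})
    df = pd.DataFrame(rows, columns=["subject", "group", "sc_um", "epi_um"])
    df.attrs["n_failed"] = failed
    return df


def group_thickness_report(
    profile_set: LabeledProfileSet,
    prominence_frac: float = 0.02,
    n_tissue: float = 1.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boxplot-style summary plus pairwise tests, per layer.

    Returns ``(summary, pairwise)``: one summary row per (group, layer)
    with n/median/quartiles, and one pairwise row per (layer, group pair)
    with the two-sided Mann-Whitney p-value and significance stars
    (``*`` p<0.05, ``**`` p<0.01).
    """
    per = profile_thicknesses(profile_set, prominence_frac, n_tissue)
    if per.empty:
        raise LandmarkError("no profile yielded a full landmark triple")
    layers = {"stratum_corneum": "sc_um", "viable_epidermis": "epi_um"}
    summary_rows, pair_rows = [], []
    groups = list(dict.fromkeys(per["group"]))
    for layer, col in layers.items():
        for g in groups:
            vals = per.loc[per["group"] == g, col].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summary_rows.append({"group": g, "layer": layer, "n": vals.size,
                                 "median_um": med, "q1_um": q1, "q3_um": q3})
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                va = per.loc[per["group"] == a, col].to_numpy()
                vb = per.loc[per["group"] == b, col].to_numpy()
                u, p = mann_whitney(va, vb)
                pair_rows.append({"layer": layer, "group_a": a, "group_b": b,
                                  "U": u, "p_value": p,
                                  "stars": significance_stars(p)})
    return pd.DataFrame(summary_rows), pd.DataFrame(pair_rows)
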