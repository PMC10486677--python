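"""Signal conditioning: exclusion masks, smoothing, surface handling, averaging.

The conditioning chain for one B-scan is: drop excluded/flagged columns,
detect each surviving column's tissue surface on the raw signal, shift the
columns so their surfaces coincide, average laterally into one A-scan, then
smooth.  Surface alignment before averaging matters: averaging tilted
columns unaligned would smear the very landmarks the analysis relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .ascan import AScan

__all__ = [
    "ExclusionMask",
    "NoSurfaceError",
    "gaussian_kernel",
    "gaussian_smooth",
    "median_smooth",
    "detect_surface",
    "remove_air",
    "auto_flag_columns",
    "average_bscan",
]


class NoSurfaceError(ValueError):
    """Raised when a profile has no detectable air/tissue transition."""


# ---------------------------------------------------------------------------
# exclusion masks

@dataclass(frozen=True)
class ExclusionMask:
    """Column intervals flagged invalid, per B-scan.

    ``intervals`` maps a B-scan index to half-open ``[start, stop)`` column
    ranges.  Overlapping or touching ranges are merged on construction.
    """

    intervals: dict[int, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[int, tuple[tuple[int, int], ...]] = {}
        for b, ranges in self.intervals.items():
            cleaned = []
            for lo, hi in ranges:
                lo, hi = int(lo), int(hi)
                if lo < 0 or hi < lo:
                    raise ValueError(f"bad interval ({lo}, {hi}) for b-scan {b}")
                if hi > lo:
                    cleaned.append((lo, hi))
            cleaned.sort()
            merged: list[list[int]] = []
            for lo, hi in cleaned:
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            norm[int(b)] = tuple((lo, hi) for lo, hi in merged)
        object.__setattr__(self, "intervals", norm)

    def excluded_columns(self, bscan_index: int, n_ascans: int) -> np.ndarray:
        """Boolean mask of length ``n_ascans``; True where excluded."""
        out = np.zeros(n_ascans, dtype=bool)
        for lo, hi in self.intervals.get(int(bscan_index), ()):
            if hi > n_ascans:
                raise ValueError(
                    f"interval ({lo}, {hi}) exceeds image width {n_ascans}")
            out[lo:hi] = True
        return out

    # JSON is the on-disk format: {"0": [[10, 40], [200, 230]], ...}
    def to_json(self, path: str | Path) -> None:
        payload = {str(b): [list(r) for r in ranges]
                   for b, ranges in self.intervals.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ExclusionMask":
        payload = json.loads(Path(path).read_text())
        return cls({int(b): tuple(tuple(r) for r in ranges)
                    for b, ranges in payload.items()})


# ---------------------------------------------------------------------------
# smoothing

def gaussian_kernel(window: int = 9, sigma: float = 1.5) -> np.ndarray:
    """Discrete Gaussian taps of odd length ``window``, normalized to sum 1."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.arange(window) - window // 2
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth_array(values: np.ndarray, window: int, sigma: float) -> np.ndarray:
    if window > values.size:
        raise ValueError(f"window {window} longer than profile ({values.size})")
    k = gaussian_kernel(window, sigma)
    half = window // 2
    padded = np.pad(values, half, mode="reflect")
    return np.convolve(padded, k, mode="valid")


def gaussian_smooth(profile: AScan, window: int = 9, sigma: float = 1.5) -> AScan:
    """Gaussian noise filter (default: 9 taps, sigma 1.5), reflect-padded
    so the output has the input's length and total intensity is preserved
    up to border effects."""
    return profile.with_intensities(_smooth_array(profile.intensities, window, sigma))


def median_smooth(profile: AScan, window: int = 3) -> AScan:
    """Running median (default window 3) with edge replication.

    Monotone profiles are interior fixed points; isolated single-sample
    spikes are removed entirely.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window > len(profile):
        raise ValueError("window longer than profile")
    out = median_filter(profile.intensities, size=window, mode="nearest")
    return profile.with_intensities(out)


# ---------------------------------------------------------------------------
# surface handling

def detect_surface(
    profile: AScan,
    n_floor: int = 10,
    n_sigma: float = 5.0,
    min_rise_frac: float = 0.01,
    run_length: int = 3,
) -> int:
    """Index of the air/tissue transition (start of the stratum corneum).

    The air floor is estimated from the first ``n_floor`` samples — using
    their lower half, so the estimate survives the surface ramp intruding
    into the leading window when the air gap is short.  The surface is the
    first index whose intensity exceeds ``floor_mean + n_sigma * floor_sd``
    and stays above it for ``run_length`` consecutive samples (guard
    against isolated speckle spikes).  ``min_rise_frac`` of the
    floor-to-peak range is added to the threshold so the rule is defined
    for noiseless input, where the floor SD is exactly zero.
    Surface-origin profiles return 0 unconditionally.
    """
    if profile.origin == "surface":
        return 0
    y = profile.intensities
    if y.size <= n_floor + run_length:
        raise NoSurfaceError("profile too short for surface detection")
    floor = np.sort(y[:n_floor])[:max(n_floor // 2, 2)]
    threshold = floor.mean() + n_sigma * floor.std() \
        + min_rise_frac * max(y.max() - floor.mean(), 0.0)
    above = y > threshold
    if run_length > 1:
        run = np.convolve(above.astype(int), np.ones(run_length, dtype=int), "valid")
        hits = np.nonzero(run == run_length)[0]
    else:
        hits = np.nonzero(above)[0]
    if hits.size == 0:
        raise NoSurfaceError("no tissue surface: intensity never clears the air floor")
    return int(hits[0])


def remove_air(profile: AScan, **detect_kwargs) -> AScan:
    """Shift the profile so the detected surface becomes index 0.

    Idempotent: surface-origin input is returned unchanged.
    """
    if profile.origin == "surface":
        return profile
    idx = detect_surface(profile, **detect_kwargs)
    return profile.with_intensities(profile.intensities[idx:], origin="surface")


# ---------------------------------------------------------------------------
# B-scan -> A-scan

def write_ascan_csv(path: str | Path, profile: AScan) -> None:
    """Two-column CSV (depth_um, intensity) for an averaged A-scan."""
    depth = profile.depth_um
    with open(path, "w") as fh:
        fh.write("depth_um,intensity\n")
        for d, v in zip(depth, profile.intensities):
            fh.write(f"{d:.6g},{v:.10g}\n")


def read_ascan_csv(path: str | Path, origin: str = "surface") -> AScan:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("expected a two-column (depth_um, intensity) CSV")
    pitch = float(data[1, 0] - data[0, 0])
    return AScan(data[:, 1], axial_pitch_um=pitch, origin=origin)  # type: ignore[arg-type]


def auto_flag_columns(
    bscan: np.ndarray,
    axial_pitch_um: float,
    max_surface_dev: int = 20,
    min_subsurface_frac: float = 0.5,
    **detect_kwargs,
) -> np.ndarray:
    """Automatic proxy for manual outlier-region exclusion.

    A column is flagged when (a) its surface cannot be detected, (b) its
    surface index deviates from the B-scan's median surface by more than
    ``max_surface_dev`` samples (steep slope), or (c) its mean sub-surface
    intensity falls below ``min_subsurface_frac`` of the median over
    columns (hair shadow).  Returns a boolean mask, True = excluded.
    """
    bscan = np.asarray(bscan, dtype=float)
    n_cols = bscan.shape[0]
    surfaces = np.full(n_cols, -1)
    sub_means = np.full(n_cols, np.nan)
    for j in range(n_cols):
        col = AScan(np.clip(bscan[j], 0, None), axial_pitch_um)
        try:
            s = detect_surface(col, **detect_kwargs)
        except NoSurfaceError:
            continue
        surfaces[j] = s
        sub_means[j] = bscan[j, s:].mean()
    flagged = surfaces < 0
    ok = ~flagged
    if ok.any():
        med_surface = np.median(surfaces[ok])
        med_sub = np.median(sub_means[ok])
        flagged |= np.abs(surfaces - med_surface) > max_surface_dev
        flagged |= sub_means < min_subsurface_frac * med_sub
    return flagged


def average_bscan(
    bscan: np.ndarray,
    mask: ExclusionMask | None = None,
    bscan_index: int = 0,
    axial_pitch_um: float = 2.31,
    auto_flag: bool = False,
    **detect_kwargs,
) -> AScan:
    """Per-depth mean over non-excluded, surface-aligned columns.

    ``bscan`` has shape ``(n_ascans, n_samples)``.  Each surviving column's
    surface is detected on the raw signal, columns are shifted to a common
    surface origin, truncated to the shortest aligned length, and averaged.
    The result has ``origin="surface"``.
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2:
        raise ValueError("bscan must be 2-D (n_ascans, n_samples)")
    n_cols = bscan.shape[0]
    excluded = np.zeros(n_cols, dtype=bool)
    if mask is not None:
        excluded |= mask.excluded_columns(bscan_index, n_cols)
    if auto_flag:
        excluded |= auto_flag_columns(bscan, axial_pitch_um, **detect_kwargs)

    aligned: list[np.ndarray] = []
    for j in np.nonzero(~excluded)[0]:
        col = AScan(np.clip(bscan[j], 0, None), axial_pitch_um)
        try:
            s = detect_surface(col, **detect_kwargs)
        except NoSurfaceError:
            continue
        aligned.append(col.intensities[s:])
    if not aligned:
        raise ValueError("all columns excluded or without a detectable surface")
    length = min(a.size for a in aligned)
    stack = np.stack([a[:length] for a in aligned])
    return AScan(stack.mean(axis=0), axial_pitch_um=axial_pitch_um, origin="surface")
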