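"""Depth-resolved intensity profiles (A-scans) and their axial grid.

An A-scan is a single backscattered-intensity profile over depth at one
lateral position.  ``origin`` records whether index 0 is the start of the
raw scan (``"probe"``, i.e. the profile still contains the air gap above
the skin) or the detected tissue surface (``"surface"``).  Intensities are
arbitrary units: every statistic downstream is invariant to a global
intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Origin = Literal["probe", "surface"]


@dataclass(frozen=True)
class AScan:
    """One depth-resolved intensity profile.

    Parameters
    ----------
    intensities
        Non-negative, finite backscattered intensities, one per depth sample.
    axial_pitch_um
        Physical depth per sample in micrometres (> 0).
    origin
        ``"probe"`` if index 0 is the start of the raw scan, ``"surface"``
        if the air gap has been removed and index 0 is the skin surface.
    """

    intensities: np.ndarray
    axial_pitch_um: float
    origin: Origin = "probe"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if not (np.isfinite(self.axial_pitch_um) and self.axial_pitch_um > 0):
            raise ValueError("axial_pitch_um must be a positive finite number")
        if self.origin not in ("probe", "surface"):
            raise ValueError(f"unknown origin {self.origin!r}")
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return int(self.intensities.size)

    @property
    def depth_um(self) -> np.ndarray:
        """Depth of each sample in micrometres from index 0."""
        return np.arange(len(self)) * self.axial_pitch_um

    def with_intensities(self, values: np.ndarray, origin: Origin | None = None) -> "AScan":
        """Return a copy carrying ``values`` (same grid unless ``origin`` given)."""
        return replace(self, intensities=np.asarray(values, dtype=float),
                       origin=self.origin if origin is None else origin)
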