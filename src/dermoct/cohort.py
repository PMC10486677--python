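"""Subject-tagged collections of averaged A-scans.

A :class:`LabeledProfileSet` is the in-memory exchange object between the
simulation, layer, attenuation, similarity and classification stages: a flat
list of averaged surface-origin profiles, each carrying the subject it came
from and the subject's group label.  Subject identity matters because
train/test splits and group statistics must never mix scans of one animal
across sides of a comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from .ascan import AScan


@dataclass(frozen=True)
class LabeledProfile:
    subject_id: str
    group: str
    scan: AScan


@dataclass(frozen=True)
class LabeledProfileSet:
    profiles: tuple[LabeledProfile, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        for p in self.profiles:
            if not p.subject_id:
                raise ValueError("every profile needs a non-empty subject_id")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[LabeledProfile]:
        return iter(self.profiles)

    def groups(self) -> tuple[str, ...]:
        """Distinct group labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.group, None)
        return tuple(seen)

    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.subject_id, None)
        return tuple(seen)

    def subject_group(self) -> dict[str, str]:
        """Map subject id -> group label (must be consistent)."""
        out: dict[str, str] = {}
        for p in self.profiles:
            if out.setdefault(p.subject_id, p.group) != p.group:
                raise ValueError(f"subject {p.subject_id!r} appears in two groups")
        return out

    def select(self, *, group: str | None = None,
               subjects: Sequence[str] | None = None) -> "LabeledProfileSet":
        keep = [p for p in self.profiles
                if (group is None or p.group == group)
                and (subjects is None or p.subject_id in set(subjects))]
        return LabeledProfileSet(tuple(keep))
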