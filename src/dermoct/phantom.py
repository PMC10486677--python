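"""Layered-skin OCT phantom: synthetic A-scans, B-scans and labeled cohorts.

The forward model is the minimal piecewise profile that reproduces what an
averaged skin A-scan at ~930 nm actually shows, top to bottom:

* an air gap at the noise floor,
* a bright stratum-corneum band (linear ramp up to the first peak, then
  down to the valley at the stratum-corneum / viable-epidermis boundary),
* a darker viable epidermis (linear ramp back up),
* the dermis entry peak followed by exponential extinction
  ``i0 * exp(-mu * z)`` with ``z`` measured from dermis onset,
* an additive baseline (detector noise floor) on every sample.

Only the positions and relative intensities of the three landmarks (first
peak, valley, second peak) and the dermal decay rate carry information for
the downstream analysis; the straight-line segments between landmarks are a
deliberate non-commitment.  Speckle is modelled as i.i.d. multiplicative
gamma factors with mean 1 and shape ``1/CV^2`` — the intensity character of
fully developed speckle without a coherent wave model.

Default geometry mirrors the spectral-domain device the pipeline targets:
2.9 mm maximum depth over 1253 samples, i.e. 2.31 um axial pitch in air;
divide reported depths by the tissue refractive index (1.4) for physical
depth in tissue.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ascan import AScan
from .cohort import LabeledProfile, LabeledProfileSet

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "noiseless_template",
    "simulate_ascan",
    "simulate_bscan",
    "simulate_averaged_ascan",
    "simulate_cohort",
    "write_bscan_tiff",
    "read_bscan_tiff",
    "healthy_spec",
    "lymphedema_spec",
    "two_group_cohort_spec",
]

#: gamma shape for CV=0.2 speckle would be 25; kept symbolic via 1/cv^2.
_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one layered-skin A-scan.

    Depths are physical micrometres on the sampling grid; intensities are
    arbitrary units.  Landmark intensities are ``*_rel * i0`` so that with
    ``dermis_peak_rel = 1`` the dermis entry peak equals ``i0``.
    """

    air_gap_um: float = 60.0
    sc_thickness_um: float = 20.0
    epi_thickness_um: float = 50.0
    dermis_mu_per_cm: float = 80.0
    i0: float = 1.0
    baseline: float = 0.03
    sc_peak_rel: float = 0.9
    valley_rel: float = 0.55
    dermis_peak_rel: float = 1.0
    speckle_cv: float = 0.2
    axial_pitch_um: float = 2.31
    n_samples: int = 1253
    #: fraction of the stratum corneum over which intensity rises to the
    #: first peak (shape-only parameter; landmark positions do not move).
    sc_rise_frac: float = 0.3
    #: air-region intensity above the baseline, relative to i0.
    air_floor_rel: float = 0.005

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pos = {
            "sc_thickness_um": self.sc_thickness_um,
            "epi_thickness_um": self.epi_thickness_um,
            "dermis_mu_per_cm": self.dermis_mu_per_cm,
            "i0": self.i0,
            "axial_pitch_um": self.axial_pitch_um,
        }
        for name, v in pos.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        nonneg = {
            "air_gap_um": self.air_gap_um,
            "baseline": self.baseline,
            "speckle_cv": self.speckle_cv,
            "air_floor_rel": self.air_floor_rel,
        }
        for name, v in nonneg.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be >= 0 and finite, got {v}")
        for name in ("sc_peak_rel", "valley_rel", "dermis_peak_rel"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.valley_rel >= min(self.sc_peak_rel, self.dermis_peak_rel):
            raise ValueError("valley_rel must be below both peak intensities")
        if not 0 < self.sc_rise_frac < 1:
            raise ValueError("sc_rise_frac must lie in (0, 1)")
        if int(self.n_samples) < 4:
            raise ValueError("n_samples must be at least 4")
        depth_span = self.n_samples * self.axial_pitch_um
        if self.air_gap_um + self.sc_thickness_um + self.epi_thickness_um >= depth_span:
            raise ValueError("profile too short to contain the dermis onset")

    def replace(self, **changes) -> "PhantomSpec":
        return replace(self, **changes)


def noiseless_template(spec: PhantomSpec) -> np.ndarray:
    """Evaluate the noise-free piecewise profile on the spec's grid."""
    z = np.arange(int(spec.n_samples), dtype=float) * float(spec.axial_pitch_um)
    surface = spec.air_gap_um
    sc_peak_z = surface + spec.sc_rise_frac * spec.sc_thickness_um
    valley_z = surface + spec.sc_thickness_um
    dermis_z = valley_z + spec.epi_thickness_um

    air = spec.air_floor_rel * spec.i0
    sc_peak = spec.sc_peak_rel * spec.i0
    valley = spec.valley_rel * spec.i0
    dermis_peak = spec.dermis_peak_rel * spec.i0
    mu_per_um = spec.dermis_mu_per_cm * 1e-4

    t = np.piecewise(
        z,
        [
            z < surface,
            (z >= surface) & (z < sc_peak_z),
            (z >= sc_peak_z) & (z < valley_z),
            (z >= valley_z) & (z < dermis_z),
            z >= dermis_z,
        ],
        [
            lambda d: np.full_like(d, air),
            lambda d: air + (sc_peak - air) * (d - surface) / (sc_peak_z - surface),
            lambda d: sc_peak + (valley - sc_peak) * (d - sc_peak_z) / (valley_z - sc_peak_z),
            lambda d: valley + (dermis_peak - valley) * (d - valley_z) / (dermis_z - valley_z),
            lambda d: dermis_peak * np.exp(-mu_per_um * (d - dermis_z)),
        ],
    )
    return t + spec.baseline


def _speckle(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Multiplicative gamma speckle factors, mean 1, coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    k = 1.0 / cv**2
    return rng.gamma(shape=k, scale=1.0 / k, size=shape)


def simulate_ascan(spec: PhantomSpec, seed: int | np.random.Generator) -> AScan:
    """One speckled A-scan drawn from the phantom forward model.

    Identical ``(spec, seed)`` give identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = noiseless_template(spec)
    values = template * _speckle(rng, spec.speckle_cv, template.shape)
    return AScan(values, axial_pitch_um=spec.axial_pitch_um, origin="probe")


def simulate_bscan(
    spec: PhantomSpec,
    n_ascans: int,
    tilt_um_per_ascan: float = 0.0,
    hair_columns: Iterable[int] = (),
    seed: int | np.random.Generator = 0,
    hair_shadow: float = 0.3,
) -> np.ndarray:
    """Array of ``n_ascans`` adjacent A-scans, shape ``(n_ascans, n_samples)``.

    Column ``j`` has its air gap shifted by ``j * tilt_um_per_ascan``
    (lateral surface tilt).  Columns in ``hair_columns`` are multiplied by
    ``hair_shadow`` below their surface, mimicking the shadow a hair casts.
    """
    if n_ascans <= 0:
        raise ValueError("n_ascans must be positive")
    hair = set(int(c) for c in hair_columns)
    bad = [c for c in hair if not 0 <= c < n_ascans]
    if bad:
        raise ValueError(f"hair_columns outside [0, {n_ascans}): {sorted(bad)}")
    if not 0 <= hair_shadow <= 1:
        raise ValueError("hair_shadow must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    image = np.empty((n_ascans, int(spec.n_samples)))
    for j in range(n_ascans):
        gap = spec.air_gap_um + j * tilt_um_per_ascan
        if gap < 0:
            raise ValueError("tilt drives the air gap negative")
        col_spec = spec.replace(air_gap_um=gap)
        col = noiseless_template(col_spec)
        if j in hair:
            below = np.arange(len(col)) * spec.axial_pitch_um >= gap
            col = np.where(below, col * hair_shadow, col)
        image[j] = col * _speckle(rng, spec.speckle_cv, col.shape)
    return image


def simulate_averaged_ascan(
    spec: PhantomSpec,
    n_columns: int = 100,
    seed: int | np.random.Generator = 0,
) -> AScan:
    """Averaged A-scan: the mean of ``n_columns`` speckled columns.

    This mirrors how measured profiles are produced (an A-scan for analysis
    is the lateral average of the usable columns of one B-scan), and is the
    noise level every recovery guarantee in this package is stated at.
    Surface alignment is trivial here because all columns share one air gap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = noiseless_template(spec)
    factors = _speckle(rng, spec.speckle_cv, (int(n_columns), template.size))
    return AScan(template * factors.mean(axis=0),
                 axial_pitch_um=spec.axial_pitch_um, origin="probe")


# ---------------------------------------------------------------------------
# cohorts

#: PhantomSpec fields that may vary between subjects.
_VARIABLE_FIELDS = (
    "air_gap_um", "sc_thickness_um", "epi_thickness_um", "dermis_mu_per_cm",
    "i0", "baseline", "sc_peak_rel", "valley_rel", "dermis_peak_rel",
)


@dataclass(frozen=True)
class GroupSpec:
    """Population model of one group: mean phantom plus between-subject SDs."""

    mean: PhantomSpec
    between_subject_sd: Mapping[str, float] = field(default_factory=dict)
    n_subjects: int = 8
    scans_per_subject: int = 5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.scans_per_subject < 1:
            raise ValueError("scans_per_subject must be >= 1")
        unknown = set(self.between_subject_sd) - set(_VARIABLE_FIELDS)
        if unknown:
            raise ValueError(f"unknown variable fields: {sorted(unknown)}")
        for k, v in self.between_subject_sd.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"SD for {k} must be >= 0, got {v}")


@dataclass(frozen=True)
class CohortSpec:
    """Per-group population models keyed by group label."""

    groups: Mapping[str, GroupSpec]
    #: columns laterally averaged into each stored profile.
    columns_per_scan: int = 100

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        object.__setattr__(self, "groups", dict(self.groups))
        if self.columns_per_scan < 1:
            raise ValueError("columns_per_scan must be >= 1")

    # -- config-file round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "columns_per_scan": self.columns_per_scan,
            "groups": {
                label: {
                    "mean": asdict(g.mean),
                    "between_subject_sd": dict(g.between_subject_sd),
                    "n_subjects": g.n_subjects,
                    "scans_per_subject": g.scans_per_subject,
                }
                for label, g in self.groups.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        groups = {
            label: GroupSpec(
                mean=PhantomSpec(**g["mean"]),
                between_subject_sd=dict(g.get("between_subject_sd", {})),
                n_subjects=int(g.get("n_subjects", 8)),
                scans_per_subject=int(g.get("scans_per_subject", 5)),
            )
            for label, g in d["groups"].items()
        }
        return cls(groups=groups, columns_per_scan=int(d.get("columns_per_scan", 100)))


def _draw_subject_spec(mean: PhantomSpec, sd: Mapping[str, float],
                       rng: np.random.Generator) -> PhantomSpec:
    """Gaussian perturbation of the variable fields; resample (never truncate)
    any draw that violates the PhantomSpec constraints, so the accepted
    distribution stays unbiased away from the bounds."""
    for _ in range(_MAX_RESAMPLE):
        changes = {
            k: float(getattr(mean, k) + s * rng.standard_normal())
            for k, s in sd.items()
        }
        try:
            return mean.replace(**changes)
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid subject spec; SDs too large "
                       "relative to the mean parameters")


def _subject_layout(cohort: CohortSpec):
    """Deterministic (global_index, group_label, subject_id, GroupSpec) tuples."""
    k = 0
    for label in cohort.groups:
        g = cohort.groups[label]
        for s in range(g.n_subjects):
            yield k, label, f"{label}-{s:03d}", g
            k += 1


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # one independent stream per subject so metadata and data generation
    # can replay parameter draws without replaying every speckle draw
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(index,)))


def simulate_cohort(cohort: CohortSpec, seed: int) -> LabeledProfileSet:
    """Draw a labeled multi-subject cohort of averaged A-scans.

    Per-subject generative parameters are drawn once per subject; each
    subject then contributes ``scans_per_subject`` independently speckled,
    laterally averaged, surface-origin profiles.  Byte-identical output for
    identical (cohort, seed).
    """
    from .preprocess import remove_air  # local import: avoids a module cycle
    profiles: list[LabeledProfile] = []
    for k, label, sid, g in _subject_layout(cohort):
        rng = _subject_rng(seed, k)
        subject_spec = _draw_subject_spec(g.mean, g.between_subject_sd, rng)
        for _ in range(g.scans_per_subject):
            raw = simulate_averaged_ascan(subject_spec, cohort.columns_per_scan, rng)
            profiles.append(LabeledProfile(sid, label, remove_air(raw)))
    return LabeledProfileSet(tuple(profiles))


def simulate_cohort_volumes(cohort: CohortSpec, seed: int):
    """Yield ``(subject_id, group, volume)`` raw B-scan stacks per subject.

    ``volume`` has shape ``(scans_per_subject, columns_per_scan, n_samples)``
    — axis order (b-scan, lateral, depth).  Shares subject parameter
    streams with :func:`simulate_cohort`: averaging each B-scan of a
    volume reproduces that cohort's profiles up to surface alignment.
    """
    for k, label, sid, g in _subject_layout(cohort):
        rng = _subject_rng(seed, k)
        subject_spec = _draw_subject_spec(g.mean, g.between_subject_sd, rng)
        template = noiseless_template(subject_spec)
        vol = template[None, None, :] * _speckle(
            rng, subject_spec.speckle_cv,
            (g.scans_per_subject, cohort.columns_per_scan, template.size))
        yield sid, label, vol


def cohort_metadata(cohort: CohortSpec, seed: int) -> "list[dict]":
    """Per-subject generative parameters, as rows for a metadata CSV.

    Subject parameter streams are shared with :func:`simulate_cohort`, so
    the rows describe exactly the subjects that call generates."""
    rows = []
    for k, label, sid, g in _subject_layout(cohort):
        rng = _subject_rng(seed, k)
        subject_spec = _draw_subject_spec(g.mean, g.between_subject_sd, rng)
        row = {"subject_id": sid, "group": label,
               "scans_per_subject": g.scans_per_subject}
        row.update(asdict(subject_spec))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# reference group factories
#
# Group-level defaults follow the contrasts reported for lymphedematous
# rat skin at 930 nm: dermal extinction near 79 cm^-1 (80-180 um window) in
# healthy skin dropping to ~57 and ~52 cm^-1 at successive disease stages,
# together with stratum-corneum thickening and viable-epidermis thinning.

def healthy_spec(**overrides) -> PhantomSpec:
    base = dict(sc_thickness_um=20.0, epi_thickness_um=50.0, dermis_mu_per_cm=78.912)
    base.update(overrides)
    return PhantomSpec(**base)


def lymphedema_spec(stage: int = 2, **overrides) -> PhantomSpec:
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    base = dict(
        sc_thickness_um=26.0 if stage == 1 else 30.0,
        epi_thickness_um=42.0 if stage == 1 else 36.0,
        dermis_mu_per_cm=57.282 if stage == 1 else 52.221,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def two_group_cohort_spec(
    n_subjects: int = 15,
    scans_per_subject: int = 10,
    stage: int = 2,
    columns_per_scan: int = 100,
    n_samples: int = 1253,
) -> CohortSpec:
    """Healthy vs lymphedema cohort with typical between-subject spread."""
    sd = {"dermis_mu_per_cm": 8.0, "sc_thickness_um": 2.5,
          "epi_thickness_um": 4.0, "air_gap_um": 10.0}
    mk = lambda mean: GroupSpec(mean=mean, between_subject_sd=sd,
                                n_subjects=n_subjects,
                                scans_per_subject=scans_per_subject)
    return CohortSpec(
        groups={
            "healthy": mk(healthy_spec(n_samples=n_samples)),
            "lymphedema": mk(lymphedema_spec(stage=stage, n_samples=n_samples)),
        },
        columns_per_scan=columns_per_scan,
    )


# ---------------------------------------------------------------------------
# external formats

def write_bscan_tiff(path: str | Path, volume: np.ndarray) -> None:
    """Write a ``(n_bscans, n_ascans, n_samples)`` volume as a multi-page
    16-bit grayscale TIFF.  Intensities are scaled jointly so the volume
    maximum maps to 65535; downstream statistics are scale-invariant."""
    import tifffile

    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be (n_bscans, n_ascans, n_samples)")
    peak = vol.max()
    if peak <= 0:
        raise ValueError("volume has no positive intensities")
    scaled = np.round(vol / peak * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), scaled, photometric="minisblack")


def read_bscan_tiff(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF back as a float ``(n_bscans, n_ascans, n_samples)``
    volume (single-page files gain a leading axis of length 1)."""
    import tifffile

    vol = np.asarray(tifffile.imread(str(path)), dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {vol.shape}")
    return vol


def write_metadata_csv(path: str | Path, rows: Sequence[Mapping]) -> None:
    if not rows:
        raise ValueError("no metadata rows")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
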