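"""Pipeline configuration: one YAML-serializable object for every stage.

Defaults and their rationale:

* ``gaussian_window=9, gaussian_sigma=1.5`` — the noise filter applied to
  averaged A-scans before landmark detection and fitting.
* ``median_window=3`` — the filter of the classification branch.
* ``prominence_frac=0.02`` — extrema below 2% of the profile maximum are
  speckle, not anatomy.
* ``fit_windows_um=((80,180),(180,400))`` — papillary / reticular dermis
  windows; a single (120, 400) window is the documented alternative.
* ``refractive_index=1.4`` — optical-to-physical depth conversion for
  thickness reports (the device states depth in air).
* ``cpf_normalize=True`` — CPF compares shapes, not brightness.
* ``svm_c=1.0, svm_gamma='scale'`` — standard untuned SVM defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .phantom import CohortSpec, two_group_cohort_spec

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # filtering
    gaussian_window: int = 9
    gaussian_sigma: float = 1.5
    median_window: int = 3
    # landmarks / thickness
    prominence_frac: float = 0.02
    refractive_index: float = 1.4
    # extinction fitting
    fit_windows_um: tuple[tuple[float, float], ...] = ((80.0, 180.0), (180.0, 400.0))
    # CPF
    cpf_normalize: bool = True
    cpf_reference_group: str = "healthy"
    # classification
    feature_bins: int = 200
    feature_depth_um: float = 400.0
    train_fraction: float = 0.8
    n_repeats: int = 3
    svm_c: float = 1.0
    svm_gamma: float | str = "scale"
    # randomness
    seed: int = 0
    # synthetic cohort (used by the `simulate` command)
    cohort: CohortSpec = field(default_factory=two_group_cohort_spec)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_windows_um"] = [list(w) for w in self.fit_windows_um]
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "fit_windows_um" in d:
            d["fit_windows_um"] = tuple(tuple(float(v) for v in w)
                                        for w in d["fit_windows_um"])
        if "cohort" in d:
            d["cohort"] = CohortSpec.from_dict(d["cohort"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
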