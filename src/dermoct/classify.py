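"""Subject-wise SVM classification of intensity depth profiles.

The classifier sees what a clinician-facing tool would see: the averaged,
air-removed, median-filtered intensity profile over the first ~400 um of
skin, resampled to a fixed number of depth bins.  Splits are made at the
subject (animal) level — scans of one subject never appear on both sides
of a split — because scans of the same animal are strongly correlated and
pooling them across train and test would inflate accuracy.  The default
design is three repeats of a subject-wise 80/20 split, an RBF-kernel SVM,
and plain accuracy (correct predictions / total predictions) summarized as
mean +/- SD over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ascan import AScan
from .attenuation import normalize_to_max
from .cohort import LabeledProfileSet
from .preprocess import median_smooth, remove_air

__all__ = ["SplitPlan", "extract_features", "make_splits",
           "train_and_evaluate", "EvaluationResult"]


def extract_features(
    profile: AScan,
    n_bins: int = 200,
    depth_um: float = 400.0,
    median_window: int = 3,
    normalize: bool = True,
) -> np.ndarray:
    """Fixed-length feature vector from one profile.

    Air removal, window-3 median filtration, optional max-normalization,
    truncation to ``depth_um`` and linear resampling to ``n_bins`` bins.
    Profiles shorter than the truncation depth are padded with their own
    minimum (noise-floor proxy) and a warning is issued.  Per-feature
    standardization is *not* done here: it belongs to the training stage,
    which must derive its statistics from the training set only.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scan = remove_air(profile)
    scan = median_smooth(scan, median_window)
    if normalize:
        scan = normalize_to_max(scan)
    y = scan.intensities
    depth = scan.depth_um
    if depth[-1] < depth_um:
        warnings.warn(
            f"profile covers {depth[-1]:.0f} um < {depth_um:.0f} um; "
            "padding with the profile minimum", stacklevel=2)
        n_pad = int(np.ceil((depth_um - depth[-1]) / scan.axial_pitch_um))
        y = np.concatenate([y, np.full(n_pad, y.min())])
        depth = np.arange(y.size) * scan.axial_pitch_um
    grid = np.linspace(0.0, depth_um, n_bins)
    return np.interp(grid, depth, y)


@dataclass(frozen=True)
class SplitPlan:
    """Per-repeat subject partitions; train and test are disjoint and
    jointly cover all subjects within each repeat."""

    repeats: tuple[tuple[frozenset, frozenset], ...]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        for train, test in self.repeats:
            if train & test:
                raise ValueError("train and test subjects overlap")
            if not train or not test:
                raise ValueError("each repeat needs non-empty train and test sets")


def make_splits(
    profile_set: LabeledProfileSet,
    train_fraction: float = 0.8,
    n_repeats: int = 3,
    seed: int = 0,
    max_retries: int = 100,
) -> SplitPlan:
    """Subject-disjoint random splits, deterministic given ``seed``.

    Each repeat samples ``train_fraction`` of the subjects (without
    replacement) for training; a draw that leaves any class absent from
    either side is resampled (bounded retries, then an error).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    subj_group = profile_set.subject_group()
    subjects = np.array(sorted(subj_group))
    if subjects.size < 2:
        raise ValueError("need at least two subjects to split")
    n_train = int(round(train_fraction * subjects.size))
    n_train = min(max(n_train, 1), subjects.size - 1)
    classes = set(subj_group.values())
    rng = np.random.default_rng(seed)

    repeats = []
    for _ in range(n_repeats):
        for _ in range(max_retries):
            perm = rng.permutation(subjects)
            train, test = frozenset(perm[:n_train]), frozenset(perm[n_train:])
            if {subj_group[s] for s in train} == classes \
                    and {subj_group[s] for s in test} == classes:
                repeats.append((train, test))
                break
        else:
            raise ValueError(
                "could not draw a split with every class on both sides; "
                "too few subjects per class")
    return SplitPlan(tuple(repeats), train_fraction, seed)


@dataclass(frozen=True)
class EvaluationResult:
    accuracies: tuple[float, ...]
    flagged_repeats: tuple[int, ...]
    n_test: tuple[int, ...]

    def _valid(self) -> tuple[float, ...]:
        # single-class test repeats are flagged and left out of the summary
        kept = tuple(a for r, a in enumerate(self.accuracies)
                     if r not in self.flagged_repeats)
        return kept or self.accuracies

    @property
    def mean(self) -> float:
        return float(np.mean(self._valid()))

    @property
    def sd(self) -> float:
        v = self._valid()
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"repeat": range(len(self.accuracies)),
                             "accuracy": self.accuracies, "n_test": self.n_test})


def _default_svm() -> Pipeline:
    # gamma="scale" is 1 / (n_features * feature variance); C=1.  The
    # standardizer is inside the pipeline so its statistics are fitted on
    # the training profiles only.
    return Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(kernel="rbf", C=1.0, gamma="scale"))])


def train_and_evaluate(
    profile_set: LabeledProfileSet,
    plan: SplitPlan,
    svm_params: dict | None = None,
    n_bins: int = 200,
    depth_um: float = 400.0,
    normalize: bool = True,
) -> EvaluationResult:
    """Fit one SVM per repeat on training subjects; accuracy on test subjects.

    Accuracy is the fraction of correct predictions on the held-out
    profiles.  A repeat whose test side degenerates to a single class is
    evaluated but flagged.  Deterministic given (data, plan).
    """
    feats = {}
    labels = {}
    by_subject: dict[str, list[int]] = {}
    for i, p in enumerate(profile_set):
        feats[i] = extract_features(p.scan, n_bins, depth_um, normalize=normalize)
        labels[i] = p.group
        by_subject.setdefault(p.subject_id, []).append(i)

    accuracies, flagged, n_tests = [], [], []
    for r, (train_s, test_s) in enumerate(plan.repeats):
        tr = [i for s in sorted(train_s) for i in by_subject.get(s, [])]
        te = [i for s in sorted(test_s) for i in by_subject.get(s, [])]
        if not tr or not te:
            raise ValueError(f"repeat {r}: empty train or test profile list")
        x_tr = np.stack([feats[i] for i in tr])
        y_tr = np.array([labels[i] for i in tr])
        x_te = np.stack([feats[i] for i in te])
        y_te = np.array([labels[i] for i in te])
        if np.unique(y_tr).size < 2:
            raise ValueError(f"repeat {r}: training set holds a single class")
        model = _default_svm()
        if svm_params:
            model.set_params(**{f"svm__{k}": v for k, v in svm_params.items()})
        model.fit(x_tr, y_tr)
        acc = float(np.mean(model.predict(x_te) == y_te))
        accuracies.append(acc)
        n_tests.append(len(te))
        if np.unique(y_te).size < 2:
            flagged.append(r)
            warnings.warn(f"repeat {r}: test set holds a single class; "
                          "excluded from the accuracy summary", stacklevel=2)
    return EvaluationResult(tuple(accuracies), tuple(flagged), tuple(n_tests))
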