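"""Binary RBF-SVM artifact classifiers over fingerprint feature subsets.

Each artifact type (eyeblink, eye movement, myogenic) gets an independent
binary support-vector machine with a radial-basis-function kernel, trained
on expert (or ground-truth) labels over a chosen subset of the 14
fingerprint features.  The published optimal subsets are available as
presets.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_NAMES

__all__ = [
    "LabeledICSet",
    "FeatureSubset",
    "ClassifierModel",
    "train",
    "predict",
    "preset_classifiers",
]

ARTIFACT_TYPES = ("eyeblink", "eye-movement", "myogenic")


@dataclass(frozen=True)
class FeatureSubset:
    """Inclusion mask over the fixed 14-feature fingerprint order."""

    mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        mask = tuple(bool(b) for b in self.mask)
        object.__setattr__(self, "mask", mask)
        if len(mask) == 0 or not any(mask):
            raise ValueError("feature subset must include at least one feature")

    @classmethod
    def from_names(cls, names, n_features: int = len(FEATURE_NAMES)) -> "FeatureSubset":
        names = set(names)
        unknown = names - set(FEATURE_NAMES[:n_features])
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        return cls(tuple(f in names for f in FEATURE_NAMES[:n_features]))

    @classmethod
    def full(cls, n_features: int = len(FEATURE_NAMES)) -> "FeatureSubset":
        return cls((True,) * n_features)

    @classmethod
    def from_int(cls, bits: int, n_features: int) -> "FeatureSubset":
        return cls(tuple(bool(bits >> i & 1) for i in range(n_features)))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f for f, b in zip(FEATURE_NAMES, self.mask) if b)

    @property
    def size(self) -> int:
        return sum(self.mask)

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def as_int(self) -> int:
        return sum(1 << i for i, b in enumerate(self.mask) if b)


@dataclass
class LabeledICSet:
    """Fingerprints paired with binary artifact labels across datasets.

    ``fingerprints`` is a feature table (rows = ICs) containing at least the
    fingerprint columns and a ``dataset_id`` column; ``labels`` is 1 for
    artifact, 0 for non-artifact, one per row.
    """

    fingerprints: pd.DataFrame
    labels: np.ndarray
    artifact_type: str = "eyeblink"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.fingerprints) != self.labels.size:
            raise ValueError("one label per fingerprint row required")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def dataset_ids(self) -> np.ndarray:
        return self.fingerprints["dataset_id"].to_numpy()

    def feature_matrix(self, subset: FeatureSubset | None = None) -> np.ndarray:
        cols = list(subset.names) if subset is not None else list(FEATURE_NAMES)
        missing = [c for c in cols if c not in self.fingerprints.columns]
        if missing:
            raise KeyError(f"fingerprint table missing feature columns: {missing}")
        return self.fingerprints[cols].to_numpy(float)

    def restrict_to(self, dataset_ids) -> "LabeledICSet":
        keep = np.isin(self.dataset_ids, list(dataset_ids))
        return LabeledICSet(
            fingerprints=self.fingerprints.loc[keep].reset_index(drop=True),
            labels=self.labels[keep],
            artifact_type=self.artifact_type,
        )


@dataclass
class ClassifierModel:
    """A trained binary RBF-SVM bound to a specific feature subset."""

    subset: FeatureSubset
    svm: SVC
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"subset": self.subset.mask, "svm": self.svm, "metadata": self.metadata}, fh)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        return cls(subset=FeatureSubset(obj["subset"]), svm=obj["svm"], metadata=obj["metadata"])


def train(
    train_set: LabeledICSet,
    subset: FeatureSubset | None = None,
    C: float = 1.0,
    gamma: str | float = "scale",
    class_weight: str | dict | None = "balanced",
    seed: int = 0,
) -> ClassifierModel:
    """Fit an RBF-SVM on the masked feature columns of a labeled IC set.

    Artifact ICs are rare (often a few percent of a corpus), so
    inverse-frequency class weighting is on by default.  Features are used
    as-is: the fingerprint normalization already places them on comparable
    [0, 1]-ish scales.
    """
    subset = subset if subset is not None else FeatureSubset.full()
    x = train_set.feature_matrix(subset)
    y = train_set.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    svm = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight, random_state=seed)
    svm.fit(x, y)
    return ClassifierModel(
        subset=subset,
        svm=svm,
        metadata={"C": C, "gamma": gamma, "class_weight": class_weight, "seed": seed,
                  "artifact_type": train_set.artifact_type, "n_train": int(y.size)},
    )


def predict(model: ClassifierModel, fingerprints: pd.DataFrame) -> np.ndarray:
    """Binary labels (1 = artifact) for each fingerprint row.

    Exact ties at the decision boundary resolve to non-artifact, the
    conservative choice for data retention.
    """
    if len(fingerprints) == 0:
        return np.zeros(0, dtype=int)
    cols = list(model.subset.names)
    missing = [c for c in cols if c not in fingerprints.columns]
    if missing:
        raise KeyError(f"fingerprint table missing feature columns: {missing}")
    x = fingerprints[cols].to_numpy(float)
    d = model.svm.decision_function(x)
    # decision_function > 0 favors classes_[1]; ensure 1 == artifact
    positive = int(np.argmax(model.svm.classes_ == 1))
    if positive == 1:
        return (d > 0).astype(int)
    return (d < 0).astype(int)


def preset_classifiers() -> dict[str, FeatureSubset]:
    """The published optimal feature subsets per artifact type.

    eyeblink: 4 features; eye-movement: 10 features; myogenic: all 14.
    """
    return {
        "eyeblink": FeatureSubset.from_names(["K", "MEV", "SAD", "PSD_DELTA"]),
        "eye-movement": FeatureSubset.from_names(
            ["K", "MEV", "SED", "PSD_DELTA", "PSD_THETA", "PSD_BETA",
             "PSD_GAMMA", "CIF", "MIF", "EM_CORR"]
        ),
        "myogenic": FeatureSubset.full(),
    }
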