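"""Feature fusion, dataset splitting, classifiers, and multi-class metrics.

Handcrafted and deep descriptors are fused at the feature level (plain
concatenation) and fed to one of four classifiers — SVM, k-nearest
neighbors, random forest, or gradient boosting (XGBoost) — after a 70:30
stratified train/test split. Evaluation is via the K x K confusion matrix
and the derived one-vs-rest accuracy / precision / recall / F1, with macro
averaging across the five severity grades; both the harmonic mean of the
macro precision and recall (``macro_f1_hm``) and the unweighted mean of
per-class F1 (``macro_f1_avg``) are reported, since both conventions appear
in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import FeatureVector, GradingLabel, InvalidSpecError, GRADE_NAMES

__all__ = [
    "Dataset",
    "ConfusionMatrix",
    "MetricsReport",
    "ClassifierModel",
    "fuse",
    "split_dataset",
    "train_classifier",
    "evaluate",
    "metrics_from_confusion",
    "f1_from_pr",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("SVM", "KNN", "RF", "XGB")


@dataclass
class Dataset:
    """A feature matrix with aligned labels and image ids."""

    X: np.ndarray
    names: list[str]
    set_id: str
    ids: list[str]
    labels: list[int] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidSpecError("Dataset.X must be 2-D")
        if self.X.shape[1] != len(self.names):
            raise InvalidSpecError("feature count does not match names")
        if len(self.ids) != self.X.shape[0]:
            raise InvalidSpecError("ids length does not match rows")
        if self.labels is not None and len(self.labels) != self.X.shape[0]:
            raise InvalidSpecError("labels length does not match rows")

    def __len__(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector],
                     labels: list[GradingLabel | int] | None = None) -> "Dataset":
        if not vectors:
            raise InvalidSpecError("cannot build a Dataset from zero vectors")
        set_ids = {v.set_id for v in vectors}
        lengths = {len(v) for v in vectors}
        if len(set_ids) != 1 or len(lengths) != 1:
            raise InvalidSpecError("vectors must share set_id and length")
        lab = None
        if labels is not None:
            lab = [l.grade if isinstance(l, GradingLabel) else int(l) for l in labels]
        return cls(
            X=np.stack([v.values for v in vectors]),
            names=list(vectors[0].names),
            set_id=vectors[0].set_id,
            ids=[v.source_image_id for v in vectors],
            labels=lab,
        )

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            X=self.X[idx], names=self.names, set_id=self.set_id,
            ids=[self.ids[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )


@dataclass
class ConfusionMatrix:
    """K x K counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise InvalidSpecError("confusion matrix must be K x K")
        if (self.counts < 0).any():
            raise InvalidSpecError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for class index ``k`` by marginalization."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Accuracy plus per-class and macro precision / recall / F1."""

    accuracy: float
    per_class_precision: dict[str, float]
    per_class_recall: dict[str, float]
    per_class_f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1_hm: float
    macro_f1_avg: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                name: {
                    "precision": self.per_class_precision[name],
                    "recall": self.per_class_recall[name],
                    "f1": self.per_class_f1[name],
                }
                for name in self.per_class_precision
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1_hm": self.macro_f1_hm,
                "f1_avg": self.macro_f1_avg,
            },
        }


def fuse(handcrafted: FeatureVector, deep: FeatureVector) -> FeatureVector:
    """Feature-level fusion: handcrafted-then-deep concatenation.

    Names are prefixed by origin so the layout stays auditable; both inputs
    must describe the same source image.
    """
    if handcrafted.source_image_id != deep.source_image_id:
        raise InvalidSpecError(
            f"cannot fuse vectors from different images: "
            f"{handcrafted.source_image_id!r} vs {deep.source_image_id!r}"
        )
    values = np.concatenate([handcrafted.values, deep.values])
    names = ([f"hc_{n}" for n in handcrafted.names]
             + [f"deep_{n}" if not n.startswith("deep_") else n for n in deep.names])
    return FeatureVector(values=values, names=names, set_id="FUSED",
                         source_image_id=handcrafted.source_image_id)


def split_dataset(data: Dataset, train_fraction: float = 0.70, seed: int = 0,
                  stratified: bool = True) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive train/test partition (default 70:30).

    Under stratification each class is shuffled with the seeded generator
    and split with ``floor(train_fraction * n_class)`` samples in train, the
    remainder in test. A class with fewer than 2 members cannot be split and
    is kept whole in train (with a warning).
    """
    if not 0.0 < train_fraction < 1.0:
        raise InvalidSpecError("train_fraction must lie in (0, 1)")
    if data.labels is None and stratified:
        raise InvalidSpecError("stratified split requires labels")
    rng = np.random.default_rng(seed)
    n = len(data)
    if not stratified:
        perm = rng.permutation(n)
        n_train = int(np.floor(train_fraction * n))
        return data.subset(perm[:n_train]), data.subset(perm[n_train:])
    labels = np.asarray(data.labels)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        if idx.size < 2:
            warnings.warn(f"class {cls} has fewer than 2 members; kept whole in train",
                          stacklevel=2)
            train_idx.extend(idx)
            continue
        n_train = int(np.floor(train_fraction * idx.size))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return data.subset(np.asarray(train_idx)), data.subset(np.asarray(test_idx))


@dataclass
class ClassifierModel:
    """A fitted classifier behind a uniform predict contract."""

    kind: str
    estimator: object
    scaler: object | None
    n_features: int
    classes: list[int]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise InvalidSpecError(
                f"feature length mismatch: model expects {self.n_features}, "
                f"got {X.shape[1]}"
            )
        if self.scaler is not None:
            X = self.scaler.transform(X)
        pred = self.estimator.predict(X)
        return np.asarray([self.classes[p] for p in pred]) \
            if self.kind == "XGB" else np.asarray(pred)


_DEFAULT_HYPERPARAMS = {
    "SVM": {"C": 1.0, "gamma": "auto", "kernel": "rbf"},
    "KNN": {"n_neighbors": 5, "metric": "euclidean"},
    "RF": {"n_estimators": 300},
    "XGB": {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1,
            "reg_alpha": 0.0, "reg_lambda": 1.0},
}


def train_classifier(kind: str, train: Dataset,
                     hyperparams: dict | None = None,
                     seed: int = 0) -> ClassifierModel:
    """Fit one of the four supported classifiers on a labelled train set.

    Features are standardized to train-set mean/std for the scale-sensitive
    learners (SVM, KNN) only; tree ensembles see raw features. The seed is
    threaded to every stochastic learner.
    """
    kind = kind.upper()
    if kind not in CLASSIFIER_KINDS:
        raise InvalidSpecError(f"unknown classifier kind {kind!r}")
    if train.labels is None:
        raise InvalidSpecError("training requires labels")
    y = np.asarray(train.labels)
    classes = sorted(set(int(c) for c in y))
    if len(classes) < 2:
        raise InvalidSpecError("training requires at least 2 classes")
    hp = {**_DEFAULT_HYPERPARAMS[kind], **(hyperparams or {})}

    X = train.X
    scaler = None
    if kind in ("SVM", "KNN"):
        from sklearn.preprocessing import StandardScaler

        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    if kind == "SVM":
        from sklearn.svm import SVC

        est = SVC(random_state=seed, **hp).fit(X, y)
    elif kind == "KNN":
        from sklearn.neighbors import KNeighborsClassifier

        est = KNeighborsClassifier(**hp).fit(X, y)
    elif kind == "RF":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(random_state=seed, **hp).fit(X, y)
    else:  # XGB
        from xgboost import XGBClassifier

        # XGBoost expects contiguous 0-based class codes
        code = {c: i for i, c in enumerate(classes)}
        est = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **hp)
        est.fit(X, np.asarray([code[int(v)] for v in y]))

    return ClassifierModel(kind=kind, estimator=est, scaler=scaler,
                           n_features=train.X.shape[1], classes=classes)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 by convention at p = r = 0."""
    if p == 0.0 and r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy and one-vs-rest precision / recall / F1 with macro averages.

    Empty denominators (a class never predicted, or absent from the test
    set) contribute 0 to the corresponding metric.
    """
    if cm.total == 0:
        raise InvalidSpecError("cannot compute metrics of an all-zero matrix")
    k = len(cm.class_names)
    precision, recall, f1 = {}, {}, {}
    for i, name in enumerate(cm.class_names):
        tp, fp, fn, _ = cm.one_vs_rest(i)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision[name] = p
        recall[name] = r
        f1[name] = f1_from_pr(p, r)
    macro_p = float(np.mean(list(precision.values())))
    macro_r = float(np.mean(list(recall.values())))
    return MetricsReport(
        accuracy=float(np.trace(cm.counts)) / cm.total,
        per_class_precision=precision,
        per_class_recall=recall,
        per_class_f1=f1,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1_hm=f1_from_pr(macro_p, macro_r),
        macro_f1_avg=float(np.mean(list(f1.values()))),
    )


def evaluate(model: ClassifierModel, test: Dataset,
             class_names: list[str] | None = None
             ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix over the full 5-grade label space plus metrics."""
    if len(test) == 0:
        raise InvalidSpecError("test set is empty")
    if test.labels is None:
        raise InvalidSpecError("evaluation requires labels")
    names = class_names or list(GRADE_NAMES)
    k = len(names)
    pred = model.predict(test.X)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(test.labels, pred):
        counts[int(t), int(p)] += 1
    cm = ConfusionMatrix(counts=counts, class_names=names)
    return cm, metrics_from_confusion(cm)
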