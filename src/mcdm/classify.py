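"""HOG + LBP features, subject-level splitting, Random-Forest
classification by majority vote, and confusion-matrix evaluation.

The feature vector is the concatenation of a histogram-of-oriented-
gradients descriptor (8x8-pixel cells, 2x2-cell blocks, 9 unsigned
orientation bins, L2 block normalization with clipping at 0.2) and a
local-binary-pattern histogram (P=8 neighbors at radius R=1, sampled
counterclockwise from the rightmost neighbor with bilinear
interpolation off-grid).  Images are converted to grayscale with
standard luminance weights before either extractor.

Splitting is at the subject level: all images of a subject land on one
side, stratified by class, so augmented copies can never leak across
the train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import hog as _sk_hog
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .render import MCDMImage

__all__ = [
    "HOGConfig",
    "LBPConfig",
    "FeatureVector",
    "DatasetSplit",
    "ForestModel",
    "EvalReport",
    "DEFAULT_GRID",
    "hog_features",
    "lbp_code",
    "lbp_histogram",
    "extract_features",
    "subject_split",
    "train_rf",
    "predict",
    "predict_batch",
    "evaluate",
    "feature_importance",
]

POSITIVE_CLASS = "ischemic"

#: Grid-search space for the Random Forest.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 200, 500],
    "max_depth": [None, 10, 20],
}


@dataclass(frozen=True)
class HOGConfig:
    """HOG descriptor parameters (pixels per cell, cells per block, bins)."""

    cell: tuple[int, int] = (8, 8)
    block: tuple[int, int] = (2, 2)
    n_bins: int = 9

    def __post_init__(self) -> None:
        if min(self.cell) < 1 or min(self.block) < 1 or self.n_bins < 1:
            raise ValueError("HOG parameters must be positive")

    def descriptor_length(self, image_shape: tuple[int, int]) -> int:
        """Closed-form descriptor length for an H x W image."""
        cells = (image_shape[0] // self.cell[0], image_shape[1] // self.cell[1])
        blocks = (cells[0] - self.block[0] + 1, cells[1] - self.block[1] + 1)
        return blocks[0] * blocks[1] * self.block[0] * self.block[1] * self.n_bins


@dataclass(frozen=True)
class LBPConfig:
    """LBP neighborhood: P sampling points on a circle of radius R."""

    p: int = 8
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.p < 4:
            raise ValueError("P must be >= 4")
        if self.r < 1:
            raise ValueError("R must be >= 1")


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated HOG + LBP features with layout provenance."""

    values: np.ndarray
    hog_length: int
    lbp_length: int
    subject_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size != self.hog_length + self.lbp_length:
            raise ValueError("feature length must equal hog_length + lbp_length")
        if not np.all(np.isfinite(values)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DatasetSplit:
    """Subject-level stratified split; subject sets are disjoint by
    construction."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    test_fraction: float

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subject sets overlap")


@dataclass
class ForestModel:
    """A fitted Random Forest with its grid-search record."""

    estimator: RandomForestClassifier
    n_trees: int
    seed: int
    grid_record: dict
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class EvalReport:
    """Confusion-matrix counts and derived metrics (percentages)."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc: float
    roc_points: tuple[tuple[float, float], ...]
    zero_division_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1, "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "zero_division_flags": list(self.zero_division_flags),
        }


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _to_gray(image: MCDMImage) -> np.ndarray:
    return rgb2gray(image.pixels)  # luminance weights, float in [0, 1]


def hog_features(image: MCDMImage, config: HOGConfig | None = None) -> np.ndarray:
    """Histogram-of-oriented-gradients descriptor of the grayscale image."""
    config = config or HOGConfig()
    h, w = image.shape
    if config.cell[0] * config.block[0] > h or config.cell[1] * config.block[1] > w:
        raise ValueError("cell/block configuration larger than image")
    if h % config.cell[0] or w % config.cell[1]:
        raise ValueError("image dimensions must divide into whole cells")
    return _sk_hog(
        _to_gray(image),
        orientations=config.n_bins,
        pixels_per_cell=config.cell,
        cells_per_block=config.block,
        block_norm="L2-Hys",
        feature_vector=True,
    )


def lbp_code(center: float, samples: Sequence[float]) -> int:
    """LBP code of one pixel from its circular neighbor samples.

    ``code = sum_p s(g_p - g_c) 2^p`` with ``s(x) = 1`` iff ``x >= 0``;
    ``samples`` are in sampling order (counterclockwise from angle 0).
    """
    return int(sum((1 << p) for p, g in enumerate(samples) if g - center >= 0))


def _bilinear(gray: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    r0 = np.floor(rr).astype(int)
    c0 = np.floor(cc).astype(int)
    dr = rr - r0
    dc = cc - c0
    r1 = np.minimum(r0 + 1, gray.shape[0] - 1)
    c1 = np.minimum(c0 + 1, gray.shape[1] - 1)
    return (
        gray[r0, c0] * (1 - dr) * (1 - dc)
        + gray[r0, c1] * (1 - dr) * dc
        + gray[r1, c0] * dr * (1 - dc)
        + gray[r1, c1] * dr * dc
    )


def lbp_histogram(image: MCDMImage, config: LBPConfig | None = None) -> np.ndarray:
    """Normalized 2^P-bin histogram of LBP codes over interior pixels.

    Neighbors are sampled counterclockwise starting from the rightmost
    (angle 0) at radius R, with bilinear interpolation for off-grid
    positions; the histogram sums to 1.
    """
    config = config or LBPConfig()
    gray = _to_gray(image)
    h, w = gray.shape
    margin = int(np.ceil(config.r))
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the LBP radius")
    rows, cols = np.mgrid[margin:h - margin, margin:w - margin]
    center = gray[margin:h - margin, margin:w - margin]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p in range(config.p):
        theta = 2 * np.pi * p / config.p
        dc = config.r * np.cos(theta)
        dr = -config.r * np.sin(theta)  # counterclockwise in image coordinates
        if abs(round(dc) - dc) < 1e-9 and abs(round(dr) - dr) < 1e-9:
            sample = gray[rows + int(round(dr)), cols + int(round(dc))]
        else:
            sample = _bilinear(gray, rows + dr, cols + dc)
        # epsilon absorbs bilinear-weight rounding so s(0) = 1 holds exactly
        # on flat regions (weights sum to 1 only to machine precision)
        codes += ((sample - center) >= -1e-12).astype(np.int64) << p
    hist = np.bincount(codes.ravel(), minlength=2 ** config.p).astype(float)
    return hist / hist.sum()


def extract_features(
    image: MCDMImage,
    hog_config: HOGConfig | None = None,
    lbp_config: LBPConfig | None = None,
) -> FeatureVector:
    """Concatenate HOG and LBP features (HOG block first)."""
    hog_vec = hog_features(image, hog_config)
    lbp_vec = lbp_histogram(image, lbp_config)
    return FeatureVector(
        values=np.concatenate([hog_vec, lbp_vec]),
        hog_length=hog_vec.size,
        lbp_length=lbp_vec.size,
        subject_id=image.subject_id,
        class_label=image.class_label,
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def subject_split(
    manifest: Sequence[Mapping[str, object]],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified subject-level split of an image manifest.

    ``manifest`` records need ``subject_id`` and ``class_label`` keys.
    Subjects (not images) are sampled per class without replacement to
    fill the test fraction, so every image of a subject lands on one
    side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if not manifest:
        raise ValueError("empty manifest")
    by_class: dict[str, list[str]] = {}
    subject_class: dict[str, str] = {}
    for rec in manifest:
        sid, label = str(rec["subject_id"]), str(rec["class_label"])
        if sid not in subject_class:
            subject_class[sid] = label
            by_class.setdefault(label, []).append(sid)
        elif subject_class[sid] != label:
            raise ValueError(f"subject {sid!r} appears with conflicting labels")

    rng = np.random.default_rng(seed)
    test_subjects: set[str] = set()
    for label in sorted(by_class):
        subjects = sorted(by_class[label])
        if len(subjects) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 subjects")
        n_test = int(round(len(subjects) * test_fraction))
        if n_test < 1 or n_test >= len(subjects):
            raise ValueError(
                f"test_fraction={test_fraction} yields an empty side for class {label!r}"
            )
        test_subjects.update(rng.choice(subjects, size=n_test, replace=False))

    test_idx = np.array(
        [i for i, rec in enumerate(manifest) if str(rec["subject_id"]) in test_subjects],
        dtype=int,
    )
    train_idx = np.array(
        [i for i in range(len(manifest)) if i not in set(test_idx.tolist())], dtype=int
    )
    return DatasetSplit(
        train_indices=train_idx,
        test_indices=test_idx,
        train_subjects=frozenset(subject_class) - frozenset(test_subjects),
        test_subjects=frozenset(test_subjects),
        test_fraction=test_fraction,
    )


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def _feature_matrix(features: Sequence[FeatureVector | np.ndarray]) -> np.ndarray:
    rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=float)
            for f in features]
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError("inconsistent feature lengths")
    return np.vstack(rows)


def train_rf(
    features: Sequence[FeatureVector | np.ndarray],
    labels: Sequence[str],
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    cv: int = 5,
) -> ForestModel:
    """Fit a Random Forest, optionally tuned by grid search.

    With more than one grid combination, hyperparameters are selected by
    stratified ``cv``-fold cross-validation on the training data only and
    the best configuration is refit on the full training set.  Seeded
    and single-threaded for reproducibility.
    """
    x = _feature_matrix(features)
    y = np.asarray([str(l) for l in labels])
    if x.shape[0] != y.size:
        raise ValueError("features and labels must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")

    grid = {k: list(v) for k, v in (grid or DEFAULT_GRID).items()}
    n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
    base = RandomForestClassifier(random_state=seed, n_jobs=1)
    if n_combos > 1:
        min_class = np.min(np.unique(y, return_counts=True)[1])
        folds = StratifiedKFold(n_splits=min(cv, int(min_class)), shuffle=True,
                                random_state=seed)
        search = GridSearchCV(base, grid, cv=folds, n_jobs=1, refit=True)
        search.fit(x, y)
        estimator = search.best_estimator_
        record = {
            "grid": grid,
            "best_params": search.best_params_,
            "mean_test_scores": search.cv_results_["mean_test_score"].tolist(),
        }
    else:
        params = {k: v[0] for k, v in grid.items()}
        estimator = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        estimator.fit(x, y)
        record = {"grid": grid, "best_params": params, "mean_test_scores": []}
    return ForestModel(
        estimator=estimator,
        n_trees=estimator.n_estimators,
        seed=seed,
        grid_record=record,
        classes=tuple(str(c) for c in estimator.classes_),
    )


def _tree_votes(model: ForestModel, x: np.ndarray) -> np.ndarray:
    """(n_trees, n_samples) array of per-tree class-label votes."""
    classes = np.asarray(model.classes)
    return np.stack([
        classes[tree.predict(x).astype(int)] for tree in model.estimator.estimators_
    ])


def predict_batch(
    model: ForestModel,
    features: Sequence[FeatureVector | np.ndarray],
    positive_class: str = POSITIVE_CLASS,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and positive-class vote fractions.

    The label is the mode of the per-tree votes; an exact tie between
    two classes resolves to the lexicographically smaller label.  The
    score is the fraction of trees voting ``positive_class``.
    """
    x = _feature_matrix(features)
    if x.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match training "
            f"dimension {model.estimator.n_features_in_}"
        )
    votes = _tree_votes(model, x)
    classes = sorted(model.classes)  # lexicographic order breaks ties
    counts = np.stack([(votes == c).sum(axis=0) for c in classes])
    labels = np.asarray(classes)[np.argmax(counts, axis=0)]
    scores = (votes == positive_class).mean(axis=0)
    return labels, scores


def predict(
    model: ForestModel,
    features: FeatureVector | np.ndarray,
    positive_class: str = POSITIVE_CLASS,
) -> tuple[str, float]:
    """Majority-vote prediction for a single feature vector."""
    labels, scores = predict_batch(model, [features], positive_class=positive_class)
    return str(labels[0]), float(scores[0])


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _roc_curve(y_true: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR) swept over score thresholds, high to low."""
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    pos = max(int(y.sum()), 1)
    neg = max(int((1 - y).sum()), 1)
    points = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(y.size):
        tp += int(y[i])
        fp += int(1 - y[i])
        if i + 1 < y.size and s[i + 1] == s[i]:
            continue  # only emit a point when the threshold changes
        points.append((fp / neg, tp / pos))
    return points


def evaluate(
    pred_labels: Sequence[str],
    scores: Sequence[float],
    true_labels: Sequence[str],
    positive_class: str = POSITIVE_CLASS,
) -> EvalReport:
    """Confusion matrix and the four screening metrics, plus ROC/AUC.

    Accuracy = (TP+TN)/total, Sensitivity = TP/(TP+FN), Specificity =
    TN/(TN+FP), F1 = 2TP/(2TP+FP+FN); each reported as a percentage
    rounded to two decimals.  0/0 rates are defined as 0 and flagged.
    AUC is the trapezoid-rule area under the ROC swept over score
    thresholds.
    """
    pred = np.asarray([str(l) for l in pred_labels])
    true = np.asarray([str(l) for l in true_labels])
    scores_arr = np.asarray(scores, dtype=float)
    if pred.size == 0:
        raise ValueError("empty inputs")
    if not (pred.size == true.size == scores_arr.size):
        raise ValueError("predictions, scores and truths must have equal length")
    known = set(true) | set(pred)
    if positive_class not in known:
        raise ValueError(f"unknown positive_class {positive_class!r}")

    pos_true = true == positive_class
    pos_pred = pred == positive_class
    tp = int(np.sum(pos_true & pos_pred))
    tn = int(np.sum(~pos_true & ~pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    fn = int(np.sum(pos_true & ~pos_pred))

    flags: list[str] = []

    def rate(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = rate(tp + tn, tp + tn + fp + fn, "accuracy")
    sensitivity = rate(tp, tp + fn, "sensitivity")
    specificity = rate(tn, tn + fp, "specificity")
    f1 = rate(2 * tp, 2 * tp + fp + fn, "f1")

    roc = _roc_curve(pos_true.astype(int), scores_arr)
    fpr = np.array([p[0] for p in roc])
    tpr = np.array([p[1] for p in roc])
    auc = float(np.trapezoid(tpr, fpr))

    def pct(x: float) -> float:
        # round half up (the convention of reported clinical metrics),
        # not Python's half-to-even: 92.1875 -> 92.19
        return float(np.floor(100 * x * 100 + 0.5) / 100)

    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=pct(accuracy),
        sensitivity=pct(sensitivity),
        specificity=pct(specificity),
        f1=pct(f1),
        auc=pct(auc),
        roc_points=tuple((float(a), float(b)) for a, b in roc),
        zero_division_flags=tuple(flags),
    )


def feature_importance(
    model: ForestModel,
    layout: tuple[int, int],
) -> list[tuple[int, str, float]]:
    """Impurity-decrease importances tagged HOG/LBP, sorted descending.

    ``layout`` is (hog_length, lbp_length); importances are normalized
    to sum to 1 (sklearn's convention).  Returns (feature index, domain
    tag, importance) triples.
    """
    try:
        importances = model.estimator.feature_importances_
    except Exception as exc:  # pragma: no cover - sklearn raises NotFittedError
        raise ValueError("model is not trained") from exc
    hog_length, lbp_length = layout
    if hog_length + lbp_length != importances.size:
        raise ValueError("layout does not match the model's feature dimension")
    tagged = [
        (i, "HOG" if i < hog_length else "LBP", float(v))
        for i, v in enumerate(importances)
    ]
    return sorted(tagged, key=lambda t: (-t[2], t[0]))
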