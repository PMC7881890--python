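"""Identity and group decoding with leakage-free folding.

Three experiment designs over a complete participants x images trial set:

* ``leave_one_image_out`` — one fold per image; all trials of the held-out
  image form the validation set, so identity prediction cannot exploit
  image-specific content (endogenous factors only);
* ``repeated_split`` — n independent 70/30 trial-level splits (group
  decoding);
* ``leave_one_participant_out_per_image`` — within one image, one fold per
  participant (per-image group decoding on fixation maps).

Within every fold the histogram bin edges, the standardization statistics,
the feature-selection mask and the tuned hyper-parameters are functions of
the training trials only.  Feature selection fits extremely-randomized-trees
importances and keeps features above ``t x mean importance``, with ``t`` and
the selector's own hyper-parameters chosen by stratified inner
cross-validation; classifier hyper-parameters are then tuned the same way on
the selected features.

Default search grids: C in {0.25, 0.5, 1, 2, 4} for both SVMs; selection
thresholds {1.7, 1.8, 1.9, 2.0, 2.1} x mean importance with selector
max_depth {10, 30, 50, 70, 90} and min_samples_split {2, 5, 10, 15, 20};
decision-tree criterion {gini, entropy}, max_depth {10, 20, ..., 80},
max_features {sqrt}, min_samples_leaf 1..10, min_samples_split 2..10.

The chance-level statistic is a one-sample location test of the per-fold
accuracies against the chance constant (1/n_classes for identity, 0.5 for
group decoding irrespective of class imbalance).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .event_detection import detect_fixations_idt, velocity_series
from .features import (
    N_DURATION_BINS,
    N_SACCADE_BINS,
    N_VELOCITY_BINS,
    fit_bin_edges,
    fixation_map,
    histogram_feature,
)
from .gaze_io import Trial

__all__ = [
    "FoldPlan", "ClassifierSpec", "DecodingResult", "make_folds",
    "select_features", "run_decoding", "per_image_group_decoding",
    "test_vs_chance",
]

logger = logging.getLogger(__name__)

TrialKey = tuple[str, str]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear_svm": {"C": [0.25, 0.5, 1, 2, 4]},
    "rbf_svm": {"C": [0.25, 0.5, 1, 2, 4]},
    "decision_tree": {
        "criterion": ["gini", "entropy"],
        "max_depth": [10, 20, 30, 40, 50, 60, 70, 80],
        "max_features": ["sqrt"],
        "min_samples_leaf": list(range(1, 11)),
        "min_samples_split": list(range(2, 11)),
    },
}


@dataclass
class ClassifierSpec:
    """Classifier family plus its tuning and feature-selection grids."""

    family: str = "rbf_svm"
    hyper_grid: dict[str, list] | None = None
    feature_selection: bool = True
    selection_thresholds: tuple[float, ...] = (1.7, 1.8, 1.9, 2.0, 2.1)
    selector_max_depth: tuple[int, ...] = (10, 30, 50, 70, 90)
    selector_min_samples_split: tuple[int, ...] = (2, 5, 10, 15, 20)
    selector_n_estimators: int = 50
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.hyper_grid is None:
            self.hyper_grid = {
                k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()
            }

    def make_estimator(self, params: dict, seed: int):
        if self.family == "linear_svm":
            return LinearSVC(random_state=seed, **params)
        if self.family == "rbf_svm":
            return SVC(kernel="rbf", random_state=seed, **params)
        return DecisionTreeClassifier(random_state=seed, **params)

    def param_grid(self) -> list[dict]:
        keys = sorted(self.hyper_grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.hyper_grid[k] for k in keys))
        ]


@dataclass(frozen=True)
class FoldPlan:
    """Train/validation trial-key splits for one experiment design."""

    scheme: str
    folds: tuple[tuple[tuple[TrialKey, ...], tuple[TrialKey, ...]], ...]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.folds)


@dataclass
class DecodingResult:
    """Aggregated outcome of one decoding experiment."""

    classes: list[str]
    per_fold_accuracy: np.ndarray
    confusion: np.ndarray  # true x predicted, pooled over folds
    per_class_rate: dict[str, float]
    chance: float
    test_vs_chance: tuple[float, float]
    topk_accuracy: float | None = None
    top_k: int | None = None
    selected_features: list[np.ndarray] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_fold_accuracy.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.per_fold_accuracy.std(ddof=1)) if (
            self.per_fold_accuracy.size > 1
        ) else 0.0

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())


def make_folds(
    trials: list[Trial],
    scheme: str,
    n_iter: int = 14,
    val_fraction: float = 0.3,
    seed: int = 0,
    image_id: str | None = None,
) -> FoldPlan:
    """Build the train/validation splits for one of the three designs.

    ``leave_one_image_out`` requires a complete design (every participant
    has every image) and raises with the missing pairs listed otherwise.
    ``repeated_split`` draws ``n_iter`` independent trial-level splits with
    ``floor(val_fraction * n)`` validation trials each.
    ``leave_one_participant_out_per_image`` needs ``image_id`` and yields
    one single-trial validation fold per participant.
    """
    keys = [t.key for t in trials]
    keyset = set(keys)
    if len(keyset) != len(keys):
        raise ValueError("duplicate (participant, image) trials in dataset")
    participants = sorted({p for p, _ in keys})
    images = sorted({i for _, i in keys})

    if scheme == "leave_one_image_out":
        missing = [
            (p, i) for p in participants for i in images if (p, i) not in keyset
        ]
        if missing:
            raise ValueError(
                f"incomplete design for leave_one_image_out; missing: {missing}"
            )
        folds = tuple(
            (
                tuple(k for k in keys if k[1] != img),
                tuple(k for k in keys if k[1] == img),
            )
            for img in images
        )
    elif scheme == "repeated_split":
        rng = np.random.default_rng(seed)
        n_val = int(np.floor(val_fraction * len(keys)))
        if n_val < 1 or n_val >= len(keys):
            raise ValueError("val_fraction leaves an empty train or val set")
        folds_list = []
        for _ in range(n_iter):
            order = rng.permutation(len(keys))
            val = tuple(keys[i] for i in sorted(order[:n_val]))
            train = tuple(keys[i] for i in sorted(order[n_val:]))
            folds_list.append((train, val))
        folds = tuple(folds_list)
    elif scheme == "leave_one_participant_out_per_image":
        if image_id is None:
            raise ValueError("image_id is required for the per-image scheme")
        img_keys = [k for k in keys if k[1] == image_id]
        if not img_keys:
            raise ValueError(f"no trials for image {image_id!r}")
        folds = tuple(
            (
                tuple(k for k in img_keys if k[0] != p),
                tuple(k for k in img_keys if k[0] == p),
            )
            for p in sorted(p for p, _ in img_keys)
        )
    else:
        raise ValueError(f"unknown fold scheme {scheme!r}")
    return FoldPlan(scheme=scheme, folds=folds, seed=seed)


def _inner_splits(y: np.ndarray, k: int, seed: int):
    """Stratified inner splits, degrading gracefully on tiny classes."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(k, counts.min()))
    if n_splits < 2:
        return None
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    seed: int = 0,
) -> np.ndarray:
    """Importance-based feature selection on training data only.

    Fits extremely-randomized-trees importances and keeps features with
    importance above ``t x mean importance``.  The threshold ``t`` and the
    selector's (max_depth, min_samples_split) are chosen by stratified
    inner cross-validation, scoring each candidate mask with the spec's
    classifier family at default hyper-parameters.  Never returns an empty
    set: an all-constant (zero-importance) training block falls back to the
    single most important feature with a warning.

    Returns the sorted selected feature indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("feature selection requires >= 2 classes")

    def _mask(importances: np.ndarray, t: float) -> np.ndarray:
        m = importances > t * importances.mean()
        if not m.any():
            m = np.zeros_like(m)
            m[int(np.argmax(importances))] = True
        return m

    selector_grid = list(
        itertools.product(
            spec.selector_max_depth, spec.selector_min_samples_split
        )
    )
    splits = _inner_splits(y, spec.inner_folds, seed)
    scores: dict[tuple[int, int, float], list[float]] = {
        (d, s, t): []
        for (d, s) in selector_grid
        for t in spec.selection_thresholds
    }
    if splits is not None:
        for tr, va in splits:
            for depth, split in selector_grid:
                forest = ExtraTreesClassifier(
                    n_estimators=spec.selector_n_estimators,
                    max_depth=depth,
                    min_samples_split=split,
                    random_state=seed,
                    n_jobs=1,
                )
                forest.fit(X[tr], y[tr])
                imp = forest.feature_importances_
                for t in spec.selection_thresholds:
                    m = _mask(imp, t)
                    clf = spec.make_estimator({}, seed)
                    clf.fit(X[tr][:, m], y[tr])
                    scores[(depth, split, t)].append(
                        float(clf.score(X[va][:, m], y[va]))
                    )
        best, best_score = None, -np.inf
        for depth, split in selector_grid:
            for t in spec.selection_thresholds:
                sc = float(np.mean(scores[(depth, split, t)]))
                if sc > best_score:  # strict: grid order breaks ties
                    best, best_score = (depth, split, t), sc
    else:  # too few samples per class to cross-validate: first grid point
        best = (
            spec.selector_max_depth[0],
            spec.selector_min_samples_split[0],
            spec.selection_thresholds[0],
        )
    depth, split, t = best
    forest = ExtraTreesClassifier(
        n_estimators=spec.selector_n_estimators,
        max_depth=depth,
        min_samples_split=split,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    imp = forest.feature_importances_
    if not np.any(imp > 0):
        warnings.warn(
            "all feature importances are zero; falling back to top-1 feature",
            stacklevel=2,
        )
    mask = _mask(imp, t)
    return np.flatnonzero(mask)


def _tune_params(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec, seed: int
) -> dict:
    """Pick hyper-parameters by stratified inner CV accuracy (grid order
    breaks ties)."""
    grid = spec.param_grid()
    if len(grid) == 1:
        return grid[0]
    splits = _inner_splits(y, spec.inner_folds, seed)
    if splits is None:
        return grid[0]
    best_params, best_score = grid[0], -np.inf
    for params in grid:
        accs = []
        for tr, va in splits:
            clf = spec.make_estimator(params, seed)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[va], y[va]))
        score = float(np.mean(accs))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def _decision_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        scores = clf.decision_function(X)
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores
    return clf.predict_proba(X)


class _TrialFeatureCache:
    """Per-trial raw ingredients computed once; histograms refit per fold."""

    def __init__(self, trials: list[Trial], grid: int, detector_kwargs: dict):
        self.grid = grid
        self.fixdur: dict[TrialKey, np.ndarray] = {}
        self.sacc: dict[TrialKey, np.ndarray] = {}
        self.vel: dict[TrialKey, np.ndarray] = {}
        self.summary: dict[TrialKey, np.ndarray] = {}
        self.fixmap: dict[TrialKey, np.ndarray] = {}
        for trial in trials:
            ev = detect_fixations_idt(trial, **detector_kwargs)
            fixdur = ev.fixation_durations()
            sacc = ev.saccade_lengths()
            self.fixdur[trial.key] = fixdur
            self.sacc[trial.key] = sacc
            self.vel[trial.key] = velocity_series(trial)
            self.summary[trial.key] = np.array(
                [
                    fixdur.mean() if fixdur.size else 0.0,
                    float(fixdur.size),
                    sacc.mean() if sacc.size else 0.0,
                    float(sacc.size),
                ]
            )
            self.fixmap[trial.key] = fixation_map(ev, grid)

    def fit_edges(self, keys, fitted_on: str) -> dict:
        return {
            "fixdur": fit_bin_edges(
                np.concatenate([self.fixdur[k] for k in keys]),
                N_DURATION_BINS, False, fitted_on,
            ),
            "sacc": fit_bin_edges(
                np.concatenate([self.sacc[k] for k in keys]),
                N_SACCADE_BINS, False, fitted_on,
            ),
            "vel": fit_bin_edges(
                np.concatenate([self.vel[k] for k in keys]),
                N_VELOCITY_BINS, True, fitted_on,
            ),
        }

    def matrix(self, keys, edges: dict) -> np.ndarray:
        rows = [
            np.concatenate(
                [
                    self.summary[k],
                    histogram_feature(self.fixdur[k], edges["fixdur"]),
                    histogram_feature(self.sacc[k], edges["sacc"]),
                    histogram_feature(self.vel[k], edges["vel"]),
                    self.fixmap[k],
                ]
            )
            for k in keys
        ]
        return np.vstack(rows)


def _labels_for(trials: list[Trial], label: str) -> dict[TrialKey, str]:
    if label == "individual":
        return {t.key: t.participant_id for t in trials}
    if label == "group":
        return {t.key: t.group for t in trials}
    raise ValueError(f"unknown label kind {label!r}")


def run_decoding(
    trials: list[Trial],
    label: str,
    folds: FoldPlan,
    spec: ClassifierSpec | None = None,
    grid: int = 10,
    seed: int = 0,
    top_k: int | None = None,
    detector_kwargs: dict | None = None,
    label_map: dict[TrialKey, str] | None = None,
) -> DecodingResult:
    """Run one decoding experiment over a fold plan.

    For each fold: fit histogram edges on training trials, assemble and
    standardize features with training statistics, select features, tune
    hyper-parameters by inner CV, fit, and predict the validation trials.
    ``top_k`` (defaulting to 5 for identity decoding) counts a prediction
    correct when the true class is among the k highest decision scores.
    ``label_map`` overrides the trial labels (e.g. for permutation nulls).
    """
    spec = spec if spec is not None else ClassifierSpec()
    if top_k is None and label == "individual":
        top_k = 5
    labels = label_map if label_map is not None else _labels_for(trials, label)
    cache = _TrialFeatureCache(trials, grid, detector_kwargs or {})
    classes = sorted(set(labels.values()))
    class_index = {c: i for i, c in enumerate(classes)}
    n_classes = len(classes)

    confusion = np.zeros((n_classes, n_classes), dtype=int)
    per_fold_acc: list[float] = []
    per_fold_topk: list[float] = []
    selected_all: list[np.ndarray] = []
    params_all: list[dict] = []

    for f, (train_keys, val_keys) in enumerate(folds.folds):
        edges = cache.fit_edges(train_keys, fitted_on=f"fold{f}")
        X_tr = cache.matrix(train_keys, edges)
        X_va = cache.matrix(val_keys, edges)
        y_tr = np.array([labels[k] for k in train_keys])
        y_va = np.array([labels[k] for k in val_keys])

        scaler = StandardScaler().fit(X_tr)
        X_tr = scaler.transform(X_tr)
        X_va = scaler.transform(X_va)

        if spec.feature_selection:
            sel = select_features(X_tr, y_tr, spec, seed=seed + f)
        else:
            sel = np.arange(X_tr.shape[1])
        selected_all.append(sel)
        X_tr_s, X_va_s = X_tr[:, sel], X_va[:, sel]

        params = _tune_params(X_tr_s, y_tr, spec, seed=seed + f)
        params_all.append(params)
        clf = spec.make_estimator(params, seed)
        clf.fit(X_tr_s, y_tr)
        pred = clf.predict(X_va_s)

        per_fold_acc.append(float(np.mean(pred == y_va)))
        for yt, yp in zip(y_va, pred):
            confusion[class_index[yt], class_index[yp]] += 1

        if top_k is not None:
            scores = _decision_scores(clf, X_va_s)
            k = min(top_k, scores.shape[1])
            top = np.argsort(-scores, axis=1)[:, :k]
            train_classes = np.asarray(clf.classes_)
            hits = [
                yt in train_classes[row] for yt, row in zip(y_va, top)
            ]
            per_fold_topk.append(float(np.mean(hits)))
        logger.info(
            "fold %d/%d: accuracy %.3f (%d features, params %s)",
            f + 1, len(folds.folds), per_fold_acc[-1], sel.size, params,
        )

    row_sums = confusion.sum(axis=1)
    per_class_rate = {
        c: (float(confusion[i, i] / row_sums[i]) if row_sums[i] else float("nan"))
        for c, i in class_index.items()
    }
    chance = (1.0 / n_classes) if label == "individual" else 0.5
    acc = np.array(per_fold_acc)
    return DecodingResult(
        classes=classes,
        per_fold_accuracy=acc,
        confusion=confusion,
        per_class_rate=per_class_rate,
        chance=chance,
        test_vs_chance=test_vs_chance(acc, chance),
        topk_accuracy=(
            float(np.mean(per_fold_topk)) if per_fold_topk else None
        ),
        top_k=top_k,
        selected_features=selected_all,
        chosen_params=params_all,
    )


def per_image_group_decoding(
    trials: list[Trial],
    image_id: str,
    grid: int = 20,
    seed: int = 0,
    spec: ClassifierSpec | None = None,
    detector_kwargs: dict | None = None,
) -> DecodingResult:
    """Group decoding for one image: 20x20 fixation maps, linear SVM,
    leave-one-participant-out.

    Every participant in the dataset must have a trial for ``image_id``
    (missing participants are listed in the error).  Features are the
    fixation map only; standardization and C tuning follow the training
    fold of each leave-one-out split.
    """
    participants = sorted({t.participant_id for t in trials})
    subset = [t for t in trials if t.image_id == image_id]
    have = {t.participant_id for t in subset}
    missing = [p for p in participants if p not in have]
    if missing:
        raise ValueError(
            f"image {image_id!r} missing participants: {missing}"
        )
    spec = spec if spec is not None else ClassifierSpec(
        family="linear_svm", feature_selection=False
    )
    labels = {t.key: t.group for t in subset}
    classes = sorted(set(labels.values()))
    class_index = {c: i for i, c in enumerate(classes)}
    maps = {}
    for trial in subset:
        ev = detect_fixations_idt(trial, **(detector_kwargs or {}))
        maps[trial.key] = fixation_map(ev, grid)

    folds = make_folds(
        subset, "leave_one_participant_out_per_image", image_id=image_id,
        seed=seed,
    )
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    per_fold_acc = []
    params_all = []
    for f, (train_keys, val_keys) in enumerate(folds.folds):
        X_tr = np.vstack([maps[k] for k in train_keys])
        X_va = np.vstack([maps[k] for k in val_keys])
        y_tr = np.array([labels[k] for k in train_keys])
        y_va = np.array([labels[k] for k in val_keys])
        scaler = StandardScaler().fit(X_tr)
        params = _tune_params(scaler.transform(X_tr), y_tr, spec, seed=seed + f)
        params_all.append(params)
        clf = spec.make_estimator(params, seed)
        clf.fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(X_va))
        per_fold_acc.append(float(np.mean(pred == y_va)))
        for yt, yp in zip(y_va, pred):
            confusion[class_index[yt], class_index[yp]] += 1

    row_sums = confusion.sum(axis=1)
    acc = np.array(per_fold_acc)
    return DecodingResult(
        classes=classes,
        per_fold_accuracy=acc,
        confusion=confusion,
        per_class_rate={
            c: (
                float(confusion[i, i] / row_sums[i])
                if row_sums[i] else float("nan")
            )
            for c, i in class_index.items()
        },
        chance=0.5,
        test_vs_chance=test_vs_chance(acc, 0.5),
        chosen_params=params_all,
    )


def test_vs_chance(
    per_fold_accuracy: np.ndarray, chance: float
) -> tuple[float, float]:
    """One-sample location test of fold accuracies against chance.

    Implemented as a two-sided one-sample t test (equivalent to a
    single-group ANOVA against a constant).  Zero-variance accuracies fall
    back to exact comparison with a warning: all folds equal to chance give
    (0, 1); a degenerate common value away from chance gives a signed
    infinite statistic with p = 0.
    """
    acc = np.asarray(per_fold_accuracy, dtype=float)
    if acc.size < 2:
        raise ValueError("test_vs_chance requires >= 2 folds")
    if np.ptp(acc) == 0.0:
        warnings.warn(
            "zero-variance fold accuracies; exact comparison fallback",
            stacklevel=2,
        )
        if acc[0] == chance:
            return (0.0, 1.0)
        return (float(np.sign(acc[0] - chance) * np.inf), 0.0)
    stat, p = stats.ttest_1samp(acc, popmean=chance)
    return (float(stat), float(p))
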