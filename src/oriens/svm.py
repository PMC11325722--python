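"""Time-resolved 3-class orientation decoding with linear SVMs.

For every sliding window an independent linear multiclass SVM (one-vs-
rest, C = 1) is trained on pseudo-trials built by averaging balanced
raw trials into five sets: four sets (12 samples = 4 sets x 3
orientations) train the classifier, the held-out set (3 samples) tests
it.  The 5-fold rotation is repeated 20 times with fresh random set
assignments, yielding 100 fold accuracies per window whose mean is the
reported decoding accuracy.  Softmax over the three per-class decision
values of each test sample gives posterior probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.svm import LinearSVC

from .epochs import EpochsArray
from .preprocessing import (
    WindowSpec,
    average_into_sets,
    extract_window_features,
    sliding_windows,
    undersample_balance,
    zscore_train_test,
)

__all__ = [
    "DecoderConfig",
    "AccuracyTimecourse",
    "PosteriorTimecourse",
    "decode_window",
    "decode_timecourse",
    "posterior_timecourse",
]


@dataclass(frozen=True)
class DecoderConfig:
    """Configuration of the sliding-window 3-class decoder."""

    classes: tuple[float, float, float] = (15.0, 45.0, 75.0)
    n_cv_sets: int = 5
    n_repetitions: int = 20
    C: float = 1.0
    window: WindowSpec = field(default_factory=WindowSpec)
    zscore_range_ms: tuple[float, float] = (-300.0, 900.0)
    label_column: str = "orientation"
    seed: int | None = 0

    def __post_init__(self):
        if len(set(self.classes)) != 3:
            raise ValueError("classes must be three distinct orientations")
        if self.n_cv_sets < 2:
            raise ValueError("need at least two cross-validation sets")


@dataclass
class AccuracyTimecourse:
    """Decoding accuracy per window with per-fold diagnostics.

    ``fold_accuracies`` has shape ``(n_windows, n_repetitions *
    n_cv_sets)``; ``accuracy`` is its per-window mean.
    ``n_train_samples`` records the training-fold size.
    """

    window_centers: np.ndarray
    fold_accuracies: np.ndarray
    n_train_samples: int

    @property
    def accuracy(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_center_ms": self.window_centers, "accuracy": self.accuracy}
        )


@dataclass
class PosteriorTimecourse:
    """Class posterior probabilities per window and presented orientation.

    ``raw`` has shape ``(n_windows, n_repetitions * n_cv_sets,
    n_classes, n_classes)``: for each fold, one softmax triplet per
    presented orientation — 300 probabilities per window at the default
    100 folds.  ``probabilities`` averages over folds to shape
    ``(n_windows, n_classes presented, n_classes)``.
    """

    window_centers: np.ndarray
    classes: tuple[float, ...]
    raw: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return self.raw.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        probs = self.probabilities
        for w, center in enumerate(self.window_centers):
            for i, presented in enumerate(self.classes):
                for j, cls in enumerate(self.classes):
                    rows.append(
                        {
                            "window_center_ms": center,
                            "presented": presented,
                            "class": cls,
                            "probability": probs[w, i, j],
                        }
                    )
        return pd.DataFrame(rows)


def _fit_svc(train_X, train_y, C, seed):
    clf = LinearSVC(C=C, random_state=int(seed) % (2**32), max_iter=20000)
    clf.fit(train_X, train_y)
    return clf


def _predict(clf, X):
    # Highest decision value wins; np.argmax breaks ties toward the
    # lowest class index (classes_ is sorted ascending).
    d = np.atleast_2d(clf.decision_function(X))
    return clf.classes_[np.argmax(d, axis=1)], d


def decode_window(train_X, train_y, test_X, test_y, C: float = 1.0, seed: int = 0) -> float:
    """Train a linear multiclass SVM and return the test accuracy.

    Raises
    ------
    ValueError
        If fewer than three classes are present in the training labels.
    """
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 3:
        raise ValueError("all three classes must be present in the training fold")
    clf = _fit_svc(np.asarray(train_X), train_y, C, seed)
    pred, _ = _predict(clf, np.asarray(test_X))
    return float(np.mean(pred == np.asarray(test_y)))


def _decode_engine(e: EpochsArray, cfg: DecoderConfig, collect_posteriors: bool):
    """Shared machinery for accuracy and posterior timecourses."""
    rng = np.random.default_rng(cfg.seed)
    kept = e.kept()
    class_set = np.asarray(sorted(cfg.classes), dtype=float)
    labels = kept.trial_table[cfg.label_column].to_numpy(dtype=float)
    mask = np.isin(labels, class_set)
    if not np.all(np.isin(class_set, labels)):
        missing = class_set[~np.isin(class_set, labels)]
        raise ValueError(f"epochs contain no trials for class(es) {missing}")
    sub = kept.subset(np.flatnonzero(mask))

    windows = sliding_windows(sub.times, cfg.window)
    n_windows = len(windows)
    n_folds_total = cfg.n_repetitions * cfg.n_cv_sets
    accs = np.zeros((n_windows, n_folds_total))
    raw_post = (
        np.zeros((n_windows, n_folds_total, 3, 3)) if collect_posteriors else None
    )

    fold_idx = 0
    for rep in range(cfg.n_repetitions):
        # Undersampling is redrawn for every repetition, as is the
        # random assignment of trials to averaging sets.
        balanced = undersample_balance(sub, cfg.label_column, seed=rng)
        pseudo = average_into_sets(balanced, cfg.n_cv_sets, seed=rng, label_column=cfg.label_column)
        set_index = pseudo.trial_table["set_index"].to_numpy()
        for fold in range(cfg.n_cv_sets):
            train_mask = set_index != fold
            train = pseudo.subset(np.flatnonzero(train_mask))
            test = pseudo.subset(np.flatnonzero(~train_mask))
            train_z, test_z = zscore_train_test(train, test, cfg.zscore_range_ms)
            ytr = train_z.trial_table[cfg.label_column].to_numpy(dtype=float)
            yte = test_z.trial_table[cfg.label_column].to_numpy(dtype=float)
            fold_seed = rng.integers(2**31)
            for w, window in enumerate(windows):
                Xtr = extract_window_features(train_z, window, "spatiotemporal")
                Xte = extract_window_features(test_z, window, "spatiotemporal")
                if np.unique(ytr).size < 3:
                    raise ValueError("a class is missing from the training fold")
                clf = _fit_svc(Xtr, ytr, cfg.C, fold_seed)
                pred, dec = _predict(clf, Xte)
                accs[w, fold_idx] = np.mean(pred == yte)
                if collect_posteriors:
                    probs = softmax(dec, axis=1)
                    # Rows indexed by presented orientation, columns by
                    # class, both in ascending class order.
                    order = np.argsort(clf.classes_)
                    for sample, presented in enumerate(yte):
                        i = int(np.searchsorted(class_set, presented))
                        raw_post[w, fold_idx, i, :] = probs[sample, order]
            fold_idx += 1

    centers = np.array([w.center_ms for w in windows])
    acc_tc = AccuracyTimecourse(centers, accs, n_train_samples=(cfg.n_cv_sets - 1) * 3)
    post_tc = (
        PosteriorTimecourse(centers, tuple(class_set), raw_post)
        if collect_posteriors
        else None
    )
    return acc_tc, post_tc


def decode_timecourse(e: EpochsArray, cfg: DecoderConfig) -> AccuracyTimecourse:
    """Sliding-window 3-class decoding accuracy timecourse.

    Per window: balance by undersampling, average into ``n_cv_sets``
    pseudo-trial sets, run leave-one-set-out cross-validation with
    per-fold z-scoring from training statistics, repeat with fresh
    random set assignments, and retain every fold accuracy.
    """
    acc, _ = _decode_engine(e, cfg, collect_posteriors=False)
    return acc


def posterior_timecourse(e: EpochsArray, cfg: DecoderConfig) -> PosteriorTimecourse:
    """Softmax posterior probabilities of the three classes per window."""
    _, post = _decode_engine(e, cfg, collect_posteriors=True)
    return post
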