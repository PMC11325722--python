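"""Signal conditioning and the windowing machinery shared by both
decoding analyses.

The canonical chain is: zero-phase band-pass (1–80 Hz), integer
decimation to 500 Hz, baseline correction over the pre-stimulus window,
restriction to the ten occipito-parietal electrodes, class balancing by
undersampling, trial averaging into pseudo-trial sets, per-fold
z-scoring with training statistics, and sliding 100 ms windows stepped
every 2 ms over −300…900 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochsArray

__all__ = [
    "WindowSpec",
    "Window",
    "preprocess_epochs",
    "select_electrodes",
    "undersample_balance",
    "average_into_sets",
    "zscore_train_test",
    "sliding_windows",
    "extract_window_features",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: width and step in ms over a time range."""

    width_ms: float = 100.0
    step_ms: float = 2.0
    range_ms: tuple[float, float] = (-300.0, 900.0)

    def __post_init__(self):
        if self.width_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window width and step must be positive")
        if self.range_ms[1] - self.range_ms[0] < self.width_ms:
            raise ValueError("window range must be at least one window wide")


@dataclass(frozen=True)
class Window:
    """One analysis window: sample slice plus its start/center time."""

    start_ms: float
    center_ms: float
    sl: slice


def preprocess_epochs(
    e: EpochsArray,
    band: tuple[float, float] = (1.0, 80.0),
    target_rate: float = 500.0,
    baseline: tuple[float, float] = (-300.0, 0.0),
    order: int = 6,
) -> EpochsArray:
    """Zero-phase band-pass, decimate and baseline-correct epochs.

    A Butterworth band-pass of the given order (applied forward and
    backward, so the effective attenuation is squared and the phase
    response is zero) is followed by integer decimation to
    ``target_rate`` and subtraction of the per-trial, per-electrode mean
    over the ``baseline`` window.

    Raises
    ------
    ValueError
        If the upper band edge reaches the target Nyquist rate, the
        decimation factor is not an integer, or the baseline window lies
        outside the epoch.
    """
    low, high = band
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    if high >= target_rate / 2:
        raise ValueError(
            f"upper band edge {high} Hz violates the Nyquist rate of {target_rate} Hz"
        )
    factor = e.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} Hz must divide the sampling rate {e.sampling_rate} Hz"
        )
    factor = int(round(factor))
    b0, b1 = baseline
    if b0 < e.times[0] - 1e-9 or b1 > e.times[-1] + 1e-9:
        raise ValueError("baseline window lies outside the epoch")

    sos = sps.butter(order, [low, high], btype="bandpass", fs=e.sampling_rate, output="sos")
    data = sps.sosfiltfilt(sos, e.data, axis=-1)
    data = data[:, :, ::factor]
    times = e.times[::factor]

    bmask = (times >= b0 - 1e-9) & (times <= b1 + 1e-9)
    data = data - data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochsArray(data, times, target_rate, list(e.electrode_labels), e.trial_table.copy())


def select_electrodes(e: EpochsArray, labels) -> EpochsArray:
    """Restrict (and reorder) the electrode dimension to ``labels``."""
    index = {lab: i for i, lab in enumerate(e.electrode_labels)}
    missing = [lab for lab in labels if lab not in index]
    if missing:
        raise KeyError(f"electrode(s) not present: {', '.join(missing)}")
    idx = [index[lab] for lab in labels]
    return EpochsArray(
        e.data[:, idx, :], e.times, e.sampling_rate, list(labels), e.trial_table.copy()
    )


def undersample_balance(e: EpochsArray, label_column: str, seed=None) -> EpochsArray:
    """Equalize trial counts across classes by random undersampling.

    Every class is reduced to the minimum class count by sampling
    without replacement; the draw is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    labels = e.trial_table[label_column].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("every class must have at least one trial")
    n_min = counts.min()
    chosen = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        chosen.append(rng.choice(idx, size=n_min, replace=False))
    chosen = np.sort(np.concatenate(chosen))
    return e.subset(chosen)


def average_into_sets(e: EpochsArray, n_sets: int, seed=None, label_column: str = "orientation") -> EpochsArray:
    """Average same-class trials into ``n_sets`` pseudo-trials per class.

    Trials of each class are randomly partitioned into ``n_sets`` groups
    of equal size ``count // n_sets`` (remainder trials are dropped so
    every pseudo-trial averages the same number of raw trials) and
    averaged within each group.  The output trial table has one row per
    pseudo-trial with the class label and a ``set_index`` column.
    """
    rng = np.random.default_rng(seed)
    labels = e.trial_table[label_column].to_numpy()
    classes = np.unique(labels)
    out_data, out_rows = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size < n_sets:
            raise ValueError(
                f"class {c!r} has {idx.size} trials, fewer than {n_sets} sets"
            )
        g = idx.size // n_sets
        perm = rng.permutation(idx)[: n_sets * g].reshape(n_sets, g)
        for set_index in range(n_sets):
            out_data.append(e.data[perm[set_index]].mean(axis=0))
            out_rows.append({label_column: c, "set_index": set_index, "n_averaged": g})
    return EpochsArray(
        np.stack(out_data),
        e.times,
        e.sampling_rate,
        list(e.electrode_labels),
        pd.DataFrame(out_rows),
    )


def zscore_train_test(
    train: EpochsArray, test: EpochsArray, range_ms: tuple[float, float] = (-300.0, 900.0)
) -> tuple[EpochsArray, EpochsArray]:
    """Z-score both partitions with per-electrode training statistics.

    The mean and SD are computed per electrode from the training data
    pooled over trials and over samples within ``range_ms``; both
    partitions are transformed with those statistics (the test partition
    never contributes to them).
    """
    t0, t1 = range_ms
    for part in (train, test):
        if t0 < part.times[0] - 1e-9 or t1 > part.times[-1] + 1e-9:
            raise ValueError("z-scoring range lies outside the epoch")
    mask = (train.times >= t0 - 1e-9) & (train.times <= t1 + 1e-9)
    pooled = train.data[:, :, mask]
    mu = pooled.mean(axis=(0, 2))
    sd = pooled.std(axis=(0, 2))
    if np.any(sd == 0):
        bad = [train.electrode_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero standard deviation on electrode(s): {', '.join(bad)}")

    def transform(part):
        data = (part.data - mu[None, :, None]) / sd[None, :, None]
        return EpochsArray(
            data, part.times, part.sampling_rate, list(part.electrode_labels), part.trial_table.copy()
        )

    return transform(train), transform(test)


def sliding_windows(times, spec: WindowSpec) -> list[Window]:
    """Enumerate sliding analysis windows over the epoch time axis.

    Windows of ``width_ms`` start every ``step_ms`` from the lower edge
    of ``range_ms``; each covers samples with ``start <= t < start +
    width`` and is reported with its center time ``start + width / 2``.
    """
    times = np.asarray(times, dtype=float)
    t0, t1 = spec.range_ms
    n_windows = int(np.floor((t1 - t0 - spec.width_ms) / spec.step_ms + 1e-9)) + 1
    if n_windows < 1:
        raise ValueError("window specification produces no windows")
    windows = []
    for i in range(n_windows):
        start = t0 + i * spec.step_ms
        i0 = int(np.searchsorted(times, start - 1e-9, side="left"))
        i1 = int(np.searchsorted(times, start + spec.width_ms - 1e-9, side="left"))
        if i1 <= i0:
            raise ValueError(f"window starting at {start} ms contains no samples")
        windows.append(Window(start, start + spec.width_ms / 2.0, slice(i0, i1)))
    return windows


def extract_window_features(e: EpochsArray, window: Window, mode: str = "spatiotemporal") -> np.ndarray:
    """Per-trial feature matrix for one analysis window.

    ``spatiotemporal`` flattens electrodes x in-window samples (the SVM
    path); ``window_mean`` averages over in-window samples, one feature
    per electrode (the encoding-model path).
    """
    block = e.data[:, :, window.sl]
    if mode == "spatiotemporal":
        return block.reshape(e.n_trials, -1)
    if mode == "window_mean":
        return block.mean(axis=2)
    raise ValueError(f"unknown feature mode: {mode!r}")
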