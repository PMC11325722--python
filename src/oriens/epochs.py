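"""Epoched multichannel EEG container and its on-disk format.

An :class:`EpochsArray` is a ``(trials, electrodes, samples)`` voltage
array plus its time axis (ms relative to stimulus onset), sampling rate,
electrode labels and a per-trial table (pandas DataFrame) carrying
condition labels, participant ids and a boolean ``keep`` flag that all
downstream operations honor.

The on-disk container is deliberately simple and self-describing: a
``data.npy`` array, a ``meta.json`` sidecar (labels, times, rate) and a
``trials.csv`` trial table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochsArray", "OCCIPITO_PARIETAL_ELECTRODES", "ALL_ELECTRODES"]

#: The ten occipital and parietal electrodes used by the decoding analyses.
OCCIPITO_PARIETAL_ELECTRODES = ["P3", "P4", "P7", "P8", "Pz", "PO3", "PO4", "O1", "O2", "Oz"]

#: The full 32-electrode montage of the recording setup.
ALL_ELECTRODES = [
    "FP1", "FP2", "F3", "F4", "F7", "F8", "Fz", "T7", "T8", "C3", "C4", "Cz",
    "FC1", "FC2", "FC5", "FC6", "P3", "P4", "P7", "P8", "Pz", "TP9", "TP10",
    "CP1", "CP2", "CP5", "CP6", "PO3", "PO4", "O1", "O2", "Oz",
]


@dataclass
class EpochsArray:
    """Trials x electrodes x samples voltage array with metadata.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_electrodes, n_samples)
        Voltages (µV; arbitrary units in simulation).
    times : ndarray of float
        Sample times in ms relative to stimulus onset, uniformly spaced
        at ``1000 / sampling_rate``.
    sampling_rate : float
        Sampling rate in Hz.
    electrode_labels : list of str
    trial_table : DataFrame
        One row per trial.  Conventional columns: a condition label
        (``orientation`` or ``set_name``), ``participant`` and ``keep``.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    electrode_labels: list[str]
    trial_table: pd.DataFrame

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, electrodes, samples)")
        n_trials, n_el, n_samp = self.data.shape
        if self.times.shape != (n_samp,):
            raise ValueError("times length must match the sample dimension")
        if len(self.electrode_labels) != n_el:
            raise ValueError("electrode_labels length must match the electrode dimension")
        if len(self.trial_table) != n_trials:
            raise ValueError("trial_table length must match the trial dimension")
        dt = 1000.0 / self.sampling_rate
        if n_samp > 1 and not np.allclose(np.diff(self.times), dt, atol=1e-6 * dt):
            raise ValueError("times must be uniformly spaced at 1000/sampling_rate ms")
        self.trial_table = self.trial_table.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochsArray":
        return EpochsArray(
            self.data.copy(),
            self.times.copy(),
            self.sampling_rate,
            list(self.electrode_labels),
            self.trial_table.copy(),
        )

    def subset(self, trial_indices) -> "EpochsArray":
        """Return a new EpochsArray restricted to the given trials."""
        idx = np.asarray(trial_indices)
        return EpochsArray(
            self.data[idx],
            self.times,
            self.sampling_rate,
            list(self.electrode_labels),
            self.trial_table.iloc[idx].reset_index(drop=True),
        )

    def kept(self) -> "EpochsArray":
        """Trials whose ``keep`` flag is true (all trials if no flag)."""
        if "keep" not in self.trial_table.columns:
            return self
        return self.subset(np.flatnonzero(self.trial_table["keep"].to_numpy()))

    # ---------------------------------------------------------------- I/O

    def save(self, directory) -> Path:
        """Write the container (data.npy + meta.json + trials.csv)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "data.npy", self.data)
        meta = {
            "sampling_rate": self.sampling_rate,
            "electrode_labels": list(self.electrode_labels),
            "tmin_ms": float(self.times[0]),
            "n_samples": int(self.n_samples),
        }
        with open(directory / "meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)
        self.trial_table.to_csv(directory / "trials.csv", index=False)
        return directory

    @classmethod
    def load(cls, directory) -> "EpochsArray":
        directory = Path(directory)
        data = np.load(directory / "data.npy")
        with open(directory / "meta.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        times = meta["tmin_ms"] + 1000.0 / meta["sampling_rate"] * np.arange(meta["n_samples"])
        trial_table = pd.read_csv(directory / "trials.csv")
        return cls(data, times, meta["sampling_rate"], meta["electrode_labels"], trial_table)

    @classmethod
    def from_arrays(
        cls,
        data,
        sampling_rate: float,
        tmin_ms: float,
        electrode_labels,
        trial_table=None,
    ) -> "EpochsArray":
        """Convenience importer from a plain array plus an optional trial
        table (DataFrame or path to a CSV file)."""
        data = np.asarray(data, dtype=float)
        times = tmin_ms + 1000.0 / sampling_rate * np.arange(data.shape[2])
        if trial_table is None:
            trial_table = pd.DataFrame({"trial": np.arange(data.shape[0])})
        elif not isinstance(trial_table, pd.DataFrame):
            trial_table = pd.read_csv(trial_table)
        return cls(data, times, sampling_rate, list(electrode_labels), trial_table)
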