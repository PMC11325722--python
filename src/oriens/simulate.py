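"""Synthetic EEG and behavior for the orientation-ensemble study.

Epochs are generated from the linear forward model ``B = W C + noise``:
a fixed electrodes-by-channels weight matrix ``W`` maps channel responses
``C`` (cos^7 tuning curves) to electrode voltages, scaled by a
stimulus-driven temporal envelope, with additive per-electrode AR(1)
Gaussian noise.

The single-orientation task presents six uniform orientations (-75°…75°
in 30° steps).  The ensemble task presents the four primary stimulus
sets; its channel drive is a time-varying mixture of the mean
element-channel response and the response to the (participant-biased)
average orientation.  The mixture weight follows a trapezoid inside the
configured ensemble window, which is the generator's planted ground
truth for when the ensemble representation is present.  The behavioral
adjustment task shares the same per-participant bias, giving the
brain–behavior correlation analysis a recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epochs import EpochsArray, OCCIPITO_PARIETAL_ELECTRODES
from .orientation import ChannelBasis, wrap_orientation
from .stimuli import StimulusSet, builtin_stimulus_sets, stimulus_sets_by_name

__all__ = [
    "ForwardModel",
    "SimulationConfig",
    "make_forward_model",
    "draw_participant_biases",
    "simulate_exp1",
    "simulate_exp2a",
    "simulate_exp2b",
]

#: Uniform stimulus orientations of the single-orientation task (degrees).
EXP1_ORIENTATIONS = (-75.0, -45.0, -15.0, 15.0, 45.0, 75.0)


@dataclass(frozen=True)
class ForwardModel:
    """Linear electrode weights for the channel basis.

    ``weights`` is an ``m x k`` matrix mapping the k channel responses to
    m electrode voltages; it must have full column rank so the encoding
    model is invertible.
    """

    weights: np.ndarray
    electrode_labels: tuple[str, ...]
    basis: ChannelBasis

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        m, k = w.shape
        if k != self.basis.k:
            raise ValueError("weight columns must match the number of channels")
        if len(self.electrode_labels) != m:
            raise ValueError("electrode_labels must match the number of electrodes")
        if m < k:
            raise ValueError(
                f"need at least as many electrodes as channels (m={m} < k={k})"
            )
        if np.linalg.matrix_rank(w) < k:
            raise ValueError("weight matrix must have full column rank")


def make_forward_model(
    m: int = 10,
    basis: ChannelBasis | None = None,
    seed: int | None = None,
    electrode_labels: Sequence[str] | None = None,
) -> ForwardModel:
    """Draw a random full-column-rank ``m x k`` forward weight matrix.

    Weights are standard-normal draws, redrawn in the (measure-zero)
    event of rank deficiency.  Reproducible for a fixed ``seed``.
    """
    basis = basis or ChannelBasis()
    if m < basis.k:
        raise ValueError(
            f"cannot build a rank-{basis.k} forward model with m={m} electrodes"
        )
    if electrode_labels is None:
        if m == len(OCCIPITO_PARIETAL_ELECTRODES):
            electrode_labels = list(OCCIPITO_PARIETAL_ELECTRODES)
        else:
            electrode_labels = [f"E{i + 1}" for i in range(m)]
    rng = np.random.default_rng(seed)
    for _ in range(100):
        w = rng.standard_normal((m, basis.k))
        if np.linalg.matrix_rank(w) == basis.k:
            return ForwardModel(w, tuple(electrode_labels), basis)
    raise RuntimeError("failed to draw a full-rank weight matrix")  # pragma: no cover


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    Trial counts mirror the experimental design: 8 blocks x 120 trials
    split over six orientations in the single-orientation task (160 per
    orientation), 4 blocks x 120 trials over the four primary sets in the
    ensemble EEG task (120 per set), and 60 trials per set over all eight
    sets (primaries plus dummies) in the behavioral task.

    The signal envelope ramps on at ``signal_onset_ms`` (50 ms linear
    ramp), sustains, and ramps off over 100 ms from ``signal_offset_ms``.
    The ensemble mixture weight is a trapezoid that rises from 0 to 1
    over ``ensemble_ramp_ms`` after ``ensemble_onset_ms``, holds, and
    falls back to 0 by ``ensemble_offset_ms`` — the planted window of
    ensemble representation.
    """

    n_participants: int = 12
    trials_per_orientation: int = 160
    trials_per_set: int = 120
    trials_per_set_2b: int = 60
    sampling_rate_hz: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-1000.0, 1500.0)
    signal_onset_ms: float = 80.0
    signal_offset_ms: float = 800.0
    signal_onset_ramp_ms: float = 50.0
    signal_offset_ramp_ms: float = 100.0
    ensemble_onset_ms: float = 400.0
    ensemble_offset_ms: float = 700.0
    ensemble_ramp_ms: float = 100.0
    mixture_weight: Callable | None = None
    signal_gain: float = 1.0
    noise_sd: float = 1.0
    noise_ar1_coefficient: float = 0.5
    participant_bias_sd: float = 5.0
    report_noise_sd: float = 8.0
    seed: int | None = 0

    def __post_init__(self):
        t0, t1 = self.epoch_window_ms
        if not t0 < t1:
            raise ValueError("epoch window must have positive duration")
        if not self.ensemble_onset_ms < self.ensemble_offset_ms:
            raise ValueError("ensemble_onset_ms must precede ensemble_offset_ms")
        if not t0 <= self.ensemble_onset_ms <= t1:
            raise ValueError("ensemble window must lie within the epoch")
        for name in (
            "signal_onset_ramp_ms",
            "signal_offset_ramp_ms",
            "ensemble_ramp_ms",
            "sampling_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.noise_ar1_coefficient < 1:
            raise ValueError("noise_ar1_coefficient must be in [0, 1)")

    def times(self) -> np.ndarray:
        """Epoch sample times in ms."""
        t0, t1 = self.epoch_window_ms
        n = int(round((t1 - t0) * self.sampling_rate_hz / 1000.0))
        return t0 + 1000.0 / self.sampling_rate_hz * np.arange(n)

    def envelope(self, times) -> np.ndarray:
        """Stimulus-driven amplitude envelope in [0, 1] at ``times``."""
        t = np.asarray(times, dtype=float)
        rise = (t - self.signal_onset_ms) / self.signal_onset_ramp_ms
        fall = (self.signal_offset_ms + self.signal_offset_ramp_ms - t) / self.signal_offset_ramp_ms
        return np.clip(np.minimum(rise, fall), 0.0, 1.0)

    def mixture(self, times) -> np.ndarray:
        """Ensemble-vs-element mixture weight in [0, 1] at ``times``."""
        if self.mixture_weight is not None:
            mix = np.asarray(self.mixture_weight(np.asarray(times, dtype=float)), dtype=float)
            if np.any(mix < 0) or np.any(mix > 1):
                raise ValueError("mixture weight must lie in [0, 1] at every time point")
            return mix
        t = np.asarray(times, dtype=float)
        rise = (t - self.ensemble_onset_ms) / self.ensemble_ramp_ms
        fall = (self.ensemble_offset_ms - t) / self.ensemble_ramp_ms
        return np.clip(np.minimum(rise, fall), 0.0, 1.0)


def draw_participant_biases(config: SimulationConfig, rng=None) -> np.ndarray:
    """Per-participant perceptual bias (degrees), shared between the
    ensemble EEG task and the behavioral adjustment task."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    return rng.normal(0.0, config.participant_bias_sd, size=config.n_participants)


def _ar1_noise(rng, shape, sd, phi):
    """AR(1) noise along the last axis with stationary SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=shape)
    # Stationary start: give the first sample the full marginal SD.
    eps[..., 0] *= 1.0 / np.sqrt(1.0 - phi**2)
    return sps.lfilter([1.0], [1.0, -phi], eps, axis=-1)


def simulate_exp1(
    config: SimulationConfig,
    model: ForwardModel,
    rng=None,
    participant: int = 0,
) -> EpochsArray:
    """Simulate one participant's single-orientation EEG session.

    Each trial's noiseless signal is ``envelope(t) * W @ C(theta)`` for
    the trial's uniform orientation; AR(1) Gaussian noise is added per
    electrode.  Trial counts are exactly balanced across the six
    orientations and the trial order is randomized.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    times = config.times()
    env = config.envelope(times)
    orientations = np.repeat(EXP1_ORIENTATIONS, config.trials_per_orientation)
    rng.shuffle(orientations)
    n_trials = orientations.size
    m = model.weights.shape[0]

    signatures = {
        theta: config.signal_gain * (model.weights @ model.basis.response(theta))
        for theta in EXP1_ORIENTATIONS
    }
    data = np.empty((n_trials, m, times.size))
    for theta, sig in signatures.items():
        mask = orientations == theta
        data[mask] = sig[:, None] * env[None, :]
    data += _ar1_noise(
        rng, data.shape, config.noise_sd, config.noise_ar1_coefficient
    )

    trial_table = pd.DataFrame(
        {
            "orientation": orientations,
            "participant": participant,
            "keep": True,
        }
    )
    return EpochsArray(data, times, config.sampling_rate_hz, list(model.electrode_labels), trial_table)


def simulate_exp2a(
    config: SimulationConfig,
    model: ForwardModel,
    participant_biases: Sequence[float],
    rng=None,
    sets: Sequence[StimulusSet] | None = None,
) -> EpochsArray:
    """Simulate the ensemble-discrimination EEG session(s).

    The channel drive at time t is
    ``(1 - mix(t)) * mean_i C(component_i) + mix(t) * C(average + bias)``
    scaled by the signal envelope and mapped through the forward weights.
    One block of trials is generated per participant bias; trials carry
    the stimulus-set name and participant index.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if sets is None:
        sets = [s for s in builtin_stimulus_sets() if not s.is_dummy]
    else:
        registry = stimulus_sets_by_name()
        resolved = []
        for s in sets:
            if isinstance(s, StimulusSet):
                resolved.append(s)
            elif s in registry:
                resolved.append(registry[s])
            else:
                raise ValueError(f"unknown stimulus set name: {s!r}")
        sets = resolved
    times = config.times()
    env = config.envelope(times)
    mix = config.mixture(times)
    m = model.weights.shape[0]

    all_data, rows = [], []
    for p, bias in enumerate(participant_biases):
        set_names = np.repeat([s.name for s in sets], config.trials_per_set)
        rng.shuffle(set_names)
        data = np.empty((set_names.size, m, times.size))
        for s in sets:
            c_elem = model.basis.response(np.asarray(s.components)).mean(axis=1)
            c_ens = model.basis.response(wrap_orientation(s.average + bias))
            drive = np.outer(c_elem, (1.0 - mix)) + np.outer(c_ens, mix)
            sig = config.signal_gain * (model.weights @ drive) * env[None, :]
            data[set_names == s.name] = sig
        data += _ar1_noise(rng, data.shape, config.noise_sd, config.noise_ar1_coefficient)
        all_data.append(data)
        rows.append(
            pd.DataFrame({"set_name": set_names, "participant": p, "keep": True})
        )

    return EpochsArray(
        np.concatenate(all_data, axis=0),
        times,
        config.sampling_rate_hz,
        list(model.electrode_labels),
        pd.concat(rows, ignore_index=True),
    )


def simulate_exp2b(
    config: SimulationConfig,
    participant_biases: Sequence[float],
    rng=None,
) -> pd.DataFrame:
    """Simulate continuous reports of perceived average orientation.

    Each report is ``wrap(average + bias + N(0, report_noise_sd))``.
    Trials are flagged ``excluded`` when the set is a dummy or when the
    sign of the report disagrees with the sign of the true average (a
    report of exactly 0° never matches and is excluded).

    Returns a DataFrame with columns ``participant, set, trial,
    report_deg, excluded``.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    sets = builtin_stimulus_sets()
    rows = []
    for p, bias in enumerate(participant_biases):
        order = np.repeat(np.arange(len(sets)), config.trials_per_set_2b)
        rng.shuffle(order)
        noise = rng.normal(0.0, config.report_noise_sd, size=order.size)
        for trial, (si, eta) in enumerate(zip(order, noise)):
            s = sets[si]
            report = wrap_orientation(s.average + bias + eta)
            excluded = s.is_dummy or (np.sign(report) != np.sign(s.average))
            rows.append(
                {
                    "participant": p,
                    "set": s.name,
                    "trial": trial,
                    "report_deg": report,
                    "excluded": bool(excluded),
                }
            )
    return pd.DataFrame(rows)
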