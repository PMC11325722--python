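"""Inverted encoding model (IEM) for orientation representations.

The encoding model writes the window-mean EEG pattern as a linear
weighted sum of six hypothetical orientation-channel responses,
``B = W C``.  The weight matrix is estimated by least squares on the
single-orientation task,

    W_hat = B1 C1' (C1 C1')^-1,

and inverted on the ensemble task to recover channel responses,

    C2_hat = (W_hat' W_hat)^-1 W_hat' B2.

Cross-decoding runs this per sliding window inside the same balanced,
trial-averaged, 5-fold x 20-repetition scheme as the SVM analysis.
Estimated channel profiles are aligned on the channel tuned to each
set's average orientation; the OLS slope of the aligned profile against
the folded orientation offset is the *orientation sensitivity* (positive
slope = representation peaked at the set average).  Channel profiles can
also be read out as a continuous orientation by correlating them with
the basis prediction for each of 180 candidate orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochsArray
from .orientation import ChannelBasis, wrap_orientation
from .preprocessing import WindowSpec, sliding_windows
from .stimuli import StimulusSet, stimulus_sets_by_name

__all__ = [
    "IEMConfig",
    "ChannelResponseTimecourse",
    "SensitivityTimecourse",
    "CrossDecoder",
    "estimate_weights",
    "invert_channel_responses",
    "cross_decode_timecourse",
    "align_profile",
    "ALIGNED_OFFSETS",
    "orientation_sensitivity",
    "sensitivity_timecourse",
    "continuous_decode",
    "candidate_orientations",
    "decoded_deviation_timecourse",
]

#: Channel offsets (degrees from the set average) of an aligned profile,
#: in reporting order; the fourth position is the average itself.
ALIGNED_OFFSETS = (-90.0, -60.0, -30.0, 0.0, 30.0, 60.0)

_COND_NUMBER_LIMIT = 1e10


def estimate_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Least-squares estimate of the forward weights, ``m x k``.

    ``B1`` is electrodes x samples, ``C1`` channels x samples (one
    column per training sample).  Raises if ``C1 C1'`` is singular or
    ill-conditioned (training orientations must span the channel space).
    """
    B1 = np.asarray(B1, dtype=float)
    C1 = np.asarray(C1, dtype=float)
    gram = C1 @ C1.T
    if np.linalg.cond(gram) > _COND_NUMBER_LIMIT:
        raise np.linalg.LinAlgError(
            "C1 C1' is singular or ill-conditioned; training orientations do "
            "not span the channel space"
        )
    return np.linalg.solve(gram, C1 @ B1.T).T


def invert_channel_responses(W_hat: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Invert the encoding model: channel responses ``k x n`` from EEG.

    ``B2`` is electrodes x conditions.  Raises on rank-deficient
    ``W_hat``.
    """
    W_hat = np.asarray(W_hat, dtype=float)
    B2 = np.asarray(B2, dtype=float)
    gram = W_hat.T @ W_hat
    if np.linalg.cond(gram) > _COND_NUMBER_LIMIT:
        raise np.linalg.LinAlgError("estimated weight matrix is rank deficient")
    return np.linalg.solve(gram, W_hat.T @ B2)


@dataclass(frozen=True)
class IEMConfig:
    """Configuration of the cross-decoding IEM analysis."""

    n_cv_sets: int = 5
    n_repetitions: int = 20
    window: WindowSpec = field(default_factory=WindowSpec)
    zscore_range_ms: tuple[float, float] = (-300.0, 900.0)
    orientation_column: str = "orientation"
    set_column: str = "set_name"
    seed: int | None = 0

    def __post_init__(self):
        if self.n_cv_sets < 2:
            raise ValueError("need at least two cross-validation sets")


@dataclass
class ChannelResponseTimecourse:
    """Estimated channel responses per window and ensemble condition.

    ``responses`` has shape ``(n_windows, n_conditions, k)`` and is the
    average over all fold x repetition estimates (``n_estimates`` of
    them per window and condition).
    """

    window_centers: np.ndarray
    condition_names: list[str]
    basis: ChannelBasis
    responses: np.ndarray
    n_estimates: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, center in enumerate(self.window_centers):
            for ci, cond in enumerate(self.condition_names):
                for ki, ch in enumerate(self.basis.centers):
                    rows.append(
                        {
                            "window_center_ms": center,
                            "condition": cond,
                            "channel_center": ch,
                            "response": self.responses[w, ci, ki],
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class SensitivityTimecourse:
    """Orientation sensitivity (profile slope) per window and set type."""

    window_centers: np.ndarray
    slopes: dict[str, np.ndarray]
    profiles: dict[str, np.ndarray]  # set type -> (n_windows, 6) aligned

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for set_type, sl in self.slopes.items():
            for center, s in zip(self.window_centers, sl):
                rows.append(
                    {"window_center_ms": center, "set_type": set_type, "sensitivity": s}
                )
        return pd.DataFrame(rows)


class CrossDecoder:
    """Cross-decoding engine: fit weights on the single-orientation task,
    invert them on the ensemble task, per sliding window.

    Window-mean features are precomputed once at construction so that
    repeated runs (for example under label permutation in significance
    testing) only redo the cheap balancing, averaging and linear-algebra
    steps.
    """

    def __init__(
        self,
        exp1: EpochsArray,
        exp2a: EpochsArray,
        basis: ChannelBasis | None = None,
        cfg: IEMConfig | None = None,
    ):
        self.basis = basis or ChannelBasis()
        self.cfg = cfg or IEMConfig()
        if list(exp1.electrode_labels) != list(exp2a.electrode_labels):
            raise ValueError("the two experiments must share the electrode set")
        if not np.isclose(exp1.sampling_rate, exp2a.sampling_rate):
            raise ValueError("the two experiments must share the sampling rate")

        exp1 = exp1.kept()
        exp2a = exp2a.kept()
        self.windows = sliding_windows(exp1.times, self.cfg.window)
        windows2 = sliding_windows(exp2a.times, self.cfg.window)
        if not np.allclose(
            [w.center_ms for w in self.windows], [w.center_ms for w in windows2]
        ):
            raise ValueError("window layouts of the two experiments disagree")
        self.window_centers = np.array([w.center_ms for w in self.windows])

        self.labels1 = exp1.trial_table[self.cfg.orientation_column].to_numpy(dtype=float)
        # Per-trial window-mean features: (n_trials, m, n_windows).
        self._feat1 = np.stack(
            [exp1.data[:, :, w.sl].mean(axis=2) for w in self.windows], axis=-1
        )
        # Raw epochs over the z-scoring range, for training statistics.
        t0, t1 = self.cfg.zscore_range_ms
        zmask = (exp1.times >= t0 - 1e-9) & (exp1.times <= t1 + 1e-9)
        if not zmask.any():
            raise ValueError("z-scoring range lies outside the epoch")
        self._zdata1 = exp1.data[:, :, zmask]

        set_names = exp2a.trial_table[self.cfg.set_column].to_numpy()
        self.condition_names = [str(n) for n in pd.unique(set_names)]
        registry = stimulus_sets_by_name()
        self.condition_sets = {}
        for name in self.condition_names:
            if name not in registry:
                raise ValueError(f"unknown stimulus set name: {name!r}")
            self.condition_sets[name] = registry[name]
        # Per-condition mean window features: (n_conditions, m, n_windows).
        cond_feats = []
        for name in self.condition_names:
            mask = set_names == name
            mean_epoch = exp2a.data[mask].mean(axis=0)
            cond_feats.append(
                np.stack([mean_epoch[:, w.sl].mean(axis=1) for w in self.windows], -1)
            )
        self._B2 = np.stack(cond_feats)

    def channel_responses(self, rng=None, labels=None) -> ChannelResponseTimecourse:
        """Run the full cross-decoding analysis.

        ``labels`` optionally overrides the training-task orientation
        labels (used by permutation tests); ``rng`` overrides the seeded
        random stream for balancing and set assignment.
        """
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
        labels = self.labels1 if labels is None else np.asarray(labels, dtype=float)
        if labels.shape != self.labels1.shape:
            raise ValueError("label override must match the number of training trials")
        classes = np.unique(labels)
        n_windows = len(self.windows)
        n_cond = len(self.condition_names)
        k = self.basis.k
        total = np.zeros((n_windows, k, n_cond))
        n_min = min(np.sum(labels == c) for c in classes)
        if n_min < cfg.n_cv_sets:
            raise ValueError("not enough trials per orientation for the CV sets")
        g = n_min // cfg.n_cv_sets

        n_estimates = 0
        for rep in range(cfg.n_repetitions):
            # Undersample to the minimum class count, then partition each
            # class into n_cv_sets groups of g trials (remainder dropped).
            groups = np.empty((len(classes), cfg.n_cv_sets, g), dtype=int)
            for ci, c in enumerate(classes):
                idx = np.flatnonzero(labels == c)
                idx = rng.choice(idx, size=n_min, replace=False)
                groups[ci] = rng.permutation(idx)[: cfg.n_cv_sets * g].reshape(
                    cfg.n_cv_sets, g
                )
            # Pseudo-trial features and z-range epochs: class-major order.
            pseudo_feat = self._feat1[groups].mean(axis=2)  # (nc, n_sets, m, nW)
            pseudo_z = self._zdata1[groups].mean(axis=2)  # (nc, n_sets, m, Tz)
            for fold in range(cfg.n_cv_sets):
                sel = [s for s in range(cfg.n_cv_sets) if s != fold]
                train_feat = pseudo_feat[:, sel].reshape(-1, *pseudo_feat.shape[2:])
                train_z = pseudo_z[:, sel].reshape(-1, *pseudo_z.shape[2:])
                train_orient = np.repeat(classes, len(sel))
                mu = train_z.mean(axis=(0, 2))
                sd = train_z.std(axis=(0, 2))
                if np.any(sd == 0):
                    raise ValueError("zero training standard deviation on an electrode")
                # (nW, m, n_train)
                B1 = np.transpose(
                    (train_feat - mu[None, :, None]) / sd[None, :, None], (2, 1, 0)
                )
                B2 = np.transpose(
                    (self._B2 - mu[None, :, None]) / sd[None, :, None], (2, 1, 0)
                )
                C1 = self.basis.response(train_orient)  # (k, n_train)
                # Batched equivalents of estimate_weights /
                # invert_channel_responses across windows (same algebra;
                # equivalence is covered by the unit tests).
                gram1 = C1 @ C1.T
                if np.linalg.cond(gram1) > _COND_NUMBER_LIMIT:
                    raise np.linalg.LinAlgError(
                        "C1 C1' is singular; training orientations do not "
                        "span the channel space"
                    )
                proj = np.linalg.solve(gram1, C1).T  # (n_train, k)
                W_hat = B1 @ proj  # (nW, m, k)
                gram2 = np.einsum("wmk,wml->wkl", W_hat, W_hat)
                rhs = np.einsum("wmk,wmc->wkc", W_hat, B2)
                try:
                    total += np.linalg.solve(gram2, rhs)
                except np.linalg.LinAlgError as exc:  # pragma: no cover
                    raise np.linalg.LinAlgError(
                        "estimated weight matrix is rank deficient"
                    ) from exc
                n_estimates += 1

        responses = np.transpose(total / n_estimates, (0, 2, 1))
        return ChannelResponseTimecourse(
            self.window_centers,
            list(self.condition_names),
            self.basis,
            responses,
            n_estimates,
        )


def cross_decode_timecourse(
    exp1: EpochsArray,
    exp2a: EpochsArray,
    basis: ChannelBasis | None = None,
    cfg: IEMConfig | None = None,
) -> ChannelResponseTimecourse:
    """Estimate channel-response timecourses for the ensemble task by
    cross-decoding from the single-orientation task (convenience wrapper
    around :class:`CrossDecoder`)."""
    return CrossDecoder(exp1, exp2a, basis, cfg).channel_responses()


def align_profile(c_hat, set_average: float, basis: ChannelBasis) -> np.ndarray:
    """Reorder a channel-response vector by offset from the set average.

    The returned profile is ordered by wrapped offset ``center -
    average`` as ``(-90, -60, -30, 0, +30, +60)``; the fourth entry is
    the channel tuned to the average orientation.  The set average must
    coincide with one of the channel centers.
    """
    c_hat = np.asarray(c_hat, dtype=float)
    if c_hat.shape[-1] != basis.k:
        raise ValueError("profile length must equal the basis size")
    # Offsets live in [-90, 90) so that the +90 == -90 channel lands on
    # the -90 slot of the reporting order.
    offsets = np.mod(np.asarray(basis.centers) - set_average + 90.0, 180.0) - 90.0
    order = []
    for target in ALIGNED_OFFSETS:
        hits = np.flatnonzero(np.isclose(offsets, target))
        if hits.size != 1:
            raise ValueError(
                "set average must coincide with a channel center and the "
                "channel grid must cover offsets -90..60 in 30-degree steps"
            )
        order.append(hits[0])
    return c_hat[..., order]


_SENS_X = np.array([-90.0, -60.0, -60.0, -30.0, -30.0, 0.0])


def orientation_sensitivity(profile) -> float:
    """OLS slope of an aligned profile against folded orientation offset.

    The six aligned responses are folded across the sign of the offset:
    y = (p(-90), p(-60), p(+60), p(-30), p(+30), p(0)) is regressed on
    x = (-90, -60, -60, -30, -30, 0).  Units: response per degree.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape[-1] != 6 or not np.all(np.isfinite(p)):
        raise ValueError("profile must be six finite aligned responses")
    y = p[..., [0, 1, 5, 2, 4, 3]]
    x = _SENS_X - _SENS_X.mean()
    return (y * x).sum(axis=-1) / (x**2).sum()


def sensitivity_timecourse(
    tc: ChannelResponseTimecourse,
    condition_sets: dict[str, StimulusSet] | None = None,
) -> SensitivityTimecourse:
    """Aligned profiles and sensitivity per window, split by set type.

    Profiles of the two conditions sharing a set type ("w" or "w/o")
    are aligned on their own average orientation and then averaged, so
    +45° and -45° conditions fold onto a common axis.
    """
    if condition_sets is None:
        registry = stimulus_sets_by_name()
        condition_sets = {name: registry[name] for name in tc.condition_names}
    by_type: dict[str, list[np.ndarray]] = {}
    for ci, name in enumerate(tc.condition_names):
        s = condition_sets[name]
        aligned = align_profile(tc.responses[:, ci, :], s.average, tc.basis)
        by_type.setdefault(s.set_type, []).append(aligned)
    profiles = {t: np.mean(v, axis=0) for t, v in by_type.items()}
    slopes = {t: orientation_sensitivity(p) for t, p in profiles.items()}
    return SensitivityTimecourse(tc.window_centers, slopes, profiles)


def candidate_orientations() -> np.ndarray:
    """The 180 integer-degree candidates (-89°…90°) for continuous decoding."""
    return np.arange(-89.0, 91.0)


def continuous_decode(
    c_hat,
    basis: ChannelBasis,
    true_average_sign: float,
    true_average: float | None = None,
) -> float:
    """Decode a continuous orientation from a channel-response vector.

    The basis prediction is computed for each of the 180 integer-degree
    candidates; the decoded orientation is the candidate with the
    highest Pearson correlation to ``c_hat`` among those whose sign
    matches ``true_average_sign`` (0° is excluded; +90° counts as
    positive).  Correlation ties are broken toward the candidate closest
    to ``true_average`` (default ``sign * 45``).
    """
    c_hat = np.asarray(c_hat, dtype=float)
    if np.ptp(c_hat) == 0:
        raise ValueError("channel responses are constant; correlation is undefined")
    sign = np.sign(true_average_sign)
    if sign == 0:
        raise ValueError("true_average_sign must be nonzero")
    if true_average is None:
        true_average = 45.0 * sign
    grid = candidate_orientations()
    allowed = grid[np.sign(grid) == sign]
    pred = basis.response(allowed)  # (k, n_candidates)
    pz = pred - pred.mean(axis=0)
    cz = c_hat - c_hat.mean()
    denom = np.linalg.norm(pz, axis=0) * np.linalg.norm(cz)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pz.T @ cz) / denom
    r[~np.isfinite(r)] = -np.inf
    best = np.flatnonzero(r >= r.max() - 1e-12)
    winner = best[np.argmin(np.abs(allowed[best] - true_average))]
    return float(allowed[winner])


def decoded_deviation_timecourse(
    tc: ChannelResponseTimecourse,
    condition_sets: dict[str, StimulusSet] | None = None,
) -> pd.DataFrame:
    """Continuously decoded orientation deviation per window and set type.

    For each condition the channel profile is decoded to a continuous
    orientation and the true set average is subtracted, collapsing the
    +45° and -45° conditions onto a common deviation axis (a clockwise
    bias is positive for both); the two conditions of each set type are
    then averaged.

    Returns a tidy DataFrame with columns ``window_center_ms, set_type,
    decoded_deviation_deg``.
    """
    if condition_sets is None:
        registry = stimulus_sets_by_name()
        condition_sets = {name: registry[name] for name in tc.condition_names}
    rows = []
    for w, center in enumerate(tc.window_centers):
        devs: dict[str, list[float]] = {}
        for ci, name in enumerate(tc.condition_names):
            s = condition_sets[name]
            sign = np.sign(s.average)
            decoded = continuous_decode(
                tc.responses[w, ci], tc.basis, sign, true_average=s.average
            )
            dev = wrap_orientation(decoded - s.average)
            devs.setdefault(s.set_type, []).append(dev)
        for set_type, v in devs.items():
            rows.append(
                {
                    "window_center_ms": center,
                    "set_type": set_type,
                    "decoded_deviation_deg": float(np.mean(v)),
                }
            )
    return pd.DataFrame(rows)
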