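"""Cluster-based permutation inference and the brain–behavior analysis.

Pointwise p-values use the add-one permutation rule, p = (1 + #{null >=
observed}) / (n_perm + 1), one-tailed upper (the hypotheses — above-
chance accuracy, positive sensitivity, positive correlation — are
directional).  Clusters are maximal runs of consecutive windows with
pointwise p below the cluster-defining threshold; their sizes are
compared against the permutation distribution of the *maximum* cluster
size, which controls the family-wise error rate over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochsArray
from .iem import (
    CrossDecoder,
    IEMConfig,
    decoded_deviation_timecourse,
    sensitivity_timecourse,
)
from .orientation import ChannelBasis, wrap_orientation
from .stimuli import stimulus_sets_by_name

__all__ = [
    "PermutationNull",
    "Cluster",
    "ClusterTestResult",
    "CorrelationTimecourse",
    "pointwise_pvalues",
    "cluster_permutation_test",
    "decoding_null",
    "sensitivity_null",
    "group_sensitivity_null",
    "perceived_deviations",
    "behavior_correlation_timecourse",
    "correlation_null",
]


@dataclass
class PermutationNull:
    """Null statistic values per window: shape ``(n_perm, n_windows)``."""

    window_centers: np.ndarray
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.window_centers.size:
            raise ValueError("null values must be (n_perm, n_windows)")

    @property
    def n_perm(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    size: int
    p_value: float


@dataclass
class ClusterTestResult:
    """Observed clusters with permutation p-values.

    ``clusters`` lists every suprathreshold run; ``significant_clusters``
    those whose size-level p-value beats ``cluster_threshold``.
    """

    clusters: list[Cluster]
    cluster_alpha: float
    cluster_threshold: float
    pointwise_p: np.ndarray
    window_centers: np.ndarray
    null_max_cluster_sizes: np.ndarray

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.cluster_threshold]

    def to_dict(self) -> dict:
        return {
            "cluster_alpha": self.cluster_alpha,
            "cluster_threshold": self.cluster_threshold,
            "clusters": [
                {
                    "start_ms": c.start_ms,
                    "end_ms": c.end_ms,
                    "size": c.size,
                    "p_value": c.p_value,
                    "significant": c.p_value < self.cluster_threshold,
                }
                for c in self.clusters
            ],
        }


def pointwise_pvalues(observed, null: PermutationNull) -> np.ndarray:
    """One-tailed (upper) add-one permutation p-value per window."""
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (null.values.shape[1],):
        raise ValueError("observed timecourse and null windows disagree")
    exceed = (null.values >= observed[None, :]).sum(axis=0)
    return (1.0 + exceed) / (null.n_perm + 1.0)


def _clusters_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    runs = []
    in_run = False
    for i, flag in enumerate(mask):
        if flag and not in_run:
            start, in_run = i, True
        elif not flag and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    return runs


def cluster_permutation_test(
    observed,
    null: PermutationNull,
    cluster_alpha: float = 0.05,
    cluster_threshold: float = 0.05,
) -> ClusterTestResult:
    """Cluster-based permutation test over a statistic timecourse.

    Observed clusters are maximal runs of windows with pointwise p <
    ``cluster_alpha``.  The null distribution of cluster size is built
    by applying the same pointwise rule within the null: each
    permutation's statistic is ranked against the full null per window,
    its clusters are formed, and its maximum cluster size recorded.  A
    cluster is significant when its add-one size-level p-value is below
    ``cluster_threshold``.
    """
    observed = np.asarray(observed, dtype=float)
    p_obs = pointwise_pvalues(observed, null)

    # Rank every permutation within the null, per window (self included,
    # so the null pointwise p is at least 1/n_perm).
    n_perm = null.n_perm
    p_null = np.empty_like(null.values)
    for w in range(null.values.shape[1]):
        col = null.values[:, w]
        srt = np.sort(col)
        ge = n_perm - np.searchsorted(srt, col, side="left")
        p_null[:, w] = ge / n_perm

    max_sizes = np.zeros(n_perm)
    for i in range(n_perm):
        runs = _clusters_from_mask(p_null[i] < cluster_alpha)
        if runs:
            max_sizes[i] = max(stop - start for start, stop in runs)

    clusters = []
    for start, stop in _clusters_from_mask(p_obs < cluster_alpha):
        size = stop - start
        p_cluster = (1.0 + np.sum(max_sizes >= size)) / (n_perm + 1.0)
        clusters.append(
            Cluster(
                start_ms=float(null.window_centers[start]),
                end_ms=float(null.window_centers[stop - 1]),
                size=size,
                p_value=float(p_cluster),
            )
        )
    return ClusterTestResult(
        clusters,
        cluster_alpha,
        cluster_threshold,
        p_obs,
        null.window_centers,
        max_sizes,
    )


def decoding_null(
    epochs_list: list[EpochsArray],
    cfg,
    n_perm: int = 100,
    seed: int | None = 0,
) -> PermutationNull:
    """Permutation null of the group-mean decoding-accuracy timecourse.

    For every permutation, each participant's orientation labels are
    shuffled and the full sliding-window decoding analysis is rerun; the
    statistic is the mean accuracy across participants.  ``cfg`` is a
    :class:`oriens.svm.DecoderConfig`.
    """
    from .svm import decode_timecourse

    rng = np.random.default_rng(seed)
    values = []
    centers = None
    for _ in range(n_perm):
        accs = []
        for e in epochs_list:
            shuffled = e.kept().copy()
            labels = shuffled.trial_table[cfg.label_column].to_numpy()
            shuffled.trial_table[cfg.label_column] = rng.permutation(labels)
            tc = decode_timecourse(shuffled, cfg)
            accs.append(tc.accuracy)
            centers = tc.window_centers
        values.append(np.mean(accs, axis=0))
    return PermutationNull(centers, np.vstack(values), seed=seed)


def sensitivity_null(
    exp1: EpochsArray,
    exp2a: EpochsArray,
    basis: ChannelBasis | None = None,
    cfg: IEMConfig | None = None,
    n_perm: int = 100,
    seed: int | None = 0,
    decoder: CrossDecoder | None = None,
) -> dict[str, PermutationNull]:
    """Permutation null of orientation sensitivity, per set type.

    For every permutation the training-task orientation labels are
    shuffled and the full cross-decoding plus sensitivity computation is
    rerun; the statistic distribution is returned per set type.
    """
    if decoder is None:
        decoder = CrossDecoder(exp1, exp2a, basis, cfg)
    rng = np.random.default_rng(seed)
    values: dict[str, list[np.ndarray]] = {}
    for _ in range(n_perm):
        perm_labels = rng.permutation(decoder.labels1)
        tc = decoder.channel_responses(rng=rng, labels=perm_labels)
        sens = sensitivity_timecourse(tc)
        for set_type, sl in sens.slopes.items():
            values.setdefault(set_type, []).append(sl)
    return {
        t: PermutationNull(decoder.window_centers, np.vstack(v), seed=seed)
        for t, v in values.items()
    }


def group_sensitivity_null(
    decoders: list[CrossDecoder],
    n_perm: int = 100,
    seed: int | None = 0,
) -> dict[str, PermutationNull]:
    """Permutation null of the across-participant mean sensitivity.

    Each permutation shuffles every participant's training labels,
    reruns cross-decoding and averages the sensitivity timecourses over
    participants.
    """
    rng = np.random.default_rng(seed)
    values: dict[str, list[np.ndarray]] = {}
    for _ in range(n_perm):
        per_type: dict[str, list[np.ndarray]] = {}
        for dec in decoders:
            perm_labels = rng.permutation(dec.labels1)
            tc = dec.channel_responses(rng=rng, labels=perm_labels)
            for set_type, sl in sensitivity_timecourse(tc).slopes.items():
                per_type.setdefault(set_type, []).append(sl)
        for set_type, sls in per_type.items():
            values.setdefault(set_type, []).append(np.mean(sls, axis=0))
    centers = decoders[0].window_centers
    return {
        t: PermutationNull(centers, np.vstack(v), seed=seed) for t, v in values.items()
    }


def perceived_deviations(reports: pd.DataFrame) -> pd.DataFrame:
    """Per-participant perceived deviation from the true average, by set
    type.

    Non-excluded reports are reduced to ``wrap(report - average)`` (the
    true average is subtracted, so +45° and -45° sets fold onto a common
    deviation axis) and averaged per participant and set type.  Returns
    columns ``participant, set_type, perceived_deviation_deg``.
    """
    registry = stimulus_sets_by_name()
    rows = []
    kept = reports[~reports["excluded"].astype(bool)]
    for (participant, set_name), grp in kept.groupby(["participant", "set"]):
        s = registry[str(set_name)]
        dev = wrap_orientation(grp["report_deg"].to_numpy() - s.average)
        rows.append(
            {
                "participant": participant,
                "set_type": s.set_type,
                "deviation": dev.mean(),
                "n": len(grp),
            }
        )
    per_set = pd.DataFrame(rows)
    per_set["weighted"] = per_set["deviation"] * per_set["n"]
    agg = per_set.groupby(["participant", "set_type"], as_index=False)[["weighted", "n"]].sum()
    agg["perceived_deviation_deg"] = agg["weighted"] / agg["n"]
    return agg[["participant", "set_type", "perceived_deviation_deg"]]


@dataclass
class CorrelationTimecourse:
    """Pearson r across participants per window and set type.

    Windows where either variable has zero variance are flagged
    ``undefined`` and carry NaN rather than raising.
    """

    window_centers: np.ndarray
    r: dict[str, np.ndarray]
    undefined: dict[str, np.ndarray]
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for set_type, rr in self.r.items():
            for center, val, und in zip(
                self.window_centers, rr, self.undefined[set_type]
            ):
                rows.append(
                    {
                        "window_center_ms": center,
                        "set_type": set_type,
                        "r": val,
                        "undefined": bool(und),
                    }
                )
        return pd.DataFrame(rows)


def _pearson_over_participants(decoded_matrix: np.ndarray, perceived: np.ndarray):
    """r per window between (participants x windows) and (participants,)."""
    x = decoded_matrix - decoded_matrix.mean(axis=0, keepdims=True)
    y = perceived - perceived.mean()
    num = x.T @ y
    denom = np.sqrt((x**2).sum(axis=0) * (y**2).sum())
    undefined = denom == 0
    r = np.full(decoded_matrix.shape[1], np.nan)
    r[~undefined] = num[~undefined] / denom[~undefined]
    return r, undefined


def behavior_correlation_timecourse(
    decoded: pd.DataFrame,
    reports_or_perceived: pd.DataFrame,
) -> CorrelationTimecourse:
    """Correlate decoded and perceived average-orientation deviations.

    ``decoded`` is tidy with columns ``participant, set_type,
    window_center_ms, decoded_deviation_deg`` (per-participant output of
    :func:`oriens.iem.decoded_deviation_timecourse`).  The second
    argument is either raw behavioral reports (with an ``excluded``
    column) or the output of :func:`perceived_deviations`.

    Requires at least three participants.
    """
    if "perceived_deviation_deg" in reports_or_perceived.columns:
        perceived = reports_or_perceived
    else:
        perceived = perceived_deviations(reports_or_perceived)

    set_types = sorted(decoded["set_type"].unique())
    centers = np.sort(decoded["window_center_ms"].unique())
    r: dict[str, np.ndarray] = {}
    undefined: dict[str, np.ndarray] = {}
    n_participants = None
    for set_type in set_types:
        d = decoded[decoded["set_type"] == set_type].pivot_table(
            index="participant", columns="window_center_ms", values="decoded_deviation_deg"
        )
        p = perceived[perceived["set_type"] == set_type].set_index("participant")[
            "perceived_deviation_deg"
        ]
        common = d.index.intersection(p.index)
        if len(common) < 3:
            raise ValueError("need at least three participants with usable reports")
        n_participants = len(common)
        r[set_type], undefined[set_type] = _pearson_over_participants(
            d.loc[common, centers].to_numpy(), p.loc[common].to_numpy()
        )
    return CorrelationTimecourse(centers, r, undefined, n_participants)


def correlation_null(
    decoders: list[CrossDecoder],
    reports_or_perceived: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = 0,
) -> dict[str, PermutationNull]:
    """Permutation null of the brain–behavior correlation timecourse.

    For each permutation, every participant's training-task orientation
    labels are shuffled, the inverted encoding model is refit, the
    continuous orientation is re-decoded per window, and the
    across-participant correlation with the (fixed) perceived deviations
    is recomputed.
    """
    if "perceived_deviation_deg" in reports_or_perceived.columns:
        perceived = reports_or_perceived
    else:
        perceived = perceived_deviations(reports_or_perceived)
    rng = np.random.default_rng(seed)
    values: dict[str, list[np.ndarray]] = {}
    for _ in range(n_perm):
        frames = []
        for pi, dec in enumerate(decoders):
            perm_labels = rng.permutation(dec.labels1)
            tc = dec.channel_responses(rng=rng, labels=perm_labels)
            devs = decoded_deviation_timecourse(tc)
            devs["participant"] = pi
            frames.append(devs)
        decoded = pd.concat(frames, ignore_index=True)
        corr = behavior_correlation_timecourse(decoded, perceived)
        for set_type, rr in corr.r.items():
            values.setdefault(set_type, []).append(np.nan_to_num(rr, nan=0.0))
    centers = decoders[0].window_centers
    return {
        t: PermutationNull(centers, np.vstack(v), seed=seed) for t, v in values.items()
    }
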