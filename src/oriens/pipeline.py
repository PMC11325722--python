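"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes the five stages — simulate, preprocess,
decode, iem, stats — writing CSV/JSON artifacts and a manifest (config
hash, per-stage timings, file checksums) to the output directory.  A
single global seed is expanded into independent per-stage streams, so
e.g. changing the number of permutations never perturbs the simulation
draws.  ``summarize_run`` turns a manifest into a human-readable report
comparing recovered clusters with the generator's planted ensemble
window.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import OCCIPITO_PARIETAL_ELECTRODES
from .iem import CrossDecoder, IEMConfig, decoded_deviation_timecourse, sensitivity_timecourse
from .orientation import ChannelBasis
from .preprocessing import preprocess_epochs, select_electrodes
from .simulate import (
    SimulationConfig,
    draw_participant_biases,
    make_forward_model,
    simulate_exp1,
    simulate_exp2a,
    simulate_exp2b,
)
from .stats import (
    behavior_correlation_timecourse,
    cluster_permutation_test,
    correlation_null,
    decoding_null,
    group_sensitivity_null,
    perceived_deviations,
)
from .svm import DecoderConfig, decode_timecourse

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "summarize_run"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Full configuration of the synthetic end-to-end study."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    iem: IEMConfig = field(default_factory=IEMConfig)
    band_hz: tuple[float, float] = (1.0, 80.0)
    target_rate_hz: float = 500.0
    baseline_ms: tuple[float, float] = (-300.0, 0.0)
    electrodes: tuple[str, ...] = tuple(OCCIPITO_PARIETAL_ELECTRODES)
    decode_both_classifiers: bool = True
    n_perm_decoding: int = 1000
    n_perm_sensitivity: int = 1000
    n_perm_correlation: int = 1000
    cluster_alpha: float = 0.05
    cluster_threshold: float = 0.05
    correlation_cluster_alpha: float = 0.1
    correlation_cluster_threshold: float = 0.1
    outdir: str = "oriens_run"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _write_json(obj, path: Path) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate → preprocess → decode → iem → stats and return the
    manifest (also written to ``<outdir>/manifest.json``).

    Every result file is deterministic for a fixed config and seed.
    """
    outdir = Path(cfg.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("ok")
        probe.unlink()
    except OSError as exc:
        raise PipelineError(f"output directory not writable: {outdir} ({exc})") from exc

    # One global seed, expanded into independent per-stage streams.
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["simulate", "decode", "iem", "stats"], ss.spawn(4)
        )
    }

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": [],
    }
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("decode", _stage_decode),
        ("iem", _stage_iem),
        ("stats", _stage_stats),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            outputs = fn(cfg, state, seeds, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": name,
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": [
                    {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                    for p in outputs
                ],
            }
        )

    _write_json(manifest, outdir / "manifest.json")
    return manifest


# --------------------------------------------------------------- stages


def _stage_simulate(cfg, state, seeds, outdir):
    rng = seeds["simulate"]
    sim = cfg.sim
    biases = draw_participant_biases(sim, rng)
    exp1, exp2a = [], []
    for p in range(sim.n_participants):
        model = make_forward_model(
            m=len(cfg.electrodes), seed=rng, electrode_labels=list(cfg.electrodes)
        )
        exp1.append(simulate_exp1(sim, model, rng=rng, participant=p))
        exp2a.append(simulate_exp2a(sim, model, [biases[p]], rng=rng))
    reports = simulate_exp2b(sim, biases, rng=rng)
    state.update(exp1=exp1, exp2a=exp2a, reports=reports, biases=biases)
    out = [
        _write_csv(reports, outdir / "behavior_reports.csv"),
        _write_json(
            {
                "n_participants": sim.n_participants,
                "participant_biases_deg": list(np.round(biases, 6)),
                "planted_ensemble_window_ms": [
                    sim.ensemble_onset_ms,
                    sim.ensemble_offset_ms,
                ],
                "signal_window_ms": [sim.signal_onset_ms, sim.signal_offset_ms],
            },
            outdir / "simulation_ground_truth.json",
        ),
    ]
    return out


def _stage_preprocess(cfg, state, seeds, outdir):
    def prep(e):
        e = preprocess_epochs(e, cfg.band_hz, cfg.target_rate_hz, cfg.baseline_ms)
        return select_electrodes(e, list(cfg.electrodes))

    state["exp1"] = [prep(e) for e in state["exp1"]]
    state["exp2a"] = [prep(e) for e in state["exp2a"]]
    meta = {
        "band_hz": list(cfg.band_hz),
        "target_rate_hz": cfg.target_rate_hz,
        "baseline_ms": list(cfg.baseline_ms),
        "electrodes": list(cfg.electrodes),
        "n_trials_exp1": [e.n_trials for e in state["exp1"]],
        "n_trials_exp2a": [e.n_trials for e in state["exp2a"]],
    }
    return [_write_json(meta, outdir / "preprocessing.json")]


def _stage_decode(cfg, state, seeds, outdir):
    rng = seeds["decode"]
    class_sets = [tuple(sorted(cfg.decoder.classes))]
    if cfg.decode_both_classifiers:
        mirrored = tuple(sorted(-c for c in cfg.decoder.classes))
        if mirrored != class_sets[0]:
            class_sets.append(mirrored)
    rows = []
    group = {}
    for classes in class_sets:
        per_participant = []
        for p, e in enumerate(state["exp1"]):
            dcfg = dataclasses.replace(
                cfg.decoder, classes=classes, seed=int(rng.integers(2**31))
            )
            tc = decode_timecourse(e, dcfg)
            per_participant.append(tc.accuracy)
            for c, a in zip(tc.window_centers, tc.accuracy):
                rows.append(
                    {
                        "window_center_ms": c,
                        "participant": p,
                        "classifier": str(classes),
                        "accuracy": a,
                    }
                )
        group[classes] = np.mean(per_participant, axis=0)
        state["decode_centers"] = tc.window_centers
    state["accuracy_group"] = np.mean(list(group.values()), axis=0)
    state["accuracy_rows"] = rows
    df = pd.DataFrame(rows)
    mean_df = pd.DataFrame(
        {
            "window_center_ms": state["decode_centers"],
            "accuracy": state["accuracy_group"],
        }
    )
    return [
        _write_csv(df, outdir / "accuracy_per_participant.csv"),
        _write_csv(mean_df, outdir / "accuracy_group_mean.csv"),
    ]


def _stage_iem(cfg, state, seeds, outdir):
    rng = seeds["iem"]
    decoders, sens, devs, resp = [], {}, [], []
    for p, (e1, e2) in enumerate(zip(state["exp1"], state["exp2a"])):
        icfg = dataclasses.replace(cfg.iem, seed=int(rng.integers(2**31)))
        dec = CrossDecoder(e1, e2, ChannelBasis(), icfg)
        decoders.append(dec)
        tc = dec.channel_responses()
        resp.append(tc.responses)
        st = sensitivity_timecourse(tc)
        for set_type, sl in st.slopes.items():
            sens.setdefault(set_type, []).append(sl)
        d = decoded_deviation_timecourse(tc)
        d["participant"] = p
        devs.append(d)
    state["iem_decoders"] = decoders
    state["iem_centers"] = decoders[0].window_centers
    state["sensitivity_group"] = {t: np.mean(v, axis=0) for t, v in sens.items()}
    state["decoded_devs"] = pd.concat(devs, ignore_index=True)

    mean_resp = np.mean(resp, axis=0)
    tc0 = decoders[0]
    resp_rows = []
    for w, center in enumerate(state["iem_centers"]):
        for ci, cond in enumerate(tc0.condition_names):
            for ki, ch in enumerate(ChannelBasis().centers):
                resp_rows.append(
                    {
                        "window_center_ms": center,
                        "condition": cond,
                        "channel_center": ch,
                        "response": mean_resp[w, ci, ki],
                    }
                )
    sens_rows = [
        {"window_center_ms": c, "set_type": t, "sensitivity": s}
        for t, sl in state["sensitivity_group"].items()
        for c, s in zip(state["iem_centers"], sl)
    ]
    return [
        _write_csv(pd.DataFrame(resp_rows), outdir / "channel_responses_group.csv"),
        _write_csv(pd.DataFrame(sens_rows), outdir / "sensitivity_group.csv"),
        _write_csv(state["decoded_devs"], outdir / "decoded_orientations.csv"),
    ]


def _stage_stats(cfg, state, seeds, outdir):
    rng = seeds["stats"]
    results = {}
    outputs = []

    # Decoding accuracy vs. label-permutation null.
    if cfg.n_perm_decoding > 0:
        null = decoding_null(
            state["exp1"], cfg.decoder, cfg.n_perm_decoding, seed=rng
        )
        test = cluster_permutation_test(
            state["accuracy_group"], null, cfg.cluster_alpha, cfg.cluster_threshold
        )
        results["decoding_accuracy"] = test.to_dict()
        outputs.append(
            _write_csv(
                pd.DataFrame(
                    {
                        "window_center_ms": state["decode_centers"],
                        "accuracy": state["accuracy_group"],
                        "pointwise_p": test.pointwise_p,
                    }
                ),
                outdir / "decoding_pvalues.csv",
            )
        )

    # Orientation sensitivity vs. permutation null, per set type.
    if cfg.n_perm_sensitivity > 0:
        nulls = group_sensitivity_null(
            state["iem_decoders"], cfg.n_perm_sensitivity, seed=rng
        )
        sens_results = {}
        rows = []
        for set_type, null in nulls.items():
            test = cluster_permutation_test(
                state["sensitivity_group"][set_type],
                null,
                cfg.cluster_alpha,
                cfg.cluster_threshold,
            )
            sens_results[set_type] = test.to_dict()
            for c, s, p in zip(
                state["iem_centers"],
                state["sensitivity_group"][set_type],
                test.pointwise_p,
            ):
                rows.append(
                    {
                        "window_center_ms": c,
                        "set_type": set_type,
                        "sensitivity": s,
                        "pointwise_p": p,
                    }
                )
        results["sensitivity"] = sens_results
        outputs.append(
            _write_csv(pd.DataFrame(rows), outdir / "sensitivity_pvalues.csv")
        )

    # Brain–behavior correlation vs. permutation null, per set type.
    if cfg.n_perm_correlation > 0:
        perceived = perceived_deviations(state["reports"])
        corr = behavior_correlation_timecourse(state["decoded_devs"], perceived)
        nulls = correlation_null(
            state["iem_decoders"], perceived, cfg.n_perm_correlation, seed=rng
        )
        corr_results = {}
        rows = []
        for set_type, null in nulls.items():
            observed = np.nan_to_num(corr.r[set_type], nan=0.0)
            test = cluster_permutation_test(
                observed,
                null,
                cfg.correlation_cluster_alpha,
                cfg.correlation_cluster_threshold,
            )
            corr_results[set_type] = test.to_dict()
            for c, r, p in zip(corr.window_centers, corr.r[set_type], test.pointwise_p):
                rows.append(
                    {
                        "window_center_ms": c,
                        "set_type": set_type,
                        "r": r,
                        "pointwise_p": p,
                    }
                )
        results["correlation"] = corr_results
        outputs.append(
            _write_csv(pd.DataFrame(rows), outdir / "correlation_pvalues.csv")
        )

    outputs.append(_write_json(results, outdir / "cluster_results.json"))
    state["stats_results"] = results
    return outputs


# -------------------------------------------------------------- report


def summarize_run(manifest_or_path) -> str:
    """Human-readable summary of a pipeline run.

    Reads the cluster results and simulation ground truth written by the
    run and reports, per analysis, the significant clusters and how they
    relate to the planted ensemble window.  Regeneration from the same
    manifest is idempotent.
    """
    if isinstance(manifest_or_path, (str, Path)):
        path = Path(manifest_or_path)
        if path.is_dir():
            path = path / "manifest.json"
        with open(path, "r", encoding="utf-8") as fh:
            manifest = json.load(fh)
        outdir = path.parent
    else:
        manifest = manifest_or_path
        outdir = Path(manifest["config"]["outdir"])

    lines = [
        "oriens pipeline run summary",
        f"  config hash : {manifest['config_hash']}",
        f"  seed        : {manifest['seed']}",
        "  stages      : "
        + ", ".join(
            f"{s['name']} ({s['seconds']}s)" for s in manifest["stages"]
        ),
    ]
    complete = {s["name"] for s in manifest["stages"]}
    expected = {"simulate", "preprocess", "decode", "iem", "stats"}
    if not expected.issubset(complete):
        lines.append(
            "  WARNING: incomplete run, missing stages: "
            + ", ".join(sorted(expected - complete))
        )

    gt_path = outdir / "simulation_ground_truth.json"
    planted = signal = None
    if gt_path.exists():
        with open(gt_path) as fh:
            gt = json.load(fh)
        planted = gt["planted_ensemble_window_ms"]
        signal = gt.get("signal_window_ms")
        lines.append(
            f"  planted ensemble window: {planted[0]:.0f}-{planted[1]:.0f} ms"
        )

    res_path = outdir / "cluster_results.json"
    if not res_path.exists():
        lines.append("  no statistics results found (no significant clusters reported)")
        return "\n".join(lines)
    with open(res_path) as fh:
        results = json.load(fh)

    def describe(name, block, reference, ref_label):
        if block is None:
            return [f"  {name}: not computed"]
        sub = []
        if "clusters" in block:
            block = {"": block}
        for set_type, test in block.items():
            label = f"{name}{' [' + set_type + ']' if set_type else ''}"
            sig = [c for c in test["clusters"] if c["significant"]]
            if not sig:
                sub.append(f"  {label}: no significant clusters")
                continue
            for c in sig:
                span = f"{c['start_ms']:.0f}-{c['end_ms']:.0f} ms"
                note = ""
                if reference is not None:
                    overlaps = c["end_ms"] >= reference[0] and c["start_ms"] <= reference[1]
                    note = (
                        f"  [overlaps {ref_label}]"
                        if overlaps
                        else f"  [outside {ref_label}]"
                    )
                sub.append(
                    f"  {label}: cluster {span} (size {c['size']}, p={c['p_value']:.4g}){note}"
                )
        return sub

    if "decoding_accuracy" in results:
        lines += describe(
            "decoding accuracy", results["decoding_accuracy"], signal, "signal window"
        )
    if "sensitivity" in results:
        lines += describe(
            "orientation sensitivity", results["sensitivity"], planted, "planted window"
        )
    if "correlation" in results:
        lines += describe(
            "brain-behavior correlation", results["correlation"], planted, "planted window"
        )
    if not results:
        lines.append("  no significant clusters")
    return "\n".join(lines)
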