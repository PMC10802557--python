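"""End-to-end analysis pipeline with a reproducible seed tree.

Orchestrates simulate (or load) -> interaction detection -> aggression
metrics -> triggered sequences (aggression + size-matched controls) ->
approach geometry -> decoding -> three-step typing, and collects every
recording-level statistic into one machine-readable summary.  Each stage
draws its randomness from a seed derived deterministically from the
master seed and the stage name, so stages can be re-run in isolation and
a config+seed pair always yields the identical summary.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import aggression, circstats, decoding, interactions, seqtypes, sequences
from .data_model import ArenaSpec, Recording, read_recording, write_recording
from .synthetic import GeneratorParams, generate_recording

__all__ = ["RunConfig", "run_pipeline", "paired_signed_rank", "stage_seed",
           "heading_angles_by_state"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    # input: either generator parameters or paths to pose/event CSVs
    generator: dict = field(default_factory=dict)
    pose_path: str | None = None
    event_path: str | None = None
    arena: dict = field(default_factory=dict)
    # analysis parameters
    min_frames: int = 6
    extension_cm: float = 3.0
    subsample_k: int = 50
    n_permutations: int = 1000
    n_iterations: int = 200
    n_shuffles: int = 200
    post_window_s: float = 5.0
    watson_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def heading_angles_by_state(rec: Recording, seqs) -> dict:
    """Heading-to-female angles at each trigger's last frame, by male state."""
    pose = {
        m: rec.poses_of(m)[["x_cm", "y_cm", "nose_x_cm", "nose_y_cm"]].to_numpy()
        for m in rec.mouse_ids
    }
    out: dict[str, list[float]] = {}
    for s in seqs:
        f = s.trigger.end_frame
        male = pose[s.male_partner_id][f]
        female = pose[s.female_id][f]
        try:
            ang = circstats.heading_angle_to_target(male[:2], male[2:], female[:2])
        except ValueError:
            continue
        out.setdefault(s.male_state, []).append(ang)
    return out


def paired_signed_rank(values_a, values_b):
    """Two-sided Wilcoxon signed-rank test for paired recording medians.

    Returns ``(W, p)`` where W is the sum of the ranks of the positive
    differences (b - a), the convention used for reporting; p is exact
    for small samples without ties.  All-zero differences give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = b - a
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    ranks = sstats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    res = sstats.wilcoxon(nz)
    return w_pos, float(res.pvalue)


def _decode_summary(res: decoding.DecodingResult) -> dict:
    return {
        "mean_accuracy_pct": res.mean,
        "sd_pct": res.sd,
        "chance_pct": res.chance_pct,
        "z": res.z,
        "p": res.p,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one recording; returns the summary dict.

    If ``config.out_dir`` is set, stage tables and ``summary.json`` are
    written there.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary: dict = {"seed": config.seed}

    # -- stage: input ------------------------------------------------------
    try:
        if config.pose_path:
            arena = ArenaSpec(**config.arena) if config.arena else ArenaSpec()
            rec = read_recording(config.pose_path, config.event_path, arena)
            truth = None
        else:
            params = GeneratorParams(**config.generator)
            rec, truth = generate_recording(params, seed=stage_seed(config.seed, "simulate"))
    except Exception as exc:  # noqa: BLE001
        fail("input", exc)
    summary["n_frames"] = rec.n_frames
    summary["n_events"] = len(rec.events)
    if out_dir:
        write_recording(rec, out_dir / "poses.csv", out_dir / "events.csv")
        if truth is not None:
            truth.to_csv(out_dir / "ground_truth.csv", index=False)

    # -- stage: interactions ----------------------------------------------
    try:
        si = interactions.detect_interactions(
            rec, "opposite_sex", min_frames=config.min_frames,
            extension_cm=config.extension_cm,
        )
    except Exception as exc:  # noqa: BLE001
        fail("interactions", exc)
    summary["n_interactions"] = len(si)
    if out_dir:
        interactions.interactions_to_dataframe(si).to_csv(
            out_dir / "interactions.csv", index=False
        )

    # -- stage: aggression metrics ----------------------------------------
    try:
        agg = aggression.summarize_aggression(rec, tie_break="time")
        summary["aggression"] = {
            "score": agg.score,
            "dominant": agg.dominant_id,
            "counts": {agg.male1: agg.n_aggressive_male1, agg.male2: agg.n_aggressive_male2},
            "aggressor_time_share_pct": agg.aggressor_time_share,
            "submissive_time_s": agg.submissive_time_s,
        }
    except aggression.DominanceTieError:
        summary["aggression"] = None

    # -- stage: triggered sequences ---------------------------------------
    try:
        seq_summary = {}
        seqs_by_class = {}
        n_aggressive = len(sequences.trigger_events(rec, "aggression"))
        for cls in sequences.TRIGGER_CLASSES:
            triggers = None
            if cls != "aggression":
                triggers = sequences.subsample_control_triggers(
                    rec.events, cls, n_aggressive,
                    seed=stage_seed(config.seed, f"subsample-{cls}"),
                )
            seqs = sequences.extract_triggered_sequences(
                rec, si, cls, triggers=triggers
            )
            seqs_by_class[cls] = seqs
            first, second = sequences.ROLE_PAIRS[cls]
            entry: dict = {"n_sequences": len(seqs)}
            if seqs:
                n1 = sum(s.male_state == first for s in seqs)
                n2 = len(seqs) - n1
                lat = {
                    st: float(np.median([s.latency_s for s in seqs if s.male_state == st]))
                    for st in (first, second)
                    if any(s.male_state == st for s in seqs)
                }
                dur = {
                    st: float(np.median([s.duration_s for s in seqs if s.male_state == st]))
                    for st in (first, second)
                    if any(s.male_state == st for s in seqs)
                }
                entry.update(
                    counts={first: n1, second: n2},
                    median_latency_s=lat,
                    median_duration_s=dur,
                )
                if n1 + n2 > 0:
                    perm = sequences.permute_identity(
                        seqs, n_permutations=config.n_permutations,
                        seed=stage_seed(config.seed, f"permute-{cls}"),
                    )
                    entry["difference_index"] = perm.actual_value
                    entry["permutation"] = {
                        "null_mean": perm.null_mean,
                        "null_sd": perm.null_sd,
                        "z": perm.z,
                        "p": perm.p,
                    }
            seq_summary[cls] = entry
            if out_dir and seqs:
                sequences.sequences_to_dataframe(seqs, rec.fps).to_csv(
                    out_dir / f"sequences_{cls}.csv", index=False
                )
        summary["sequences"] = seq_summary
    except Exception as exc:  # noqa: BLE001
        fail("sequences", exc)

    # -- stage: geometry ---------------------------------------------------
    try:
        geo = {}
        by_state = heading_angles_by_state(rec, seqs_by_class["aggression"])
        for st, vals in by_state.items():
            summ = circstats.circular_summary(vals)
            geo[st] = {
                "n": summ.n,
                "median_deg": summ.median_deg,
                "variance": summ.variance,
            }
        if {"aggressor", "aggressed"} <= set(by_state):
            u2, p = circstats.watson_u2(
                by_state["aggressor"], by_state["aggressed"],
                n_permutations=config.watson_permutations,
                seed=stage_seed(config.seed, "watson"),
            )
            geo["watson_u2"] = {"u2": u2, "p": p}
        summary["heading_angles"] = geo
    except Exception as exc:  # noqa: BLE001
        fail("geometry", exc)

    # -- stage: decoding ---------------------------------------------------
    try:
        dec = {}
        aggr_seqs = seqs_by_class["aggression"]
        if len(aggr_seqs) >= 8:
            feats = decoding.state_feature_table(aggr_seqs)
            if feats["label"].nunique() == 2:
                res = decoding.decode(
                    feats, model="tree", n_iterations=config.n_iterations,
                    seed=stage_seed(config.seed, "decode-observed"),
                )
                dec["state_observed"] = _decode_summary(res)
                matched = decoding.size_match(
                    feats, seed=stage_seed(config.seed, "size-match")
                )
                if len(matched) >= 8:
                    res = decoding.decode(
                        matched, model="tree", n_iterations=config.n_iterations,
                        seed=stage_seed(config.seed, "decode-matched"),
                    )
                    dec["state_size_matched"] = _decode_summary(res)
                rand_rec = decoding.randomize_triggers(
                    rec, "aggression", seed=stage_seed(config.seed, "randomize")
                )
                rand_seqs = sequences.extract_triggered_sequences(rand_rec, si, "aggression")
                rand_feats = (
                    decoding.state_feature_table(rand_seqs) if rand_seqs else None
                )
                if rand_feats is not None and len(rand_feats) >= 8 \
                        and rand_feats["label"].nunique() == 2:
                    res = decoding.decode(
                        rand_feats, model="tree", n_iterations=config.n_iterations,
                        seed=stage_seed(config.seed, "decode-randomized"),
                    )
                    dec["state_randomized"] = _decode_summary(res)
            walk_seqs = seqs_by_class.get("walking", [])
            if len(walk_seqs) >= 4:
                res = decoding.decode_sequence_class(
                    aggr_seqs, walk_seqs, n_iterations=config.n_iterations,
                    seed=stage_seed(config.seed, "decode-class"),
                )
                dec["sequence_class"] = _decode_summary(res)
        summary["decoding"] = dec
    except Exception as exc:  # noqa: BLE001
        fail("decoding", exc)

    # -- stage: three-step typing -----------------------------------------
    try:
        typed = seqtypes.extract_three_step(rec, si)
        st: dict = {
            "n_typed": len(typed.sequences),
            "type_counts": typed.type_counts,
            "type_proportions_pct": typed.type_proportions_pct,
            "n_excluded_same_male": typed.n_excluded_same_male,
        }
        if typed.sequences and config.n_shuffles > 0:
            props = seqtypes.type_proportions_vs_null(
                rec, si, n_shuffles=config.n_shuffles,
                seed=stage_seed(config.seed, "type-null"),
            )
            st["proportions_vs_null"] = props.to_dict(orient="records")
        fights = seqtypes.fight_association(rec, typed)
        st["fights"] = {
            "total": fights.n_fights_total,
            "after_type1": fights.n_after_type1,
            "after_other": fights.n_after_other,
            "unattributed": fights.n_unattributed,
        }
        summary["three_step"] = st
    except Exception as exc:  # noqa: BLE001
        fail("three_step", exc)

    # headline qualitative flags for smoke checks
    aggr = summary["sequences"].get("aggression", {})
    idx = aggr.get("difference_index")
    counts = summary["three_step"]["type_counts"]
    modal = max(counts, key=counts.get) if counts else None
    summary["flags"] = {
        "index_below_zero": bool(idx is not None and idx < 0),
        "type1_modal": modal == 1,
        "fewer_fights_after_type1": (
            summary["three_step"]["fights"]["after_type1"]
            < summary["three_step"]["fights"]["after_other"]
        ),
    }

    if out_dir:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary
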