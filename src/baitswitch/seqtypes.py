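"""Three-step "bait-and-switch" sequences.

A three-step sequence is an aggressive encounter followed by two
male-female social interactions: the first (si1) pairs one of the males
with a female, the second (si2) is the next male-female interaction by
the *other* male.  The combination of the si1 male's behavioral state and
whether si2 involves the same female defines four types:

    type 1: (aggressed, F)  then (aggressor, same F)   — bait-and-switch
    type 2: (aggressor, F)  then (aggressed, same F)
    type 3: (aggressed, F)  then (aggressor, other F)
    type 4: (aggressor, F)  then (aggressed, other F)

An si2 by the *same* male is not a typed sequence; such cases are
excluded and counted so totals reconcile.  Type proportions are compared
to a temporally randomized null (trigger times redrawn, interactions
untouched), inter-individual distances are phase-normalized across the
four phases of the sequence (trigger, latency gap, si1, 5-s post window),
and fights are attributed to the typed sequence they follow to quantify
the de-escalating effect of the bait-and-switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BehaviorEvent, Recording, event_roles
from .decoding import DecodingResult, decode, randomize_triggers, size_match
from .interactions import SocialInteraction
from .sequences import trigger_events

__all__ = [
    "ThreeStepSequence",
    "ThreeStepExtraction",
    "DistanceProfiles",
    "FightAssociation",
    "classify_three_step",
    "extract_three_step",
    "type_proportions_vs_null",
    "distance_profiles",
    "decode_type_from_kinematics",
    "decode_type_from_distances",
    "fight_association",
]

SEQUENCE_TYPES = (1, 2, 3, 4)


@dataclass(frozen=True)
class ThreeStepSequence:
    trigger: BehaviorEvent
    si1: SocialInteraction
    si2: SocialInteraction
    aggressor_id: str
    aggressed_id: str
    si1_male: str
    si1_female: str
    si2_male: str
    si2_female: str
    seq_type: int


@dataclass
class ThreeStepExtraction:
    sequences: list[ThreeStepSequence]
    n_excluded_same_male: int  # si2 by the same male as si1
    n_triggers_without_si1: int
    n_si1_without_si2: int

    @property
    def type_counts(self) -> dict:
        c = {t: 0 for t in SEQUENCE_TYPES}
        for s in self.sequences:
            c[s.seq_type] += 1
        return c

    @property
    def type_proportions_pct(self) -> dict:
        n = len(self.sequences)
        return {t: (100.0 * c / n if n else np.nan) for t, c in self.type_counts.items()}


def classify_three_step(
    si1_male_state: str, si1_female: str, si2_male_state: str, si2_female: str
) -> int:
    """Sequence type 1-4 from the two interactions' roles and females."""
    same = si1_female == si2_female
    if si1_male_state == "aggressed" and si2_male_state == "aggressor":
        return 1 if same else 3
    if si1_male_state == "aggressor" and si2_male_state == "aggressed":
        return 2 if same else 4
    raise ValueError(
        "three-step steps must alternate male state, got "
        f"{si1_male_state!r} then {si2_male_state!r}"
    )


def extract_three_step(
    rec: Recording,
    interactions: list[SocialInteraction],
    max_gap_s: float | None = None,
) -> ThreeStepExtraction:
    """Extract and type all three-step sequences of a recording.

    si1 is the earliest male-female interaction starting after the
    trigger's start and before the next aggressive trigger; si2 is the
    next male-female interaction starting after si1 ends (no trigger
    bound; ``max_gap_s`` optionally caps the si1-to-si2 gap).
    """
    males = set(rec.males)
    mf = sorted(
        (
            si
            for si in interactions
            if {rec.sex_of(si.mouse_a), rec.sex_of(si.mouse_b)} == {"M", "F"}
        ),
        key=lambda s: s.start_frame,
    )
    starts = np.array([si.start_frame for si in mf])
    triggers = trigger_events(rec, "aggression")
    fps = rec.fps
    out: list[ThreeStepSequence] = []
    n_same = n_no_si1 = n_no_si2 = 0
    for i, trig in enumerate(triggers):
        window_end = triggers[i + 1].start_frame if i + 1 < len(triggers) else np.inf
        aggressor, aggressed = event_roles(trig)
        j = int(np.searchsorted(starts, trig.start_frame, side="right"))
        if j >= len(mf) or mf[j].start_frame >= window_end:
            n_no_si1 += 1
            continue
        si1 = mf[j]
        m1 = si1.mouse_a if si1.mouse_a in males else si1.mouse_b
        f1 = si1.mouse_b if m1 == si1.mouse_a else si1.mouse_a
        k = int(np.searchsorted(starts, si1.end_frame, side="right"))
        si2 = None
        if k < len(mf):
            cand = mf[k]
            gap_s = cand.start_frame / fps - (si1.end_frame + 1) / fps
            if max_gap_s is None or gap_s <= max_gap_s:
                si2 = cand
        if si2 is None:
            n_no_si2 += 1
            continue
        m2 = si2.mouse_a if si2.mouse_a in males else si2.mouse_b
        f2 = si2.mouse_b if m2 == si2.mouse_a else si2.mouse_a
        if m2 == m1:
            n_same += 1
            continue
        st1 = "aggressor" if m1 == aggressor else "aggressed"
        st2 = "aggressor" if m2 == aggressor else "aggressed"
        out.append(
            ThreeStepSequence(
                trigger=trig,
                si1=si1,
                si2=si2,
                aggressor_id=aggressor,
                aggressed_id=aggressed,
                si1_male=m1,
                si1_female=f1,
                si2_male=m2,
                si2_female=f2,
                seq_type=classify_three_step(st1, f1, st2, f2),
            )
        )
    return ThreeStepExtraction(
        sequences=out,
        n_excluded_same_male=n_same,
        n_triggers_without_si1=n_no_si1,
        n_si1_without_si2=n_no_si2,
    )


def type_proportions_vs_null(
    rec: Recording,
    interactions: list[SocialInteraction],
    n_shuffles: int = 1000,
    seed=None,
    max_gap_s: float | None = None,
) -> pd.DataFrame:
    """Observed type proportions vs a trigger-time-randomized null.

    Each shuffle redraws the aggressive-trigger times (durations and roles
    kept, interactions untouched), re-extracts three-step sequences, and
    records the per-type proportions.  Returns one row per type with the
    actual percentage, null mean/sd and z-score.
    """
    actual = extract_three_step(rec, interactions, max_gap_s=max_gap_s)
    act_pct = actual.type_proportions_pct
    rng = np.random.default_rng(seed)
    null = {t: [] for t in SEQUENCE_TYPES}
    for _ in range(n_shuffles):
        shuffled = randomize_triggers(
            rec, "aggression", seed=int(rng.integers(0, 2**31 - 1))
        )
        ext = extract_three_step(shuffled, interactions, max_gap_s=max_gap_s)
        pct = ext.type_proportions_pct
        for t in SEQUENCE_TYPES:
            null[t].append(pct[t])
    rows = []
    for t in SEQUENCE_TYPES:
        nv = np.array(null[t], dtype=float)
        nv = nv[~np.isnan(nv)]
        mu, sd = float(nv.mean()), float(nv.std(ddof=0))
        a = act_pct[t]
        if sd > 0:
            z = (a - mu) / sd
        else:
            z = 0.0 if a == mu else float("inf") * (1 if a > mu else -1)
        rows.append(
            {
                "seq_type": t,
                "actual_pct": a,
                "null_mean_pct": mu,
                "null_sd_pct": sd,
                "z": z,
                "n_actual": actual.type_counts[t],
            }
        )
    return pd.DataFrame(rows)


# -- phase-normalized distance profiles ------------------------------------

_PHASES = ("trigger", "gap", "si1", "post")


@dataclass
class DistanceProfiles:
    """Phase-resampled male-to-female distances and snapshot table."""

    profiles: dict  # role -> (n_sequences, sum of per-phase max lengths)
    phase_lengths: dict  # phase -> resampled length
    snapshots: pd.DataFrame  # per sequence/role distances at fixed offsets


def _phase_spans(seq: ThreeStepSequence, fps: float, post_window_s: float, n_frames: int):
    t, s1 = seq.trigger, seq.si1
    post_end = min(int(s1.end_frame + post_window_s * fps), n_frames - 1)
    return {
        "trigger": (t.start_frame, t.end_frame),
        "gap": (t.end_frame + 1, s1.start_frame - 1),  # may be empty
        "si1": (s1.start_frame, s1.end_frame),
        "post": (s1.end_frame + 1, post_end),
    }


def _resample(values: np.ndarray, length: int, fallback: float) -> np.ndarray:
    """Linear resampling to ``length`` points, preserving endpoints."""
    if length < 1:
        raise ValueError("resample length must be >= 1")
    if values.size == 0:
        return np.full(length, fallback)
    if values.size == 1 or length == 1:
        return np.full(length, values[0] if values.size else fallback)
    x_old = np.linspace(0.0, 1.0, values.size)
    x_new = np.linspace(0.0, 1.0, length)
    return np.interp(x_new, x_old, values)


def distance_profiles(
    sequences: list[ThreeStepSequence],
    rec: Recording,
    post_window_s: float = 5.0,
) -> DistanceProfiles:
    """Per-frame aggressor/aggressed-to-female distances, phase-normalized.

    Each sequence is split into four phases (trigger, latency gap, si1,
    ``post_window_s`` seconds after si1).  Distances of each male to the
    si1 female are resampled phase-wise to the dataset-wide maximum length
    of that phase (linear interpolation, endpoints preserved; an empty gap
    contributes its boundary value).  Snapshots are taken at si1 start
    + 1 s and si1 end + 1, 2, 3 s.
    """
    if not sequences:
        raise ValueError("no sequences")
    fps = rec.fps
    n_frames = rec.n_frames
    pos = {
        m: rec.poses_of(m)[["x_cm", "y_cm"]].to_numpy() for m in rec.mouse_ids
    }
    spans = [_phase_spans(s, fps, post_window_s, n_frames) for s in sequences]
    phase_len = {
        ph: max(max(sp[ph][1] - sp[ph][0] + 1, 0) for sp in spans) for ph in _PHASES
    }
    phase_len = {ph: max(L, 1) for ph, L in phase_len.items()}
    total = sum(phase_len.values())
    profiles = {
        "aggressor": np.empty((len(sequences), total)),
        "aggressed": np.empty((len(sequences), total)),
    }
    snap_rows = []
    for i, (seq, sp) in enumerate(zip(sequences, spans)):
        female = pos[seq.si1_female]
        for role, male_id in (
            ("aggressor", seq.aggressor_id),
            ("aggressed", seq.aggressed_id),
        ):
            d = np.hypot(*(pos[male_id] - female).T)
            parts = []
            for ph in _PHASES:
                a, b = sp[ph]
                vals = d[a : b + 1] if b >= a else np.empty(0)
                # empty gap: carry the si1-start distance
                fallback = d[min(sp["si1"][0], n_frames - 1)]
                parts.append(_resample(vals, phase_len[ph], fallback))
            profiles[role][i] = np.concatenate(parts)
            row = {"sequence": i, "role": role, "seq_type": seq.seq_type}
            for name, frame in (
                ("start_plus_1s", seq.si1.start_frame + int(fps)),
                ("end_plus_1s", seq.si1.end_frame + int(fps)),
                ("end_plus_2s", seq.si1.end_frame + int(2 * fps)),
                ("end_plus_3s", seq.si1.end_frame + int(3 * fps)),
            ):
                row[name] = d[frame] if frame < n_frames else np.nan
            snap_rows.append(row)
    return DistanceProfiles(
        profiles=profiles,
        phase_lengths=phase_len,
        snapshots=pd.DataFrame(snap_rows),
    )


# -- type decoding ---------------------------------------------------------

def _kinematic_features(sequences, rec) -> pd.DataFrame:
    pos = {m: rec.poses_of(m)[["x_cm", "y_cm"]].to_numpy() for m in rec.males}
    fps = rec.fps
    rows = []
    for seq in sequences:
        a, b = seq.trigger.start_frame, seq.trigger.end_frame
        row = {}
        for role, mid in (("aggressor", seq.aggressor_id), ("aggressed", seq.aggressed_id)):
            xy = pos[mid][a : b + 1]
            steps = np.hypot(*np.diff(xy, axis=0).T)
            row[f"{role}_mean_speed"] = steps.mean() * fps if steps.size else 0.0
            row[f"{role}_distance_traveled"] = steps.sum()
        row["label"] = seq.seq_type
        rows.append(row)
    return pd.DataFrame(rows)


def decode_type_from_kinematics(
    sequences: list[ThreeStepSequence],
    rec: Recording,
    n_iterations: int = 1000,
    seed=None,
) -> DecodingResult:
    """Decode sequence type from trigger-phase speed and distance traveled
    of both males (4 features, chance 25%)."""
    features = _kinematic_features(sequences, rec)
    if features["label"].nunique() < 4:
        raise ValueError("need all four sequence types present")
    return decode(
        features, model="multiclass_svm", n_iterations=n_iterations, seed=seed
    )


def _distance_features(sequences, rec) -> pd.DataFrame:
    pos = {m: rec.poses_of(m)[["x_cm", "y_cm"]].to_numpy() for m in rec.mouse_ids}
    rows = []
    for seq in sequences:
        female = pos[seq.si1_female]
        frames = {
            "trig_start": seq.trigger.start_frame,
            "trig_end": seq.trigger.end_frame,
            "si1_start": seq.si1.start_frame,
            "si1_end": seq.si1.end_frame,
            "si2_start": seq.si2.start_frame,
            "si2_end": seq.si2.end_frame,
        }
        row = {}
        for role, mid in (("aggressor", seq.aggressor_id), ("aggressed", seq.aggressed_id)):
            d = np.hypot(*(pos[mid] - female).T)
            for name, f in frames.items():
                row[f"{role}_{name}"] = d[min(f, len(d) - 1)]
        row["label"] = seq.seq_type
        rows.append(row)
    return pd.DataFrame(rows)


def decode_type_from_distances(
    sequences: list[ThreeStepSequence],
    rec: Recording,
    n_iterations: int = 1000,
    seed=None,
    variant: str = "observed",
) -> DecodingResult:
    """Decode sequence type from 12 inter-individual distances (both
    males' distances to the si1 female at the start and end of the
    trigger, si1 and si2); chance 25%.  ``variant="size_matched"``
    undersamples types to the rarest type's count first."""
    features = _distance_features(sequences, rec)
    if features["label"].nunique() < 4:
        raise ValueError("need all four sequence types present")
    if variant == "size_matched":
        features = size_match(features, seed=seed)
    elif variant != "observed":
        raise ValueError(f"unknown variant {variant!r}")
    return decode(
        features, model="multiclass_svm", n_iterations=n_iterations, seed=seed
    )


# -- fights ----------------------------------------------------------------

@dataclass
class FightAssociation:
    n_fights_total: int
    n_after_type1: int
    n_after_other: int
    n_unattributed: int

    @property
    def prop_type1(self) -> float:
        return self.n_after_type1 / self.n_fights_total if self.n_fights_total else np.nan

    @property
    def prop_other(self) -> float:
        return self.n_after_other / self.n_fights_total if self.n_fights_total else np.nan


def fight_association(
    rec: Recording,
    typed: ThreeStepExtraction,
    fights: list[BehaviorEvent] | None = None,
) -> FightAssociation:
    """Attribute each fight to the typed sequence it follows.

    A fight belongs to the most recent typed sequence whose si2 has ended
    before the fight starts, provided no new aggressive trigger intervened
    — i.e. the fight falls in the interval between that sequence's end and
    the next aggressive trigger.  Fights preceding all sequences, or with
    an intervening trigger, are unattributed.  Types 2-4 are pooled as
    "other" (the paper's grouping for the de-escalation comparison).
    """
    if fights is None:
        fights = [e for e in rec.events if e.behavior == "fight"]
    seqs = sorted(typed.sequences, key=lambda s: s.si2.end_frame)
    seq_ends = np.array([s.si2.end_frame for s in seqs])
    trig_starts = np.array(
        sorted(e.start_frame for e in trigger_events(rec, "aggression"))
    )
    n1 = nother = nun = 0
    for fight in fights:
        i = int(np.searchsorted(seq_ends, fight.start_frame, side="left")) - 1
        if i < 0:
            nun += 1
            continue
        seq = seqs[i]
        # an aggressive trigger between the sequence's end and the fight
        # resets attribution
        j = np.searchsorted(trig_starts, seq.si2.end_frame, side="right")
        if j < len(trig_starts) and trig_starts[j] <= fight.start_frame:
            nun += 1
            continue
        if seq.seq_type == 1:
            n1 += 1
        else:
            nother += 1
    return FightAssociation(
        n_fights_total=len(fights),
        n_after_type1=n1,
        n_after_other=nother,
        n_unattributed=nun,
    )
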