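"""Triggered behavioral sequences and the difference index.

A *triggered sequence* pairs a trigger bout — an aggressive encounter
(chase/flee), a solitary walk, or a male-male investigation — with the
earliest male-female social interaction that starts after the trigger
starts and before the next trigger of the same class.  Latency is the
signed gap from trigger end to interaction start (negative when the
interaction begins while the trigger is still running), and the male
partner carries the behavioral state the trigger assigned him
(aggressor/aggressed, walker/non-walker, investigator/investigated).

State dependence is quantified by the difference index

    index = (n_first_state - n_second_state) / total

(for aggression triggers: aggressor minus aggressed sequence counts over
their sum; an index below 0 means the aggressed male interacted with
females more).  Two null constructions are provided: per-trigger identity
permutation (roles re-flipped with a fair coin, order and durations kept)
and a fixed-size subsampling distribution across recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    AGGRESSIVE_BEHAVIORS,
    BehaviorEvent,
    Recording,
    event_roles,
)
from .interactions import SocialInteraction

__all__ = [
    "TriggeredSequence",
    "DifferenceIndex",
    "PermutationResult",
    "SubsampleResult",
    "TRIGGER_CLASSES",
    "ROLE_PAIRS",
    "trigger_events",
    "extract_triggered_sequences",
    "subsample_control_triggers",
    "difference_index",
    "permute_identity",
    "subsample_index_distribution",
    "hourly_profile",
    "sequences_to_dataframe",
]

logger = logging.getLogger(__name__)

TRIGGER_CLASSES = ("aggression", "walking", "investigation")
#: (state counted positively in the index, its complement), per trigger class
ROLE_PAIRS = {
    "aggression": ("aggressor", "aggressed"),
    "walking": ("walker", "non_walker"),
    "investigation": ("investigator", "investigated"),
}


@dataclass(frozen=True)
class TriggeredSequence:
    trigger: BehaviorEvent
    trigger_class: str
    si: SocialInteraction
    male_partner_id: str
    female_id: str
    male_state: str
    latency_s: float
    duration_s: float


@dataclass(frozen=True)
class DifferenceIndex:
    n_first: int  # aggressor / walker / investigator sequences
    n_second: int  # aggressed / non-walker / investigated sequences

    @property
    def value(self) -> float:
        return (self.n_first - self.n_second) / (self.n_first + self.n_second)


@dataclass
class PermutationResult:
    actual_value: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    z: float
    p: float  # two-sided empirical p


@dataclass
class SubsampleResult:
    indices: np.ndarray
    mean: float
    sd: float
    z: float  # mean / sd of the subsample distribution, tested against N(0, 1)
    p: float  # two-sided normal p for that z
    frac_below_zero: float


def trigger_events(rec: Recording, trigger_class: str) -> list[BehaviorEvent]:
    """Events of the recording belonging to a trigger class, in time order."""
    if trigger_class == "aggression":
        sel = [e for e in rec.events if e.behavior in AGGRESSIVE_BEHAVIORS]
    elif trigger_class == "walking":
        sel = [e for e in rec.events if e.behavior == "walk"]
    elif trigger_class == "investigation":
        sel = [e for e in rec.events if e.behavior == "investigate"]
    else:
        raise ValueError(f"unknown trigger class {trigger_class!r}")
    return sorted(sel, key=lambda e: (e.start_frame, e.end_frame))


def _male_state(trigger: BehaviorEvent, trigger_class: str, male_id: str, males) -> str:
    if trigger_class == "aggression":
        aggressor, aggressed = event_roles(trigger)
        if male_id == aggressor:
            return "aggressor"
        if male_id == aggressed:
            return "aggressed"
        raise ValueError(f"male {male_id} not part of trigger roles")
    if trigger_class == "walking":
        return "walker" if male_id == trigger.actor_id else "non_walker"
    if trigger_class == "investigation":
        return "investigator" if male_id == trigger.actor_id else "investigated"
    raise ValueError(trigger_class)


def extract_triggered_sequences(
    rec: Recording,
    interactions: list[SocialInteraction],
    trigger_class: str = "aggression",
    triggers: list[BehaviorEvent] | None = None,
    max_window_s: float | None = None,
    pair_with: str = "first",
) -> list[TriggeredSequence]:
    """Pair each trigger with the following male-female interaction(s).

    An interaction qualifies if it starts strictly after the trigger's
    start and before the next same-class trigger's start (an interaction
    already in progress at trigger start is not a sequence; one that
    starts before the trigger *ends* is, with a negative latency).  With
    ``pair_with="first"`` (default) only the earliest qualifying
    interaction is kept, one interaction per trigger; ``"all"`` keeps
    every qualifying interaction.  ``max_window_s`` optionally caps the
    latency.
    """
    if pair_with not in ("first", "all"):
        raise ValueError("pair_with must be 'first' or 'all'")
    males = set(rec.males)
    females = set(rec.females)
    if triggers is None:
        triggers = trigger_events(rec, trigger_class)
    mf = [
        si
        for si in sorted(interactions, key=lambda s: s.start_frame)
        if (si.mouse_a in males) != (si.mouse_b in males)
        and {rec.sex_of(si.mouse_a), rec.sex_of(si.mouse_b)} == {"M", "F"}
    ]
    fps = rec.fps
    si_starts = np.array([si.start_frame for si in mf])
    out: list[TriggeredSequence] = []
    for i, trig in enumerate(triggers):
        window_end = triggers[i + 1].start_frame if i + 1 < len(triggers) else np.inf
        lo = np.searchsorted(si_starts, trig.start_frame, side="right")
        for j in range(lo, len(mf)):
            si = mf[j]
            if si.start_frame >= window_end:
                break
            latency = si.start_frame / fps - trig.end_time(fps)
            if max_window_s is not None and latency > max_window_s:
                break
            male = si.mouse_a if si.mouse_a in males else si.mouse_b
            female = si.mouse_b if male == si.mouse_a else si.mouse_a
            out.append(
                TriggeredSequence(
                    trigger=trig,
                    trigger_class=trigger_class,
                    si=si,
                    male_partner_id=male,
                    female_id=female,
                    male_state=_male_state(trig, trigger_class, male, males),
                    latency_s=latency,
                    duration_s=si.duration_s(fps),
                )
            )
            if pair_with == "first":
                break
    return out


def subsample_control_triggers(
    events: list[BehaviorEvent], trigger_class: str, n_target: int, seed=None
) -> list[BehaviorEvent]:
    """Uniform random subset of control triggers, matched to a target count.

    Control behaviors (walks, investigations) vastly outnumber aggressive
    bouts, so they are subsampled without replacement to the aggressive
    count.  If the pool is smaller than the target the whole pool is
    returned with a warning, matching the treatment of under-supplied
    recordings.
    """
    if trigger_class == "walking":
        pool = [e for e in events if e.behavior == "walk"]
    elif trigger_class == "investigation":
        pool = [e for e in events if e.behavior == "investigate"]
    else:
        raise ValueError("control triggers are 'walking' or 'investigation'")
    pool = sorted(pool, key=lambda e: e.start_frame)
    if n_target >= len(pool):
        if n_target > len(pool):
            logger.warning(
                "requested %d %s triggers but only %d available; using all",
                n_target,
                trigger_class,
                len(pool),
            )
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_target, replace=False)
    return [pool[i] for i in sorted(idx)]


def difference_index(n_first: int, n_second: int) -> DifferenceIndex:
    """Difference-over-total index for the two behavioral states."""
    if n_first < 0 or n_second < 0:
        raise ValueError("counts must be non-negative")
    if n_first + n_second == 0:
        raise ValueError("difference index undefined: no sequences")
    return DifferenceIndex(n_first=n_first, n_second=n_second)


def _state_counts(sequences, trigger_class):
    first, second = ROLE_PAIRS[trigger_class]
    states = [s.male_state for s in sequences]
    n1 = sum(st == first for st in states)
    n2 = sum(st == second for st in states)
    if n1 + n2 != len(states):
        raise ValueError("sequences carry states outside the trigger's role pair")
    return n1, n2


def permute_identity(
    sequences: list[TriggeredSequence],
    n_permutations: int = 1000,
    seed=None,
    scheme: str = "per_trigger",
) -> PermutationResult:
    """Identity-permutation null for the difference index.

    Randomizes which male held the trigger roles while keeping the order
    and duration of all behaviors fixed; each permutation recomputes the
    state the interacting male would have held and the resulting index.
    ``scheme="per_trigger"`` (default) re-flips roles independently per
    trigger with a fair coin; ``"whole_recording"`` swaps the two males'
    identities globally (coin per permutation), a sensitivity variant.
    """
    if not sequences:
        raise ValueError("no sequences to permute")
    if n_permutations < 100:
        logger.warning("n_permutations=%d is small; z may be unstable", n_permutations)
    trigger_class = sequences[0].trigger_class
    n1, n2 = _state_counts(sequences, trigger_class)
    n = n1 + n2
    actual = difference_index(n1, n2).value
    rng = np.random.default_rng(seed)
    if scheme == "per_trigger":
        flips = rng.random((n_permutations, n)) < 0.5
        first_label = ROLE_PAIRS[trigger_class][0]
        is_first = np.array([s.male_state == first_label for s in sequences])
        # a flip toggles the role the partner held
        perm_first = np.where(flips, ~is_first[None, :], is_first[None, :])
        k = perm_first.sum(axis=1)
        null = (2.0 * k - n) / n
    elif scheme == "whole_recording":
        signs = np.where(rng.random(n_permutations) < 0.5, 1.0, -1.0)
        null = signs * actual
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    mu = float(null.mean())
    sd = float(null.std(ddof=0))
    if sd > 0:
        z = (actual - mu) / sd
    else:
        z = 0.0 if actual == mu else float("inf") * (1 if actual > mu else -1)
    p_emp = (1.0 + np.sum(np.abs(null - mu) >= abs(actual - mu) - 1e-12)) / (
        n_permutations + 1.0
    )
    return PermutationResult(
        actual_value=actual,
        null_values=null,
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p=float(p_emp),
    )


def subsample_index_distribution(
    sequences_by_recording: dict,
    k: int = 50,
    n_repeats: int = 1000,
    seed=None,
) -> SubsampleResult:
    """Fixed-size subsampling distribution of the difference index.

    Each repeat draws ``k`` sequences without replacement from every
    recording, pools the state counts, and computes one index value; the
    resulting distribution is tested against zero with a z-test
    (z = mean / sd of the distribution, compared to a standard normal).
    Every recording must contribute at least ``k`` sequences.
    """
    rng = np.random.default_rng(seed)
    per_rec_first = []
    trigger_class = None
    for name, seqs in sequences_by_recording.items():
        if len(seqs) < k:
            raise ValueError(
                f"recording {name!r} has only {len(seqs)} sequences (< k={k})"
            )
        trigger_class = trigger_class or seqs[0].trigger_class
        first_label = ROLE_PAIRS[trigger_class][0]
        per_rec_first.append(
            np.array([s.male_state == first_label for s in seqs], dtype=bool)
        )
    indices = np.empty(n_repeats)
    for r in range(n_repeats):
        n1 = n2 = 0
        for flags in per_rec_first:
            pick = rng.choice(len(flags), size=k, replace=False)
            f = int(flags[pick].sum())
            n1 += f
            n2 += k - f
        indices[r] = (n1 - n2) / (n1 + n2)
    mu = float(indices.mean())
    sd = float(indices.std(ddof=0))
    z = mu / sd if sd > 0 else float("inf") * (1 if mu > 0 else -1 if mu < 0 else 0)
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return SubsampleResult(
        indices=indices,
        mean=mu,
        sd=sd,
        z=float(z),
        p=float(p),
        frac_below_zero=float(np.mean(indices < 0)),
    )


def hourly_profile(
    sequences: list[TriggeredSequence],
    rec_duration_s: float,
    fps: float,
    n_bins: int = 5,
) -> pd.DataFrame:
    """Per-time-bin proportions of sequences by male behavioral state.

    Sequences are binned by trigger start time into ``n_bins`` equal bins
    (five one-hour bins for the canonical 5-h recording).  Returns one row
    per bin with counts and the within-bin proportion of each state.
    """
    if not sequences:
        raise ValueError("no sequences")
    trigger_class = sequences[0].trigger_class
    first, second = ROLE_PAIRS[trigger_class]
    edges = np.linspace(0.0, rec_duration_s, n_bins + 1)
    rows = []
    starts = np.array([s.trigger.start_frame / fps for s in sequences])
    if (starts >= rec_duration_s).any() or (starts < 0).any():
        raise ValueError("sequence trigger outside the recording duration")
    which = np.clip(np.searchsorted(edges, starts, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = [s for s, w in zip(sequences, which) if w == b]
        nf = sum(s.male_state == first for s in sel)
        ns = sum(s.male_state == second for s in sel)
        tot = nf + ns
        rows.append(
            {
                "bin": b,
                "t_start_s": edges[b],
                "t_end_s": edges[b + 1],
                "n_" + first: nf,
                "n_" + second: ns,
                "pct_" + first: 100.0 * nf / tot if tot else np.nan,
                "pct_" + second: 100.0 * ns / tot if tot else np.nan,
            }
        )
    return pd.DataFrame(rows)


def sequences_to_dataframe(sequences: list[TriggeredSequence], fps: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trigger_class": s.trigger_class,
                "trigger_start": s.trigger.start_frame,
                "trigger_end": s.trigger.end_frame,
                "si_start": s.si.start_frame,
                "si_end": s.si.end_frame,
                "male_partner": s.male_partner_id,
                "female": s.female_id,
                "male_state": s.male_state,
                "latency_s": s.latency_s,
                "duration_s": s.duration_s,
            }
            for s in sequences
        ],
        columns=[
            "trigger_class",
            "trigger_start",
            "trigger_end",
            "si_start",
            "si_end",
            "male_partner",
            "female",
            "male_state",
            "latency_s",
            "duration_s",
        ],
    )
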