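"""Recording-level aggression summaries.

The two males of a group are compared by their *aggregate aggression
level*: the number of aggressive behaviors (chases performed plus flees
provoked) each engaged in as the aggressor.  The aggression score

    score = (n_male1 - n_male2) / (n_male1 + n_male2)

lies in [-1, 1]; 1 means male 1 performed every aggressive act, -1 that
male 2 was the sole aggressor.  Fights are excluded from the score
because both participants hold the aggressor state.  The male with the
strict majority of aggressive behaviors is the dominant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AGGRESSIVE_BEHAVIORS, Recording, event_roles

__all__ = [
    "AggressionSummary",
    "aggression_score",
    "summarize_aggression",
    "label_dominance",
    "exploration_coverage",
    "submissive_state_time",
    "aggressor_time_shares",
    "DominanceTieError",
]


class DominanceTieError(ValueError):
    """Both males performed exactly the same number of aggressive behaviors."""


@dataclass
class AggressionSummary:
    male1: str
    male2: str
    n_aggressive_male1: int  # events in which male1 held the aggressor role
    n_aggressive_male2: int
    score: float
    dominant_id: str | None
    subordinate_id: str | None
    aggressor_time_s: dict  # per-male seconds spent in the aggressor role
    aggressor_time_share: dict  # per-male share of total aggressive time
    submissive_time_s: dict  # per-male seconds spent in the aggressed role


def aggression_score(n1: int, n2: int) -> float:
    """Difference-over-total aggression score for the two males."""
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 == 0:
        raise ValueError("aggression score undefined: no aggressive behaviors")
    return (n1 - n2) / (n1 + n2)


def _aggressive_events(rec: Recording):
    return [e for e in rec.events if e.behavior in AGGRESSIVE_BEHAVIORS]


def _merged_duration_s(spans, fps: float) -> float:
    """Total seconds covered by a union of inclusive frame spans."""
    if not spans:
        return 0.0
    spans = sorted(spans)
    total = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total / fps


def summarize_aggression(rec: Recording, tie_break: str = "error") -> AggressionSummary:
    """Aggression counts, score, dominance labels and role-time budgets.

    ``tie_break``: ``"error"`` (default) raises :class:`DominanceTieError`
    on an exact count tie; ``"time"`` falls back to total aggressor time.
    """
    males = rec.males
    if len(males) != 2:
        raise ValueError(f"expected exactly 2 males, found {len(males)}")
    m1, m2 = males
    counts = {m1: 0, m2: 0}
    agg_spans = {m1: [], m2: []}
    sub_spans = {m1: [], m2: []}
    for ev in _aggressive_events(rec):
        aggressor, aggressed = event_roles(ev)
        counts[aggressor] += 1
        agg_spans[aggressor].append((ev.start_frame, ev.end_frame))
        sub_spans[aggressed].append((ev.start_frame, ev.end_frame))
    score = aggression_score(counts[m1], counts[m2])
    agg_time = {m: _merged_duration_s(agg_spans[m], rec.fps) for m in males}
    sub_time = {m: _merged_duration_s(sub_spans[m], rec.fps) for m in males}
    total = agg_time[m1] + agg_time[m2]
    share = {m: (100.0 * agg_time[m] / total if total > 0 else np.nan) for m in males}

    if counts[m1] != counts[m2]:
        dominant = m1 if counts[m1] > counts[m2] else m2
    elif tie_break == "time" and agg_time[m1] != agg_time[m2]:
        dominant = m1 if agg_time[m1] > agg_time[m2] else m2
    else:
        raise DominanceTieError(
            f"both males performed {counts[m1]} aggressive behaviors"
        )
    subordinate = m2 if dominant == m1 else m1
    return AggressionSummary(
        male1=m1,
        male2=m2,
        n_aggressive_male1=counts[m1],
        n_aggressive_male2=counts[m2],
        score=score,
        dominant_id=dominant,
        subordinate_id=subordinate,
        aggressor_time_s=agg_time,
        aggressor_time_share=share,
        submissive_time_s=sub_time,
    )


def label_dominance(summary: AggressionSummary) -> tuple[str, str]:
    """(dominant_id, subordinate_id) from a computed summary."""
    return summary.dominant_id, summary.subordinate_id


def submissive_state_time(rec: Recording, mouse_id: str) -> float:
    """Seconds the mouse spent in the aggressed role, overlap-merged."""
    spans = []
    for ev in _aggressive_events(rec):
        _, aggressed = event_roles(ev)
        if aggressed == mouse_id:
            spans.append((ev.start_frame, ev.end_frame))
    return _merged_duration_s(spans, rec.fps)


def aggressor_time_shares(rec: Recording) -> dict:
    """Per-male percentage of total aggressive time spent as the aggressor."""
    return summarize_aggression(rec, tie_break="time").aggressor_time_share


def exploration_coverage(rec: Recording, mouse_id: str, bin_area_cm2: float) -> float:
    """Percent of spatial bins the mouse's center visited.

    The arena is gridded into square bins of side ``sqrt(bin_area_cm2)``
    (9, 36 and 81 cm^2 in the standard analysis).  Arena sides need not be
    an exact multiple of the bin side; partial edge bins count as bins.
    For a circular arena the bounding-box grid is masked to bins that
    intersect the circle.
    """
    side = float(np.sqrt(bin_area_cm2))
    if side <= 0:
        raise ValueError("bin area must be > 0")
    w, h = rec.arena.bounds
    nx = int(np.ceil(w / side))
    ny = int(np.ceil(h / side))
    p = rec.poses_of(mouse_id)
    ix = np.clip((p["x_cm"].to_numpy() // side).astype(int), 0, nx - 1)
    iy = np.clip((p["y_cm"].to_numpy() // side).astype(int), 0, ny - 1)
    visited = set(zip(ix.tolist(), iy.tolist()))
    if rec.arena.shape == "circle":
        r = rec.arena.diameter_cm / 2.0
        valid = set()
        for i in range(nx):
            for j in range(ny):
                # nearest point of the bin to the circle center
                px = np.clip(r, i * side, min((i + 1) * side, w))
                py = np.clip(r, j * side, min((j + 1) * side, h))
                if (px - r) ** 2 + (py - r) ** 2 <= r**2:
                    valid.add((i, j))
        n_bins = len(valid)
        visited &= valid
    else:
        n_bins = nx * ny
    return 100.0 * len(visited) / n_bins
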