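"""Approach geometry and circular statistics.

The central geometric quantity is the *heading angle to target*: the
unsigned angle between a male's heading vector (body center to nose, v1)
and the vector from the male's center to a female's center (v2),

    theta = atan2(|v1 x v2|, v1 . v2)   in [0, 180] degrees,

snapshotted at the last frame of an aggressive encounter.  Orientation
differences between partners' body ellipses use the minimal absolute
angular difference on the circle.  Samples of angles are summarized by
the circular median (the sample angle minimizing the mean circular
absolute deviation) and the circular variance 1 - Rbar (Rbar the mean
resultant length), and compared between behavioral states with the
two-sample Watson U^2 test, with significance from label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Recording, event_roles

__all__ = [
    "CircularSummary",
    "ZoneSpec",
    "heading_angle_to_target",
    "orientation_difference",
    "circular_summary",
    "watson_u2",
    "default_zones",
    "zone_latency",
    "ZoneLatencyResult",
]


@dataclass(frozen=True)
class CircularSummary:
    median_deg: float
    variance: float  # 1 - mean resultant length, in [0, 1]
    n: int


@dataclass(frozen=True)
class ZoneSpec:
    name: str
    center_x_cm: float
    center_y_cm: float
    radius_cm: float = 6.0

    def __post_init__(self):
        if self.radius_cm <= 0:
            raise ValueError("zone radius must be > 0")


def heading_angle_to_target(male_center, male_nose, female_center) -> float:
    """Unsigned angle (degrees, [0, 180]) between heading and male-to-female vectors."""
    male_center = np.asarray(male_center, dtype=float)
    v1 = np.asarray(male_nose, dtype=float) - male_center
    v2 = np.asarray(female_center, dtype=float) - male_center
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("heading angle undefined for zero-length vector")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    return float(np.degrees(np.arctan2(abs(cross), float(np.dot(v1, v2)))))


def orientation_difference(theta1_rad: float, theta2_rad: float) -> float:
    """Minimal absolute angular difference in degrees, in [0, 180]."""
    d = np.asarray(theta1_rad, dtype=float) - np.asarray(theta2_rad, dtype=float)
    out = np.abs(np.degrees(np.arctan2(np.sin(d), np.cos(d))))
    return float(out) if out.ndim == 0 else out


def _circ_abs_dev_deg(angles_rad: np.ndarray, candidates_rad: np.ndarray) -> np.ndarray:
    """Mean circular absolute deviation (radians) of data from each candidate."""
    out = np.empty(len(candidates_rad))
    chunk = max(1, int(2e6) // max(len(angles_rad), 1))
    for i in range(0, len(candidates_rad), chunk):
        cand = candidates_rad[i : i + chunk, None]
        d = np.abs(np.angle(np.exp(1j * (angles_rad[None, :] - cand))))
        out[i : i + chunk] = d.mean(axis=1)
    return out


def circular_summary(angles_deg) -> CircularSummary:
    """Circular median and variance of a sample of angles in degrees.

    The median is the sample angle minimizing the mean circular absolute
    deviation (candidates are the data points themselves); exact ties are
    broken by the circular mean of the tied minimizers.  Variance is
    1 - Rbar, zero iff all angles coincide modulo 360.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("circular summary of an empty sample")
    rad = np.radians(a)
    z = np.exp(1j * rad)
    rbar = np.abs(z.mean())
    variance = float(max(0.0, 1.0 - rbar))

    dev = _circ_abs_dev_deg(rad, rad)
    best = dev.min()
    ties = rad[dev <= best + 1e-12]
    med = float(np.angle(np.exp(1j * ties).mean()))
    return CircularSummary(
        median_deg=float(np.degrees(med)) % 360.0, variance=variance, n=a.size
    )


def _watson_u2_stat(ind_sorted: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Watson U^2 from sample-1 membership indicators in pooled sorted order.

    ``ind_sorted`` may be (N,) or (P, N) for P permutations at once.
    """
    ind = np.atleast_2d(ind_sorted).astype(float)
    N = n1 + n2
    d = np.cumsum(ind, axis=1) / n1 - np.cumsum(1.0 - ind, axis=1) / n2
    u2 = (n1 * n2 / N**2) * (np.sum(d * d, axis=1) - np.sum(d, axis=1) ** 2 / N)
    return u2 if ind_sorted.ndim > 1 else u2[0]


def watson_u2(sample1_deg, sample2_deg, n_permutations: int = 1000, seed=None):
    """Two-sample Watson U^2 test for circular data (angles in degrees).

    Returns ``(U2, p)`` with the p-value from random label permutations,
    valid at any sample size and invariant to rotating both samples by a
    common angle.  If every pooled angle is identical, p = 1.
    """
    s1 = np.asarray(sample1_deg, dtype=float) % 360.0
    s2 = np.asarray(sample2_deg, dtype=float) % 360.0
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([s1, s2])
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    n1, n2 = s1.size, s2.size
    order = np.argsort(pooled, kind="stable")
    labels = np.concatenate([np.ones(n1), np.zeros(n2)])[order]
    u2_obs = float(_watson_u2_stat(labels, n1, n2))

    rng = np.random.default_rng(seed)
    # permute labels over pooled positions (sorted order is label-agnostic)
    P = int(n_permutations)
    keys = rng.random((P, n1 + n2))
    perm = np.argsort(keys, axis=1)
    base = np.concatenate([np.ones(n1), np.zeros(n2)])
    ind = base[perm]
    u2_null = _watson_u2_stat(ind, n1, n2)
    p = (1.0 + np.sum(u2_null >= u2_obs - 1e-12)) / (P + 1.0)
    return u2_obs, float(p)


# -- arena zones -----------------------------------------------------------

def default_zones(arena) -> list[ZoneSpec]:
    """Five 6-cm zones: North-, South-, West-central, center, East-central."""
    w, h = arena.bounds
    return [
        ZoneSpec("zone1", w / 2, 3 * h / 4),  # North central
        ZoneSpec("zone2", w / 2, h / 4),  # South central
        ZoneSpec("zone3", w / 4, h / 2),  # West central
        ZoneSpec("zone4", w / 2, h / 2),  # center
        ZoneSpec("zone5", 3 * w / 4, h / 2),  # East central
    ]


@dataclass
class ZoneLatencyResult:
    zone: str
    mouse_id: str
    role: str
    latencies_s: np.ndarray  # one entry per trigger with an entry
    n_excluded: int  # triggers with no zone entry before the limit

    @property
    def mean_s(self) -> float:
        return float(np.mean(self.latencies_s)) if self.latencies_s.size else float("nan")

    @property
    def median_s(self) -> float:
        return float(np.median(self.latencies_s)) if self.latencies_s.size else float("nan")


def zone_latency(
    rec: Recording,
    zones,
    trigger_events,
    role: str = "aggressed",
    limit: str = "next_trigger",
) -> list[ZoneLatencyResult]:
    """Latency from each aggressive-bout end until the nose enters each zone.

    For every trigger, the mouse holding ``role`` ("aggressor" or
    "aggressed") is followed from the trigger's last frame until its nose
    first lies within the zone disc; a nose already inside at the trigger
    end gives latency 0.  Triggers with no entry before the ``limit``
    ("next_trigger" or "recording_end") are excluded and counted.
    Results are grouped per zone and per mouse.
    """
    w, h = rec.arena.bounds
    for z in zones:
        if not (0 <= z.center_x_cm <= w and 0 <= z.center_y_cm <= h):
            raise ValueError(f"{z.name} center outside arena")
    triggers = sorted(trigger_events, key=lambda e: e.start_frame)
    noses = {
        m: rec.poses_of(m)[["nose_x_cm", "nose_y_cm"]].to_numpy() for m in rec.males
    }
    n_frames = rec.n_frames
    out = []
    for z in zones:
        per_mouse: dict[str, list[float]] = {m: [] for m in rec.males}
        excluded: dict[str, int] = {m: 0 for m in rec.males}
        for i, ev in enumerate(triggers):
            aggressor, aggressed = event_roles(ev)
            mouse = aggressor if role == "aggressor" else aggressed
            stop = n_frames
            if limit == "next_trigger" and i + 1 < len(triggers):
                stop = min(stop, triggers[i + 1].start_frame)
            seg = noses[mouse][ev.end_frame : stop]
            d2 = (seg[:, 0] - z.center_x_cm) ** 2 + (seg[:, 1] - z.center_y_cm) ** 2
            hit = np.flatnonzero(d2 <= z.radius_cm**2)
            if hit.size:
                per_mouse[mouse].append(hit[0] / rec.fps)
            else:
                excluded[mouse] += 1
        for m in rec.males:
            out.append(
                ZoneLatencyResult(
                    zone=z.name,
                    mouse_id=m,
                    role=role,
                    latencies_s=np.asarray(per_mouse[m]),
                    n_excluded=excluded[m],
                )
            )
    return out
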