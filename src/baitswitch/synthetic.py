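"""Synthetic group-housing recordings with embedded ground truth.

Generates dense pose tables and event tables for the canonical 2-male +
2-female group so that every downstream stage — ellipse-overlap
interaction detection, triggered-sequence extraction, circular statistics,
decoding, three-step typing — can be validated end-to-end without real
tracking data.

The movement model is deliberately simple rather than photorealistic:
each mouse wanders smoothly around a home anchor (smoothed-noise walk,
anchors far enough apart that non-scripted mice never meet), and behavior
bouts are scripted on top:

* an aggressive encounter moves the aggressed male along a path through
  the central zone with the aggressor trailing it;
* afterwards one male (the aggressed with configurable probability)
  approaches a female along a radial path whose final frames are solved
  against the package's own ellipse-overlap test, so the detected
  interaction starts at the scheduled frame with the scheduled duration;
  during contact the female holds still, which also makes the male the
  unambiguous initiator;
* the second male then approaches the same or the other female,
  completing a three-step sequence of the configured type, optionally
  followed by a fight whose probability depends on the type;
* walks and male-male investigations serve as control triggers whose
  following interaction has no role dependence.

At the end of an aggressive encounter the approaching male's nose is set
at a von Mises-distributed angle from the male-to-female direction, so
heading-angle analyses see the configured role-specific bias.

A per-trigger ground-truth table (who approached first, realized latency
and duration, sequence type, fight placement) is returned alongside the
recording for parameter-recovery tests; analyses never read it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .data_model import ArenaSpec, BehaviorEvent, MouseInfo, Recording
from .interactions import SocialEllipse, ellipses_overlap

__all__ = ["GeneratorParams", "generate_recording", "ground_truth"]

_BODY_A = 3.0  # semi-major of the body ellipse (one body length ~ 6 cm)
_BODY_B = 1.5
_NOSE_OFFSET = 0.8  # nose sits at 0.8 * a from the center along the heading


@dataclass
class GeneratorParams:
    """Study conditions for a synthetic recording.

    Latency/duration medians, heading centers and the sequence-type mix
    default to the observed values for post-aggression male-female
    interactions; the generative model around them is this package's own.
    """

    seed: int = 0
    duration_s: float = 600.0
    fps: float = 30.0
    arena_side_cm: float = 76.2

    n_aggressive_events: int = 30
    n_walks: int = 8
    n_investigations: int = 8

    #: probability the aggressed male performs the first post-aggression
    #: approach; None derives it from type_mix (types 1 + 3)
    p_aggressed_first_approach: float | None = None
    #: probability male 1 is the aggressor of a given encounter; per-event
    #: roles are exchangeable by default (state, not identity, carries the
    #: effects)
    dominance_bias: float = 0.5

    latency_median_s_aggressed: float = 0.73
    latency_median_s_aggressor: float = 3.15
    latency_sigma: float = 0.55  # log-normal shape for latencies
    si_duration_median_s_aggressed: float = 0.81
    si_duration_median_s_aggressor: float = 1.06
    si_duration_sigma: float = 0.25

    heading_center_deg_aggressed: float = 41.34
    heading_center_deg_aggressor: float = 75.94
    heading_kappa: float = 8.0

    type_mix: tuple = (0.53, 0.21, 0.09, 0.17)
    #: probability a first interaction is followed by a second (three-step)
    p_second_si: float = 1.0
    inter_si_gap_median_s: float = 1.0
    p_fight_after_type1: float = 0.1
    p_fight_after_other: float = 0.6

    control_latency_median_s: float = 3.85
    control_duration_median_s: float = 1.2
    #: probability the control trigger's actor performs the following approach
    p_actor_first_control: float = 0.5

    max_speed_cm_s: float = 60.0
    wander_sd_cm: float = 2.0

    def __post_init__(self):
        probs = [self.dominance_bias, self.p_second_si, self.p_actor_first_control,
                 self.p_fight_after_type1, self.p_fight_after_other]
        if self.p_aggressed_first_approach is not None:
            probs.append(self.p_aggressed_first_approach)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.type_mix) - 1.0) > 1e-9 or any(m < 0 for m in self.type_mix):
            raise ValueError("type_mix must be a probability 4-vector")
        for v in (self.latency_median_s_aggressed, self.latency_median_s_aggressor,
                  self.si_duration_median_s_aggressed, self.si_duration_median_s_aggressor,
                  self.control_latency_median_s, self.control_duration_median_s,
                  self.inter_si_gap_median_s):
            if v <= 0:
                raise ValueError("medians must be > 0")


@dataclass
class _Seg:
    f0: int
    f1: int
    pos: np.ndarray  # (f1 - f0 + 1, 2)
    theta: np.ndarray | None = None  # heading override (radians)


def _lognormal(rng, median, sigma):
    return float(median * np.exp(sigma * rng.standard_normal()))


def _vm_angle_deg(rng, center_deg, kappa):
    """Folded von Mises draw in [0, 180] around an unsigned center."""
    d = np.degrees(rng.vonmises(0.0, kappa))
    a = abs(center_deg + d)
    return a if a <= 180.0 else 360.0 - a


def _touch_distance(female_pos, female_theta, u, extension=3.0):
    """Center distance at which the male and female social ellipses first
    touch, male approaching nose-first along -u from direction u."""
    th_m = float(np.arctan2(-u[1], -u[0]))
    fe = SocialEllipse(female_pos[0], female_pos[1], female_theta,
                       _BODY_A + extension, _BODY_B, np.cos(female_theta),
                       np.sin(female_theta))
    lo, hi = _BODY_B * 2.0, 2.0 * (_BODY_A + extension) + 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        me = SocialEllipse(female_pos[0] + mid * u[0], female_pos[1] + mid * u[1],
                           th_m, _BODY_A + extension, _BODY_B, -u[0], -u[1])
        if ellipses_overlap(me, fe):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _approach_distances(d0, touch, n_pre, n_si):
    """Radial distance schedule: n_pre approach frames ending just outside
    contact, then n_si frames inside.  First overlap lands exactly on the
    first SI frame."""
    plunge = min(4, max(1, n_pre - 1))
    glide = n_pre - plunge
    d_pre_target = touch + 4.0
    parts = []
    if glide > 0:
        # glide ends exactly at d_pre_target so the plunge continues smoothly
        parts.append(np.linspace(d0, d_pre_target, glide))
        start = d_pre_target
    else:
        start = d0
    parts.append(np.linspace(start, touch + 0.8, plunge + 1)[1:])
    parts.append(np.full(n_si, touch - 0.8))
    return np.concatenate(parts)


def _exit_distances(touch, n_exit=4):
    return touch + 1.0 + 1.7 * np.arange(n_exit)


class _Infeasible(ValueError):
    pass


def generate_recording(params: GeneratorParams, seed=None):
    """Simulate one recording; returns ``(Recording, truth_table)``.

    ``truth_table`` is a DataFrame with one row per trigger (aggressive,
    walk or investigation) holding the scheduled ground truth.  Identical
    parameters and seed give identical output.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fps = params.fps
    side = params.arena_side_cm
    n_frames = int(round(params.duration_s * fps))
    if n_frames < 10 * fps:
        raise ValueError("duration too short")

    males = ["M1", "M2"]
    females = ["F1", "F2"]
    anchors = {
        "M1": np.array([0.26 * side, 0.21 * side]),
        "M2": np.array([0.74 * side, 0.21 * side]),
        "F1": np.array([0.26 * side, 0.79 * side]),
        "F2": np.array([0.74 * side, 0.79 * side]),
    }

    segs: dict[str, list[_Seg]] = {m: [] for m in anchors}
    #: last scripted (frame, position) per mouse, to keep transits feasible
    last_fix: dict[str, tuple[int, np.ndarray]] = {}
    events: list[BehaviorEvent] = []
    truth_rows = []

    def add_seg(mouse, seg):
        segs[mouse].append(seg)
        lf = last_fix.get(mouse)
        if lf is None or seg.f1 >= lf[0]:
            last_fix[mouse] = (seg.f1, seg.pos[-1].copy())

    def reachable(mouse, frame, target):
        """Clamp a waypoint so the idle transit respects the speed cap."""
        lf = last_fix.get(mouse)
        if lf is None:
            return np.asarray(target, dtype=float)
        f_last, p_last = lf
        budget = 0.7 * max_step * max(frame - f_last, 1)
        vec = np.asarray(target, dtype=float) - p_last
        dist = float(np.hypot(*vec))
        if dist <= budget or dist == 0.0:
            return np.asarray(target, dtype=float)
        return p_last + vec / dist * budget

    if params.p_aggressed_first_approach is None:
        p_first = params.type_mix[0] + params.type_mix[2]
    else:
        p_first = params.p_aggressed_first_approach
    mix = params.type_mix
    # P(second interaction uses the same female | first approacher's role)
    p_same_aggd = mix[0] / (mix[0] + mix[2]) if mix[0] + mix[2] > 0 else 0.5
    p_same_aggr = mix[1] / (mix[1] + mix[3]) if mix[1] + mix[3] > 0 else 0.5

    kinds = (["aggression"] * params.n_aggressive_events
             + ["walk"] * params.n_walks
             + ["investigate"] * params.n_investigations)
    rng.shuffle(kinds)

    max_step = 0.9 * params.max_speed_cm_s / fps

    def schedule_approach(male, fid, f_ref, latency_s, duration_s, start_pos=None,
                          freeze_from_ref=True):
        """Script male approaching female `fid` after reference frame f_ref.

        Returns (si_start, si_end, realized_latency_s, end_frame_of_script).
        The female freezes from f_ref (or f_ref + 1 when her previous
        script only just ended) through the interaction's end, so the
        approach geometry (and the trigger-end heading snapshot) is exact
        against a static target.
        """
        fz0 = f_ref if freeze_from_ref else f_ref + 1
        fpos = reachable(fid, fz0, anchors[fid] + rng.normal(0.0, 2.0, size=2))
        ftheta = rng.uniform(-np.pi, np.pi)
        if start_pos is None:
            start_pos = reachable(
                male, f_ref + 1, anchors[male] + rng.normal(0.0, 2.0, size=2)
            )
        u = np.asarray(start_pos, dtype=float) - fpos
        d0 = float(np.hypot(*u))
        u = u / d0
        touch = _touch_distance(fpos, ftheta, u)
        n_si = max(8, int(round(duration_s * fps)))
        n_pre = int(round(latency_s * fps))
        # keep the glide below the speed cap
        n_min = 5 + int(np.ceil(max(d0 - touch - 4.0, 0.0) / max_step))
        n_pre = max(n_pre, n_min, 8)
        d = _approach_distances(d0, touch, n_pre, n_si)
        ex = _exit_distances(touch)
        dist = np.concatenate([d, ex])
        pos = fpos[None, :] + dist[:, None] * u[None, :]
        f0 = f_ref + 1
        f1 = f0 + len(dist) - 1
        si_start = f0 + n_pre
        si_end = si_start + n_si - 1
        if si_end + 4 >= n_frames:
            raise _Infeasible("approach beyond recording end")
        th = np.full(len(dist), float(np.arctan2(-u[1], -u[0])))
        add_seg(male, _Seg(f0, f1, pos, th))
        # retreat waypoint: pull the male well clear of the female so a
        # subsequent reposition of hers cannot re-enter overlap
        f_retreat = f1 + 25
        if f_retreat < n_frames:
            rpos = fpos + (float(dist[-1]) + 18.0) * u
            rpos = np.clip(rpos, 6.0, side - 6.0)
            add_seg(male, _Seg(f_retreat, f_retreat, rpos[None, :].copy()))
            f1 = f_retreat
        # female frozen for the whole approach + contact
        nfz = si_end - fz0 + 1
        add_seg(fid, _Seg(fz0, si_end, np.tile(fpos, (nfz, 1)),
                          np.full(nfz, ftheta)))
        realized_latency = (si_start - (f_ref + 1)) / fps
        return si_start, si_end, realized_latency, f1

    t = int(2 * fps)  # warm-up
    trig_idx = 0
    for ep_i, kind in enumerate(kinds):
        gap = int(fps * (1.0 + rng.exponential(1.0)))
        t += gap
        if kind == "aggression":
            aggressor = males[0] if rng.random() < params.dominance_bias else males[1]
            aggressed = males[1] if aggressor == males[0] else males[0]
            first_role = "aggressed" if rng.random() < p_first else "aggressor"
            first_male = aggressed if first_role == "aggressed" else aggressor
            second_male = aggressor if first_male == aggressed else aggressed
            fem1 = females[int(rng.random() < 0.5)]
            p_same = p_same_aggd if first_role == "aggressed" else p_same_aggr
            same = rng.random() < p_same
            fem2 = fem1 if same else (females[0] if fem1 == females[1] else females[1])

            dtr = rng.uniform(0.8, 2.0)
            n_tr = int(round(dtr * fps))
            c0, c1 = t, t + n_tr - 1
            # chase path: mostly horizontal, ending below the target female
            f1_anchor = anchors[fem1]
            end = np.array([np.clip(f1_anchor[0] + rng.uniform(-4, 4), 10, side - 10),
                            0.42 * side])
            ang = rng.uniform(-0.2, 0.2) + (0.0 if rng.random() < 0.5 else np.pi)
            dvec = np.array([np.cos(ang), np.sin(ang) * 0.2])
            dvec /= np.hypot(*dvec)
            v_chase = 12.0
            tt = np.arange(n_tr + 8)
            path = end[None, :] - dvec[None, :] * ((n_tr + 7 - tt)[:, None] * v_chase / fps)
            path[:, 0] = np.clip(path[:, 0], 8, side - 8)
            path[:, 1] = np.clip(path[:, 1], 8, 0.48 * side)
            add_seg(aggressed, _Seg(c0, c1, path[8:].copy()))
            add_seg(aggressor, _Seg(c0, c1, path[:n_tr].copy()))
            behavior = "chase" if rng.random() < 0.7 else "flee"
            if behavior == "chase":
                events.append(BehaviorEvent("chase", aggressor, aggressed, c0, c1))
            else:
                events.append(BehaviorEvent("flee", aggressed, aggressor, c0, c1))

            if first_role == "aggressed":
                lat = _lognormal(rng, params.latency_median_s_aggressed, params.latency_sigma)
                dur = _lognormal(rng, params.si_duration_median_s_aggressed,
                                 params.si_duration_sigma)
                head_c = params.heading_center_deg_aggressed
            else:
                lat = _lognormal(rng, params.latency_median_s_aggressor, params.latency_sigma)
                dur = _lognormal(rng, params.si_duration_median_s_aggressor,
                                 params.si_duration_sigma)
                head_c = params.heading_center_deg_aggressor
            first_start_pos = path[8:][-1] if first_male == aggressed else path[:n_tr][-1]
            try:
                si1_s, si1_e, lat_real, f_end = schedule_approach(
                    first_male, fem1, c1, lat, dur, start_pos=first_start_pos)
            except _Infeasible:
                raise ValueError(
                    f"schedule infeasible: {len(kinds)} events exceed "
                    f"duration {params.duration_s} s")

            # heading snapshot at the trigger's last frame
            delta = _vm_angle_deg(rng, head_c, params.heading_kappa)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fpos_seg = segs[fem1][-1].pos[0]
            to_f = fpos_seg - first_start_pos
            base = np.arctan2(to_f[1], to_f[0])
            head = base + sign * np.radians(delta)
            # append a 1-frame heading override on the chase's final frame
            segs[first_male].append(
                _Seg(c1, c1, first_start_pos[None, :].copy(), np.array([head])))

            seq_type = 0
            dur2 = np.nan
            fight = False
            if rng.random() < params.p_second_si:
                gap2 = _lognormal(rng, params.inter_si_gap_median_s, 0.4)
                dur2 = _lognormal(rng,
                                  params.si_duration_median_s_aggressor
                                  if second_male == aggressor
                                  else params.si_duration_median_s_aggressed,
                                  params.si_duration_sigma)
                try:
                    # start after the first male's exit so a same-female
                    # freeze reposition cannot stretch the detected si1
                    si2_s, si2_e, _, f_end = schedule_approach(
                        second_male, fem2, si1_e + 10, gap2, dur2,
                        freeze_from_ref=False)
                except _Infeasible:
                    raise ValueError(
                        f"schedule infeasible: {len(kinds)} events exceed "
                        f"duration {params.duration_s} s")
                first_state = "aggressed" if first_male == aggressed else "aggressor"
                second_state = "aggressed" if second_male == aggressed else "aggressor"
                same_f = fem1 == fem2
                if first_state == "aggressed":
                    seq_type = 1 if same_f else 3
                else:
                    seq_type = 2 if same_f else 4
                p_fight = (params.p_fight_after_type1 if seq_type == 1
                           else params.p_fight_after_other)
                if rng.random() < p_fight:
                    fs = f_end + int(round(fps * 1.0))
                    fe_ = fs + int(round(fps * 1.5)) - 1
                    if fe_ < n_frames:
                        events.append(BehaviorEvent("fight", males[0], males[1], fs, fe_))
                        fight = True
                        f_end = fe_
            truth_rows.append({
                "trigger_index": trig_idx,
                "kind": "aggression",
                "behavior": behavior,
                "trigger_start": c0,
                "trigger_end": c1,
                "aggressor": aggressor,
                "aggressed": aggressed,
                "first_role": first_role,
                "first_male": first_male,
                "first_female": fem1,
                "latency_s": lat_real,
                "si_duration_s": (si1_e - si1_s + 1) / fps,
                "heading_angle_deg": delta,
                "seq_type": seq_type,
                "second_female": fem2 if seq_type else "",
                "fight_follows": fight,
            })
            t = f_end + int(0.5 * fps)
        else:
            dtr = rng.uniform(0.7, 1.5)
            n_tr = int(round(dtr * fps))
            c0, c1 = t, t + n_tr - 1
            actor = males[int(rng.random() < 0.5)]
            other = males[1] if actor == males[0] else males[0]
            if kind == "walk":
                a0 = anchors[actor] + rng.normal(0.0, 3.0, size=2)
                ang = rng.uniform(0, 2 * np.pi)
                wv = 8.0 / fps
                path = a0[None, :] + np.arange(n_tr)[:, None] * wv * np.array(
                    [np.cos(ang), np.sin(ang) * 0.3])[None, :]
                path[:, 0] = np.clip(path[:, 0], 8, side - 8)
                path[:, 1] = np.clip(path[:, 1], 8, 0.4 * side)
                add_seg(actor, _Seg(c0, c1, path))
                events.append(BehaviorEvent("walk", actor, None, c0, c1))
                state_first = "walker"
            else:
                # brief orientation toward the other male, no contact needed
                a0 = anchors[actor] + rng.normal(0.0, 3.0, size=2)
                toward = anchors[other] - a0
                toward /= np.hypot(*toward)
                path = a0[None, :] + np.arange(n_tr)[:, None] * (3.0 / fps) * toward[None, :]
                add_seg(actor, _Seg(c0, c1, path))
                events.append(BehaviorEvent("investigate", actor, other, c0, c1))
                state_first = "investigator"
            approacher = actor if rng.random() < params.p_actor_first_control else other
            fem = females[int(rng.random() < 0.5)]
            lat = _lognormal(rng, params.control_latency_median_s, 0.3)
            dur = _lognormal(rng, params.control_duration_median_s, 0.3)
            start = path[-1] if approacher == actor else None
            try:
                si_s, si_e, lat_real, f_end = schedule_approach(
                    approacher, fem, c1, lat, dur, start_pos=start)
            except _Infeasible:
                raise ValueError(
                    f"schedule infeasible: {len(kinds)} events exceed "
                    f"duration {params.duration_s} s")
            truth_rows.append({
                "trigger_index": trig_idx,
                "kind": kind,
                "behavior": "walk" if kind == "walk" else "investigate",
                "trigger_start": c0,
                "trigger_end": c1,
                "aggressor": "",
                "aggressed": "",
                "first_role": state_first if approacher == actor
                else ("non_walker" if kind == "walk" else "investigated"),
                "first_male": approacher,
                "first_female": fem,
                "latency_s": lat_real,
                "si_duration_s": (si_e - si_s + 1) / fps,
                "heading_angle_deg": np.nan,
                "seq_type": 0,
                "second_female": "",
                "fight_follows": False,
            })
            t = f_end + int(0.5 * fps)
        trig_idx += 1
        if t >= n_frames - int(6 * fps) and ep_i + 1 < len(kinds):
            raise ValueError(
                f"schedule infeasible: {len(kinds)} events exceed "
                f"duration {params.duration_s} s")

    poses = _assemble_poses(segs, anchors, n_frames, side, params, rng)
    arena = ArenaSpec(shape="rectangle", width_cm=side, height_cm=side, fps=fps)
    mice = [MouseInfo(m, "M") for m in males] + [MouseInfo(f, "F") for f in females]
    truth = pd.DataFrame(truth_rows)
    rec = Recording(
        arena=arena,
        mice=mice,
        poses=poses,
        events=sorted(events, key=lambda e: e.start_frame),
        metadata={"synthetic": True, "_ground_truth": truth},
    )
    return rec, truth


def _smooth_noise(rng, n, sd, tau_frames=60.0):
    white = rng.standard_normal((n, 2))
    rho = np.exp(-1.0 / tau_frames)
    out = lfilter([np.sqrt(1 - rho**2)], [1, -rho], white, axis=0)
    return sd * out


def _assemble_poses(segs, anchors, n_frames, side, params, rng):
    """Merge scripted segments with idle wandering into a dense pose table."""
    frames = np.arange(n_frames)
    all_pos = {}
    all_theta = {}
    for mouse, anchor in anchors.items():
        slist = sorted(segs[mouse], key=lambda s: (s.f0, s.f1))
        # later 1-frame overrides (heading snapshots) may overlap a segment;
        # merge by painting in order
        pos = np.empty((n_frames, 2))
        theta_ov = np.full(n_frames, np.nan)
        fixed = np.zeros(n_frames, dtype=bool)
        for s in slist:
            pos[s.f0 : s.f1 + 1] = s.pos
            fixed[s.f0 : s.f1 + 1] = True
            if s.theta is not None:
                theta_ov[s.f0 : s.f1 + 1] = s.theta
        # idle gaps: smoothstep between neighboring fixed positions + noise
        gaps = []
        f = 0
        while f < n_frames:
            if not fixed[f]:
                g0 = f
                while f < n_frames and not fixed[f]:
                    f += 1
                gaps.append((g0, f - 1))
            else:
                f += 1
        noise = _smooth_noise(rng, n_frames, params.wander_sd_cm)
        for g0, g1 in gaps:
            a = pos[g0 - 1] if g0 > 0 else anchor
            b = pos[g1 + 1] if g1 + 1 < n_frames else anchor
            n = g1 - g0 + 1
            s = (np.arange(1, n + 1)) / (n + 1)
            dist = float(np.hypot(*(b - a)))
            max_step = 0.9 * params.max_speed_cm_s / 30.0
            # smoothstep transit, downgraded to a constant-speed ramp when
            # its peak velocity (1.5 * dist / n) would break the speed cap
            if 1.5 * dist / (n + 1) > 0.8 * max_step:
                w = s
            else:
                w = s * s * (3 - 2 * s)
            seg = a[None, :] + w[:, None] * (b - a)[None, :]
            env = np.minimum(1.0, np.minimum(s, 1 - s) * (n + 1) / 30.0)
            wander = env[:, None] * noise[g0 : g1 + 1]
            # keep the wander's own step well under the speed cap so the
            # transit + wander total respects it
            steps = np.hypot(*np.diff(wander, axis=0, prepend=wander[:1]).T)
            peak = steps.max() if steps.size else 0.0
            if peak > 0.25 * max_step:
                wander *= 0.25 * max_step / peak
            seg += wander
            pos[g0 : g1 + 1] = seg
        pos[:, 0] = np.clip(pos[:, 0], 1.2, side - 1.2)
        pos[:, 1] = np.clip(pos[:, 1], 1.2, side - 1.2)
        all_pos[mouse] = pos

        # headings: smoothed velocity direction, held through slow frames,
        # then overridden where scripts demand
        v = np.diff(pos, axis=0, prepend=pos[:1])
        rho = 0.7
        v = lfilter([1 - rho], [1, -rho], v, axis=0)
        norm = np.hypot(v[:, 0], v[:, 1])
        ang = np.where(norm > 1e-4, np.arctan2(v[:, 1], v[:, 0]), np.nan)
        ang = pd.Series(ang).ffill().fillna(0.0).to_numpy()
        ang = np.where(np.isnan(theta_ov), ang, theta_ov)
        all_theta[mouse] = ang

    rows = []
    for mouse in anchors:
        pos = all_pos[mouse]
        ang = all_theta[mouse]
        wrapped = np.angle(np.exp(1j * ang))
        rows.append(pd.DataFrame({
            "frame": frames,
            "mouse_id": mouse,
            "x_cm": pos[:, 0],
            "y_cm": pos[:, 1],
            "theta_rad": wrapped,
            "a_cm": _BODY_A,
            "b_cm": _BODY_B,
            "nose_x_cm": pos[:, 0] + _NOSE_OFFSET * _BODY_A * np.cos(wrapped),
            "nose_y_cm": pos[:, 1] + _NOSE_OFFSET * _BODY_A * np.sin(wrapped),
        }))
    poses = pd.concat(rows, ignore_index=True)
    return poses.sort_values(["frame", "mouse_id"]).reset_index(drop=True)


def ground_truth(rec: Recording) -> pd.DataFrame:
    """Per-trigger ground-truth table of a synthetic recording."""
    if not rec.metadata.get("synthetic") or "_ground_truth" not in rec.metadata:
        raise ValueError("recording was not produced by generate_recording")
    return rec.metadata["_ground_truth"]
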