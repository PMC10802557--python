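"""Social-interaction detection from body-ellipse overlap.

Two mice are socially interacting while their *social ellipses* overlap:
the tracked body ellipse extended 3 cm along the major axis in front and
behind the animal (semi-minor axis unchanged).  Overlap runs shorter than
six frames are discarded as passing encounters.  Each retained bout is
assigned an initiator:

1. if exactly one mouse is stationary (< 0.023 cm/s) at the bout's first
   frame, the other mouse initiated;
2. if both are moving, the mouse whose ellipse *front point* (boundary
   point along the heading, taken from the center-to-nose direction) first
   pierces the partner's social ellipse initiated;
3. if both fronts pierce within six frames of each other — a head-on
   approach — the initiation is mutual.  Both-stationary bouts are labeled
   mutual and flagged.

The frame-wise overlap decision is an exact algebraic test on the pencil
of the two conics: with both ellipse matrices normalized so the interior
is negative, ``f(lam) = det(lam*E1 + E2)`` is a cubic whose root pattern
separates the configurations — the ellipses are disjoint exactly when the
cubic has two distinct positive real roots.  Tangency (a positive double
root) counts as overlap because the closed interiors share a point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Recording, instantaneous_speed

__all__ = [
    "SocialEllipse",
    "SocialInteraction",
    "fit_social_ellipse",
    "ellipses_overlap",
    "detect_interactions",
    "determine_initiator",
    "interactions_to_dataframe",
    "STATIONARY_SPEED_CM_S",
    "MIN_INTERACTION_FRAMES",
    "SOCIAL_EXTENSION_CM",
]

#: below this instantaneous speed a mouse is considered stationary
STATIONARY_SPEED_CM_S = 0.023
#: shortest overlap run that counts as a social interaction
MIN_INTERACTION_FRAMES = 6
#: front/behind extension of the social ellipse
SOCIAL_EXTENSION_CM = 3.0
#: fronts piercing within this many frames of each other -> mutual
MUTUAL_WINDOW_FRAMES = 6


@dataclass(frozen=True)
class SocialEllipse:
    cx: float
    cy: float
    theta: float  # axis orientation, radians
    a: float  # semi-major (already extended)
    b: float  # semi-minor
    heading_x: float  # unit vector center -> nose
    heading_y: float

    @property
    def front_point(self) -> tuple[float, float]:
        """Boundary point of the ellipse along the heading direction."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        # heading in the ellipse frame
        hx = c * self.heading_x + s * self.heading_y
        hy = -s * self.heading_x + c * self.heading_y
        # boundary intersection of the ray t*(hx, hy)
        t = 1.0 / np.sqrt((hx / self.a) ** 2 + (hy / self.b) ** 2)
        fx, fy = t * hx, t * hy
        return (self.cx + c * fx - s * fy, self.cy + s * fx + c * fy)

    def contains_point(self, x: float, y: float) -> bool:
        c, s = np.cos(self.theta), np.sin(self.theta)
        dx, dy = x - self.cx, y - self.cy
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class SocialInteraction:
    mouse_a: str  # lexicographically smaller id
    mouse_b: str
    start_frame: int
    end_frame: int  # inclusive
    initiator: str  # mouse_a, mouse_b, or "mutual"
    both_stationary: bool = False

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, fps: float) -> float:
        return self.n_frames / fps


def fit_social_ellipse(pose, extension_cm: float = SOCIAL_EXTENSION_CM) -> SocialEllipse:
    """Extend a tracked body ellipse into a social ellipse.

    ``pose`` is a row of the pose table (mapping or namedtuple with the
    pose columns).  The semi-major axis grows by ``extension_cm`` (3 cm in
    front and behind); the semi-minor axis is unchanged.
    """
    get = pose.__getitem__ if hasattr(pose, "__getitem__") else lambda k: getattr(pose, k)
    a, b = float(get("a_cm")), float(get("b_cm"))
    if not (a >= b > 0):
        raise ValueError(f"degenerate ellipse axes a={a}, b={b}")
    hx = float(get("nose_x_cm")) - float(get("x_cm"))
    hy = float(get("nose_y_cm")) - float(get("y_cm"))
    n = float(np.hypot(hx, hy))
    if n < 1e-12:
        # nose on center: fall back to the axial orientation
        hx, hy = np.cos(float(get("theta_rad"))), np.sin(float(get("theta_rad")))
    else:
        hx, hy = hx / n, hy / n
    return SocialEllipse(
        cx=float(get("x_cm")),
        cy=float(get("y_cm")),
        theta=float(get("theta_rad")),
        a=a + extension_cm,
        b=b,
        heading_x=hx,
        heading_y=hy,
    )


# -- algebraic overlap test ------------------------------------------------

def _conic_matrix(cx, cy, theta, a, b):
    """3x3 conic matrices (stacked) with negative interior: X^T M X < 0 inside."""
    cx, cy, theta, a, b = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (cx, cy, theta, a, b))
    )
    c, s = np.cos(theta), np.sin(theta)
    ia2, ib2 = 1.0 / a**2, 1.0 / b**2
    # A2 = R diag(1/a^2, 1/b^2) R^T
    a11 = c * c * ia2 + s * s * ib2
    a12 = c * s * (ia2 - ib2)
    a22 = s * s * ia2 + c * c * ib2
    bx = -(a11 * cx + a12 * cy)
    by = -(a12 * cx + a22 * cy)
    c0 = a11 * cx * cx + 2 * a12 * cx * cy + a22 * cy * cy - 1.0
    M = np.empty(cx.shape + (3, 3))
    M[..., 0, 0] = a11
    M[..., 0, 1] = a12
    M[..., 0, 2] = bx
    M[..., 1, 0] = a12
    M[..., 1, 1] = a22
    M[..., 1, 2] = by
    M[..., 2, 0] = bx
    M[..., 2, 1] = by
    M[..., 2, 2] = c0
    return M


def _pencil_cubic(M1, M2):
    """Coefficients (c3, c2, c1, c0) of det(lam*M1 + M2), batched."""
    c3 = np.linalg.det(M1)
    c0 = np.linalg.det(M2)
    f1 = np.linalg.det(M1 + M2)
    fm1 = np.linalg.det(M2 - M1)
    c2 = 0.5 * (f1 + fm1) - c0
    c1 = 0.5 * (f1 - fm1) - c3
    return c3, c2, c1, c0


def _separated_from_roots(c3, c2, c1, c0, rtol=1e-7):
    """True where the cubic has two distinct positive real roots (disjoint)."""
    n = c3.shape[0] if c3.ndim else 1
    c3, c2, c1, c0 = (np.atleast_1d(v) for v in (c3, c2, c1, c0))
    # monic companion matrices, batched eigenvalue solve
    comp = np.zeros((len(c3), 3, 3))
    comp[:, 1, 0] = 1.0
    comp[:, 2, 1] = 1.0
    comp[:, 0, 2] = -c0 / c3
    comp[:, 1, 2] = -c1 / c3
    comp[:, 2, 2] = -c2 / c3
    roots = np.linalg.eigvals(comp)
    scale = 1.0 + np.abs(roots.real).max(axis=1)
    real = np.abs(roots.imag) <= 1e-7 * scale[:, None]
    pos = real & (roots.real > 0)
    npos = pos.sum(axis=1)
    sep = np.zeros(len(c3), dtype=bool)
    two = npos == 2
    if two.any():
        r = np.where(pos[two], roots.real[two], -np.inf)
        r.sort(axis=1)
        r1, r2 = r[:, -2], r[:, -1]
        sep[two] = (r2 - r1) > rtol * (1.0 + r2)
    if (npos == 3).any():
        # numerically perturbed double root can split into three positives;
        # treat the two closest as the pair and test distinctness
        idx = np.where(npos == 3)[0]
        rr = np.sort(roots.real[idx], axis=1)
        gap = np.minimum(rr[:, 1] - rr[:, 0], rr[:, 2] - rr[:, 1])
        sep[idx] = gap > rtol * (1.0 + rr[:, 2])
    return sep if n > 1 else sep[:1]


def ellipses_overlap(e1: SocialEllipse, e2: SocialEllipse) -> bool:
    """Exact closed-interior intersection test for two ellipses."""
    d = np.hypot(e1.cx - e2.cx, e1.cy - e2.cy)
    if d > e1.a + e2.a:  # cheap reject: beyond maximal reach
        return False
    if d < e1.b + e2.b:  # cheap accept: inside minimal reach
        return True
    M1 = _conic_matrix(e1.cx, e1.cy, e1.theta, e1.a, e1.b)
    M2 = _conic_matrix(e2.cx, e2.cy, e2.theta, e2.a, e2.b)
    c3, c2, c1, c0 = _pencil_cubic(M1[None], M2[None])
    return not bool(_separated_from_roots(c3, c2, c1, c0)[0])


def _overlap_mask(pa: pd.DataFrame, pb: pd.DataFrame, extension_cm: float) -> np.ndarray:
    """Vectorized per-frame overlap of two mice's social ellipses.

    Both pose tables must be frame-aligned (same length, sorted by frame).
    """
    ax, ay = pa["x_cm"].to_numpy(), pa["y_cm"].to_numpy()
    bx, by = pb["x_cm"].to_numpy(), pb["y_cm"].to_numpy()
    aa = pa["a_cm"].to_numpy() + extension_cm
    ba = pb["a_cm"].to_numpy() + extension_cm
    ab = pa["b_cm"].to_numpy()
    bb = pb["b_cm"].to_numpy()
    d = np.hypot(ax - bx, ay - by)
    overlap = d < ab + bb  # certain overlap
    ambiguous = (~overlap) & (d <= aa + ba)
    if ambiguous.any():
        idx = np.flatnonzero(ambiguous)
        M1 = _conic_matrix(
            ax[idx], ay[idx], pa["theta_rad"].to_numpy()[idx], aa[idx], ab[idx]
        )
        M2 = _conic_matrix(
            bx[idx], by[idx], pb["theta_rad"].to_numpy()[idx], ba[idx], bb[idx]
        )
        sep = _separated_from_roots(*_pencil_cubic(M1, M2))
        overlap[idx] = ~sep
    return overlap


# -- bout detection --------------------------------------------------------

def _runs(mask: np.ndarray):
    """(start, end) inclusive index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask) - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_interactions(
    rec: Recording,
    pair_filter: str = "opposite_sex",
    min_frames: int = MIN_INTERACTION_FRAMES,
    extension_cm: float = SOCIAL_EXTENSION_CM,
    method: str = "ellipse",
    distance_threshold_cm: float = 3.0,
    min_duration_s: float = 0.2,
) -> list[SocialInteraction]:
    """Detect social-interaction bouts for the requested mouse pairs.

    ``pair_filter`` selects ``opposite_sex`` (male-female), ``male_male``
    or ``all`` pairs.  The default ``ellipse`` method is the social-ellipse
    overlap definition; ``method="distance"`` is a sensitivity-analysis
    fallback that instead requires the centers to stay within
    ``distance_threshold_cm`` for at least ``min_duration_s``.
    """
    ids = rec.mouse_ids
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sa, sb = rec.sex_of(a), rec.sex_of(b)
            if pair_filter == "opposite_sex" and {sa, sb} != {"M", "F"}:
                continue
            if pair_filter == "male_male" and {sa, sb} != {"M"}:
                continue
            pairs.append(tuple(sorted((a, b))))

    tables = {m: rec.poses_of(m) for m in ids}
    out: list[SocialInteraction] = []
    for a, b in pairs:
        pa, pb = tables[a], tables[b]
        if method == "distance":
            d = np.hypot(
                pa["x_cm"].to_numpy() - pb["x_cm"].to_numpy(),
                pa["y_cm"].to_numpy() - pb["y_cm"].to_numpy(),
            )
            mask = d <= distance_threshold_cm
            min_run = max(min_frames, int(np.ceil(min_duration_s * rec.fps)))
        elif method == "ellipse":
            mask = _overlap_mask(pa, pb, extension_cm)
            min_run = min_frames
        else:
            raise ValueError(f"unknown detection method {method!r}")
        for s, e in _runs(mask):
            if e - s + 1 < min_run:
                continue
            init, both_stat = determine_initiator(a, b, s, pa, pb, rec.fps, extension_cm)
            out.append(
                SocialInteraction(
                    mouse_a=a,
                    mouse_b=b,
                    start_frame=int(s),
                    end_frame=int(e),
                    initiator=init,
                    both_stationary=both_stat,
                )
            )
    out.sort(key=lambda si: (si.start_frame, si.mouse_a, si.mouse_b))
    return out


def determine_initiator(
    mouse_a: str,
    mouse_b: str,
    start_frame: int,
    pa: pd.DataFrame,
    pb: pd.DataFrame,
    fps: float,
    extension_cm: float = SOCIAL_EXTENSION_CM,
    scan_frames: int = 30,
) -> tuple[str, bool]:
    """Initiator of a bout starting at ``start_frame``.

    Returns ``(label, both_stationary)`` with label one of the two mouse
    ids or ``"mutual"``.  See the module docstring for the rule order.
    """
    sa = instantaneous_speed(pa, fps=fps)[start_frame]
    sb = instantaneous_speed(pb, fps=fps)[start_frame]
    a_stat = sa < STATIONARY_SPEED_CM_S
    b_stat = sb < STATIONARY_SPEED_CM_S
    if a_stat and b_stat:
        return "mutual", True
    if a_stat:
        return mouse_b, False
    if b_stat:
        return mouse_a, False

    # both moving: first front to pierce the partner's social ellipse
    end = min(start_frame + scan_frames, len(pa) - 1)
    pierce = {mouse_a: None, mouse_b: None}
    for f in range(start_frame, end + 1):
        ea = fit_social_ellipse(pa.iloc[f], extension_cm)
        eb = fit_social_ellipse(pb.iloc[f], extension_cm)
        if pierce[mouse_a] is None and eb.contains_point(*ea.front_point):
            pierce[mouse_a] = f
        if pierce[mouse_b] is None and ea.contains_point(*eb.front_point):
            pierce[mouse_b] = f
        if pierce[mouse_a] is not None and pierce[mouse_b] is not None:
            break
    fa, fb = pierce[mouse_a], pierce[mouse_b]
    if fa is None and fb is None:
        return "mutual", False
    if fa is None:
        return mouse_b, False
    if fb is None:
        return mouse_a, False
    if abs(fa - fb) <= MUTUAL_WINDOW_FRAMES:
        return "mutual", False
    return (mouse_a if fa < fb else mouse_b), False


def interactions_to_dataframe(interactions) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_a": si.mouse_a,
                "mouse_b": si.mouse_b,
                "start_frame": si.start_frame,
                "end_frame": si.end_frame,
                "initiator": si.initiator,
            }
            for si in interactions
        ],
        columns=["mouse_a", "mouse_b", "start_frame", "end_frame", "initiator"],
    )
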