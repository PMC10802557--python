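import numpy as np
import pytest

from baitswitch.data_model import instantaneous_speed
from baitswitch.interactions import (
    SocialEllipse,
    detect_interactions,
    determine_initiator,
    ellipses_overlap,
    fit_social_ellipse,
)
from conftest import make_recording


def _pose(x, y, theta, a=3.0, b=1.5, nose_frac=0.8):
    return {
        "x_cm": x,
        "y_cm": y,
        "theta_rad": theta,
        "a_cm": a,
        "b_cm": b,
        "nose_x_cm": x + nose_frac * a * np.cos(theta),
        "nose_y_cm": y + nose_frac * a * np.sin(theta),
    }


def _sample_oracle(e1, e2, n=10_000):
    """Boundary-point-sampling overlap oracle."""

    def boundary(e):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        u, v = e.a * np.cos(t), e.b * np.sin(t)
        c, s = np.cos(e.theta), np.sin(e.theta)
        return e.cx + c * u - s * v, e.cy + s * u + c * v

    def inside(e, x, y):
        c, s = np.cos(e.theta), np.sin(e.theta)
        dx, dy = x - e.cx, y - e.cy
        u, v = c * dx + s * dy, -s * dx + c * dy
        return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0

    x1, y1 = boundary(e1)
    x2, y2 = boundary(e2)
    return bool(
        inside(e2, x1, y1).any()
        or inside(e1, x2, y2).any()
        or inside(e1, e2.cx, e2.cy)
        or inside(e2, e1.cx, e1.cy)
    )


class TestSocialEllipse:
    def test_extension(self):
        se = fit_social_ellipse(_pose(10, 20, 0.3))
        assert se.a == pytest.approx(6.0)  # 3 cm body + 3 cm extension
        assert se.b == pytest.approx(1.5)
        assert (se.cx, se.cy) == (10, 20)

    def test_rotation_equivariance(self):
        for phi in (0.0, 0.7, -2.1):
            se = fit_social_ellipse(_pose(0, 0, phi))
            assert se.theta == pytest.approx(phi)
            assert se.a == pytest.approx(6.0)
            assert se.b == pytest.approx(1.5)

    def test_front_point_on_boundary_along_heading(self):
        se = fit_social_ellipse(_pose(5, 5, 0.0))
        fx, fy = se.front_point
        # heading is +x, so the front point is center + semi-major along x
        assert (fx, fy) == (pytest.approx(5 + se.a), pytest.approx(5.0))

    def test_degenerate_axes_error(self):
        with pytest.raises(ValueError):
            fit_social_ellipse(_pose(0, 0, 0, a=1.0, b=2.0))


class TestOverlap:
    def test_identical_true(self):
        e = SocialEllipse(3, 4, 0.5, 6, 1.5, 1, 0)
        assert ellipses_overlap(e, e)

    def test_far_apart_false(self):
        e1 = SocialEllipse(0, 0, 0, 6, 1.5, 1, 0)
        e2 = SocialEllipse(100, 0, 0, 6, 1.5, 1, 0)
        assert not ellipses_overlap(e1, e2)

    def test_containment_true(self):
        big = SocialEllipse(0, 0, 0, 10, 5, 1, 0)
        small = SocialEllipse(1, 0, 0.3, 2, 1, 1, 0)
        assert ellipses_overlap(big, small)
        assert ellipses_overlap(small, big)

    @pytest.mark.parametrize("gap,expected", [(0.01, False), (-0.01, True)])
    def test_near_tangency_matches_oracle(self, gap, expected):
        e1 = SocialEllipse(0, 0, 0, 3, 1.5, 1, 0)
        e2 = SocialEllipse(5 + gap, 0, 0, 2, 1, 1, 0)
        assert ellipses_overlap(e1, e2) is expected
        assert _sample_oracle(e1, e2) is expected

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(42)
        mismatch = 0
        for _ in range(200):
            def re():
                a = rng.uniform(1.5, 7.0)
                return SocialEllipse(
                    rng.uniform(0, 25), rng.uniform(0, 25),
                    rng.uniform(-np.pi, np.pi), a, rng.uniform(0.8, a), 1, 0,
                )
            e1, e2 = re(), re()
            mismatch += ellipses_overlap(e1, e2) != _sample_oracle(e1, e2)
        assert mismatch == 0


def _approach_recording(
    overlap_frames, n=120, meet_frame=60, drift_a=0.0, theta_a=0.0
):
    """M1 parked near x=30; F1 approaches from the right along x, dwells
    within contact for `overlap_frames`, then leaves.  Head-to-head the
    social ellipses reach 12 cm, so clearance is kept above 13 cm."""
    xa = np.full(n, 30.0) + drift_a * np.arange(n)
    contact = 30.0 + 6.0
    xb = np.empty(n)
    for f in range(n):
        if f < meet_frame:
            xb[f] = contact + 7.5 + 0.5 * (meet_frame - f)
        elif f < meet_frame + overlap_frames:
            xb[f] = contact - 1.0
        else:
            xb[f] = contact + 7.5 + 0.5 * (f - meet_frame - overlap_frames)
    pos = {
        "M1": np.stack([xa, np.full(n, 30.0)], axis=1),
        "F1": np.stack([xb, np.full(n, 30.0)], axis=1),
        "M2": np.stack([np.full(n, 5.0), np.full(n, 70.0)], axis=1),
        "F2": np.stack([np.full(n, 70.0), np.full(n, 70.0)], axis=1),
    }
    theta = {"M1": np.full(n, theta_a), "F1": np.full(n, np.pi)}
    return make_recording(pos, theta=theta)


class TestDetect:
    def test_far_apart_mice_no_interactions(self):
        n = 50
        pos = {
            "M1": np.tile([10.0, 10.0], (n, 1)),
            "F1": np.tile([70.0, 70.0], (n, 1)),
            "M2": np.tile([10.0, 70.0], (n, 1)),
            "F2": np.tile([70.0, 10.0], (n, 1)),
        }
        assert detect_interactions(make_recording(pos), "opposite_sex") == []

    def test_five_frame_overlap_discarded(self):
        rec = _approach_recording(overlap_frames=5)
        assert detect_interactions(rec, "opposite_sex") == []

    def test_twenty_frame_overlap_matches_frame_oracle(self):
        rec = _approach_recording(overlap_frames=20)
        out = detect_interactions(rec, "opposite_sex")
        assert len(out) == 1
        si = out[0]
        # brute-force per-frame oracle over the involved pair
        pa, pb = rec.poses_of("F1"), rec.poses_of("M1")
        mask = np.array([
            ellipses_overlap(
                fit_social_ellipse(pa.iloc[f]), fit_social_ellipse(pb.iloc[f])
            )
            for f in range(rec.n_frames)
        ])
        frames = np.flatnonzero(mask)
        assert si.start_frame == frames[0]
        assert si.end_frame == frames[-1]
        assert si.n_frames >= 20

    def test_six_frame_rule_on_synthetic_data(self, default_recording, default_interactions):
        assert default_interactions, "synthetic recording should contain interactions"
        assert all(si.n_frames >= 6 for si in default_interactions)
        assert all(si.mouse_a < si.mouse_b for si in default_interactions)

    def test_extension_monotonicity(self, default_recording):
        rec, _ = default_recording
        t3 = sum(
            si.n_frames for si in detect_interactions(rec, "opposite_sex", extension_cm=3.0)
        )
        t45 = sum(
            si.n_frames for si in detect_interactions(rec, "opposite_sex", extension_cm=4.5)
        )
        assert t45 >= t3

    def test_distance_method_fallback(self):
        rec = _approach_recording(overlap_frames=20)
        out = detect_interactions(
            rec, "opposite_sex", method="distance", distance_threshold_cm=8.0
        )
        assert len(out) == 1
        assert out[0].n_frames >= 6


class TestInitiator:
    def test_stationary_partner_makes_other_initiator(self):
        rec = _approach_recording(overlap_frames=20)
        out = detect_interactions(rec, "opposite_sex")
        # M1 never moves (speed 0 < 0.023 cm/s); F1 approaches
        assert out[0].initiator == "F1"
        assert not out[0].both_stationary

    def test_front_piercing_when_both_move(self):
        # both drift, but F1 closes the distance nose-first while M1 faces away
        rec = _approach_recording(overlap_frames=25, drift_a=0.01, theta_a=np.pi)
        sa = instantaneous_speed(rec.poses_of("M1"), fps=30)
        assert (sa[1:] > 0.023).all()  # genuinely above the stationary cutoff
        out = detect_interactions(rec, "opposite_sex")
        assert out[0].initiator == "F1"

    def test_head_on_symmetric_approach_is_mutual(self):
        n = 80
        mid = 35.0
        xa = np.minimum(mid - 5.5, 10.0 + 0.6 * np.arange(n))
        xb = np.maximum(mid + 5.5, 60.0 - 0.6 * np.arange(n))
        pos = {
            "M1": np.stack([xa, np.full(n, 30.0)], axis=1),
            "F1": np.stack([xb, np.full(n, 30.0)], axis=1),
            "M2": np.tile([5.0, 70.0], (n, 1)),
            "F2": np.tile([70.0, 70.0], (n, 1)),
        }
        theta = {"M1": np.zeros(n), "F1": np.full(n, np.pi)}
        rec = make_recording(pos, theta=theta)
        out = detect_interactions(rec, "opposite_sex")
        assert len(out) == 1
        assert out[0].initiator == "mutual"

    def test_both_stationary_flagged_mutual(self):
        n = 40
        pos = {
            "M1": np.tile([30.0, 30.0], (n, 1)),
            "F1": np.tile([36.0, 30.0], (n, 1)),
            "M2": np.tile([5.0, 70.0], (n, 1)),
            "F2": np.tile([70.0, 70.0], (n, 1)),
        }
        theta = {"M1": np.zeros(n), "F1": np.full(n, np.pi)}
        rec = make_recording(pos, theta=theta)
        out = detect_interactions(rec, "opposite_sex")
        assert len(out) == 1
        assert out[0].initiator == "mutual"
        assert out[0].both_stationary


def test_overlap_agrees_with_polygonal_geometry_library():
    """Cross-check the conic test against shapely polygon intersection."""
    shapely = pytest.importorskip("shapely")
    from shapely.geometry import Polygon

    def poly(e, n=256):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        u, v = e.a * np.cos(t), e.b * np.sin(t)
        c, s = np.cos(e.theta), np.sin(e.theta)
        return Polygon(zip(e.cx + c * u - s * v, e.cy + s * u + c * v))

    rng = np.random.default_rng(11)
    for _ in range(300):
        def re():
            a = rng.uniform(1.5, 7.0)
            return SocialEllipse(
                rng.uniform(0, 25), rng.uniform(0, 25),
                rng.uniform(-np.pi, np.pi), a, rng.uniform(0.8, a), 1, 0,
            )
        e1, e2 = re(), re()
        ours = ellipses_overlap(e1, e2)
        theirs = poly(e1).intersects(poly(e2))
        if ours != theirs:
            # polygonal approximation can misjudge a thin tangency band;
            # tolerate only genuinely marginal cases
            d = poly(e1).distance(poly(e2))
            assert d < 0.02, (e1, e2, ours, theirs, d)
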