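import numpy as np
import pytest

from baitswitch.circstats import (
    ZoneSpec,
    circular_summary,
    default_zones,
    heading_angle_to_target,
    orientation_difference,
    watson_u2,
    zone_latency,
)
from baitswitch.data_model import BehaviorEvent
from conftest import make_recording


class TestHeadingAngle:
    @pytest.mark.parametrize(
        "female,expected",
        [((20, 10), 0.0), ((0, 10), 180.0), ((10, 20), 90.0), ((10, 0), 90.0)],
    )
    def test_cardinal_cases(self, female, expected):
        # male at (10, 10) facing +x
        ang = heading_angle_to_target((10, 10), (12, 10), female)
        assert ang == pytest.approx(expected)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            c, nose, f = rng.uniform(0, 40, (3, 2))
            a0 = heading_angle_to_target(c, nose, f)
            phi = rng.uniform(-np.pi, np.pi)
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            t = rng.uniform(-30, 30, 2)
            a1 = heading_angle_to_target(R @ c + t, R @ nose + t, R @ f + t)
            assert a1 == pytest.approx(a0, abs=1e-9)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            heading_angle_to_target((1, 1), (1, 1), (5, 5))


class TestOrientationDifference:
    @pytest.mark.parametrize(
        "t1,t2,expected",
        [
            (0.0, 0.0, 0.0),
            (0.0, np.pi, 180.0),
            (np.radians(-3.0), np.radians(357.0), 0.0),
            (np.radians(10), np.radians(350), 20.0),
        ],
    )
    def test_values(self, t1, t2, expected):
        assert orientation_difference(t1, t2) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c = rng.uniform(-np.pi, np.pi, 3)
            assert orientation_difference(a, b) == pytest.approx(
                orientation_difference(b, a)
            )
            assert (
                orientation_difference(a, c)
                <= orientation_difference(a, b) + orientation_difference(b, c) + 1e-9
            )


class TestCircularSummary:
    def test_constant_sample(self):
        s = circular_summary([41.34] * 7)
        assert s.median_deg == pytest.approx(41.34)
        assert s.variance == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_clusters_variance_near_one(self):
        s = circular_summary([0.0] * 50 + [180.0] * 50)
        assert s.variance == pytest.approx(1.0, abs=1e-9)

    def test_von_mises_median_recovery(self):
        rng = np.random.default_rng(2)
        sample = np.degrees(rng.vonmises(np.radians(75.0), 4.0, 10_000))
        s = circular_summary(sample)
        assert abs(s.median_deg - 75.0) < 2.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            circular_summary([])


class TestWatsonU2:
    def test_identical_point_mass_p_one(self):
        u2, p = watson_u2([10.0] * 5, [10.0] * 7)
        assert (u2, p) == (0.0, 1.0)

    def test_same_sample_not_significant(self):
        rng = np.random.default_rng(3)
        s = np.degrees(rng.vonmises(0, 2, 60))
        u2, p = watson_u2(s, s.copy(), n_permutations=500, seed=0)
        assert p > 0.2

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        s1 = np.degrees(rng.vonmises(0, 2, 40))
        s2 = np.degrees(rng.vonmises(1, 2, 50))
        u2a, _ = watson_u2(s1, s2, n_permutations=10, seed=0)
        u2b, _ = watson_u2(s1 + 123.4, s2 + 123.4, n_permutations=10, seed=0)
        assert u2b == pytest.approx(u2a, rel=1e-9)

    def test_distinct_distributions_detected(self):
        rng = np.random.default_rng(5)
        s1 = np.degrees(rng.vonmises(0.0, 4.0, 100))
        s2 = np.degrees(rng.vonmises(np.pi / 2, 4.0, 100))
        _, p = watson_u2(s1, s2, n_permutations=1000, seed=0)
        assert p < 0.01

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            watson_u2([], [1.0])


class TestZones:
    def test_default_zone_layout(self):
        from baitswitch.data_model import ArenaSpec

        zones = default_zones(ArenaSpec())
        names = [z.name for z in zones]
        assert names == ["zone1", "zone2", "zone3", "zone4", "zone5"]
        z4 = zones[3]
        assert (z4.center_x_cm, z4.center_y_cm) == (76.2 / 2, 76.2 / 2)
        assert all(z.radius_cm == 6.0 for z in zones)

    def _rec_with_trigger(self, male_traj, n):
        pos = {
            "M1": np.tile([70.0, 15.0], (n, 1)),
            "M2": male_traj,
            "F1": np.tile([15.0, 70.0], (n, 1)),
            "F2": np.tile([70.0, 70.0], (n, 1)),
        }
        trig = BehaviorEvent("chase", "M1", "M2", 0, 29)
        return make_recording(pos, events=[trig]), [trig]

    def test_inside_zone_at_trigger_end_is_zero(self):
        n = 120
        zone = ZoneSpec("z", 30.0, 30.0)
        traj = np.tile([30.0, 30.0], (n, 1))
        rec, trig = self._rec_with_trigger(traj, n)
        res = zone_latency(rec, [zone], trig, role="aggressed")
        r = [x for x in res if x.mouse_id == "M2"][0]
        assert r.latencies_s.tolist() == [0.0]

    def test_straight_path_kinematic_latency(self):
        # nose starts 10 cm outside the boundary, moves at 5 cm/s -> 2 s
        n = 240
        fps = 30.0
        zone = ZoneSpec("z", 40.0, 30.0)
        x_nose_start = 40.0 - 6.0 - 10.0
        x_center_start = x_nose_start - 0.8 * 3.0  # nose offset
        xs = x_center_start + (5.0 / fps) * np.arange(n)
        traj = np.stack([xs, np.full(n, 30.0)], axis=1)
        rec, trig = self._rec_with_trigger(traj, n)
        res = zone_latency(rec, [zone], trig, role="aggressed")
        r = [x for x in res if x.mouse_id == "M2"][0]
        # path runs from frame 0; trigger ends at frame 29 (1 s in), by which
        # time the nose has closed 5 cm; remaining 5 cm at 5 cm/s -> 1 s
        assert r.mean_s == pytest.approx(1.0, abs=2 / fps)

    def test_never_entering_counts_exclusion(self):
        n = 120
        zone = ZoneSpec("z", 40.0, 30.0)
        traj = np.tile([10.0, 10.0], (n, 1))
        rec, trig = self._rec_with_trigger(traj, n)
        res = zone_latency(rec, [zone], trig, role="aggressed")
        r = [x for x in res if x.mouse_id == "M2"][0]
        assert r.latencies_s.size == 0
        assert r.n_excluded == 1

    def test_zone_outside_arena_errors(self):
        n = 60
        traj = np.tile([10.0, 10.0], (n, 1))
        rec, trig = self._rec_with_trigger(traj, n)
        with pytest.raises(ValueError):
            zone_latency(rec, [ZoneSpec("bad", 100.0, 10.0)], trig)
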