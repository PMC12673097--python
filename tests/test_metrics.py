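"""Session metrics, social interaction ratios, and the engagement index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sitpheno as sp
from sitpheno.metrics import FLAG_UNDEFINED, FLAG_ZERO_DENOM, build_profile

from conftest import make_track

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestSessionMetrics:
    def test_time_in_siz_is_count_over_fps(self, arena):
        inside = np.tile([210.0, 140.0], (150, 1))  # SIZ interior
        outside = np.tile([210.0, 400.0], (150, 1))
        xy = np.vstack([inside, outside])
        track = make_track(xy, xy, fps=30.0)
        m = sp.session_metrics(track, arena, session_minutes=None)
        assert m.time_in_siz == pytest.approx(5.0)

    def test_stationary_nose_distance(self, arena):
        # nose parked 100 px from the POI at (210, 100); scale 10 px/cm
        nose = np.tile([210.0, 200.0], (60, 1))
        center = np.tile([210.0, 400.0], (60, 1))
        track = make_track(center, nose)
        m = sp.session_metrics(track, arena, session_minutes=None)
        assert m.mean_dist_poi == pytest.approx(0.10)
        assert m.total_distance == 0.0

    def test_total_distance_matches_brute_force(self, arena):
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 5, (500, 2)), axis=0) + 210.0
        xy = np.clip(xy, 0, 420)
        track = make_track(xy, xy)
        m = sp.session_metrics(track, arena, session_minutes=None)
        oracle = 0.0
        for i in range(1, len(xy)):
            oracle += math.hypot(*(xy[i] - xy[i - 1])) / arena.scale / 100.0
        assert m.total_distance == pytest.approx(oracle, abs=1e-9)

    def test_matches_per_frame_oracle_on_simulated_track(self, arena):
        track = sp.simulate_session(
            sp.PRESETS["resilient_like"], arena=arena, session="S2",
            session_minutes=0.5, seed=9,
        )
        m = sp.session_metrics(track, arena, session_minutes=None)
        center, nose = track.xy("center"), track.xy("nose")
        t_oracle = (
            sum(
                brute := [
                    sp.in_zone(c, arena.siz_polygon_px) for c in center
                ]
            )
            / track.fps
        )
        d_oracle = np.mean(
            [math.hypot(*(n - arena.poi_px)) for n in nose]
        ) / arena.scale / 100.0
        assert m.time_in_siz == pytest.approx(t_oracle, abs=1e-9)
        assert m.mean_dist_poi == pytest.approx(d_oracle, abs=1e-9)

    def test_flagged_frames_excluded_from_mean_distance(self, arena):
        nose = np.tile([210.0, 200.0], (10, 1))  # 100 px away
        nose[5] = [210.0, 300.0]  # 200 px away, to be excluded
        track = make_track(np.tile([0.0, 400.0], (10, 1)), nose)
        m = sp.session_metrics(
            track, arena, flagged_frames=np.array([5]), session_minutes=None
        )
        assert m.mean_dist_poi == pytest.approx(0.10)
        assert m.n_flagged_frames == 1

    def test_session_trimming(self, arena):
        xy = np.tile([210.0, 140.0], (300, 1))
        track = make_track(xy, xy, fps=30.0)
        m = sp.session_metrics(track, arena, session_minutes=5 / 60)  # 5 s
        assert m.n_frames == 150
        assert m.time_in_siz == pytest.approx(5.0)


class TestRatios:
    @pytest.mark.parametrize(
        "s2, s1, expected",
        [(60.0, 30.0, 2.0), (30.0, 30.0, 1.0), (0.0, 30.0, 0.0)],
    )
    def test_type_a_values(self, s2, s1, expected):
        val, flags = sp.sir_type_a(s2, s1)
        assert val == pytest.approx(expected)
        assert not flags

    def test_type_a_zero_denominator(self):
        val, flags = sp.sir_type_a(10.0, 0.0)
        assert math.isinf(val) and FLAG_ZERO_DENOM in flags
        val, flags = sp.sir_type_a(0.0, 0.0)
        assert math.isnan(val) and FLAG_UNDEFINED in flags

    @pytest.mark.parametrize(
        "s2, s1, expected",
        [(30.0, 30.0, 0.5), (60.0, 0.0, 1.0), (0.0, 60.0, 0.0)],
    )
    def test_type_b_values(self, s2, s1, expected):
        val, flags = sp.sir_type_b(s2, s1)
        assert val == pytest.approx(expected)
        assert not flags

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sp.sir_type_a(-1.0, 1.0)
        with pytest.raises(ValueError):
            sp.sir_type_b(1.0, -1.0)

    def test_type_b_is_monotone_transform_of_type_a(self):
        """b = a / (1 + a) across 1,000 random positive session pairs."""
        rng = np.random.default_rng(2)
        pairs = rng.uniform(1e-3, 1e3, size=(1000, 2))
        for s2, s1 in pairs:
            a, _ = sp.sir_type_a(s2, s1)
            b, _ = sp.sir_type_b(s2, s1)
            assert b == pytest.approx(a / (1 + a), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(s1=positive, s2=positive, c=positive)
    def test_type_b_scale_invariance(self, s1, s2, c):
        """Multiplying both sessions by c > 0 leaves the type-B ratio
        unchanged — so distance ratios do not depend on pixel calibration."""
        b0, _ = sp.sir_type_b(s2, s1)
        b1, _ = sp.sir_type_b(c * s2, c * s1)
        assert b1 == pytest.approx(b0, rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(s1=positive, s2=positive)
    def test_swap_sessions_antisymmetry(self, s1, s2):
        b, _ = sp.sir_type_b(s2, s1)
        b_swapped, _ = sp.sir_type_b(s1, s2)
        assert b_swapped == pytest.approx(1.0 - b, abs=1e-12)


class TestSEI:
    @pytest.mark.parametrize(
        "tb, db, expected",
        [(0.5, 0.5, 1.0), (0.6, 0.4, 1.5), (0.0, 0.5, 0.0)],
    )
    def test_values(self, tb, db, expected):
        val, flags = sp.social_engagement_index(tb, db)
        assert val == pytest.approx(expected)
        assert not flags

    def test_zero_denominator_flagged(self):
        val, flags = sp.social_engagement_index(0.5, 0.0)
        assert math.isnan(val) and flags

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tb=st.floats(0.01, 0.99),
        db=st.floats(0.01, 0.99),
        eps=st.floats(1e-4, 0.009),
    )
    def test_monotonicity(self, tb, db, eps):
        """SEI strictly increases in the time ratio and strictly decreases
        in the distance ratio."""
        base, _ = sp.social_engagement_index(tb, db)
        up_t, _ = sp.social_engagement_index(tb + eps, db)
        up_d, _ = sp.social_engagement_index(tb, db + eps)
        assert up_t > base
        assert up_d < base


def _metrics(animal, session, t, d, fps=30.0, n=4500):
    return sp.SessionMetrics(
        animal_id=animal, session=session, time_in_siz=t,
        mean_dist_poi=d, total_distance=1.0, n_frames=n, fps=fps,
    )


class TestBuildProfile:
    def test_combines_all_ratios(self):
        p = build_profile(
            _metrics("a", "S1", 30.0, 0.2), _metrics("a", "S2", 60.0, 0.1)
        )
        assert p.time_sir_a == pytest.approx(2.0)
        assert p.time_sir_b == pytest.approx(2 / 3)
        assert p.dist_sir_a == pytest.approx(0.5)
        assert p.dist_sir_b == pytest.approx(1 / 3)
        assert p.sei == pytest.approx((2 / 3) / (1 / 3))

    def test_mismatched_animals_rejected(self):
        with pytest.raises(ValueError):
            build_profile(
                _metrics("a", "S1", 1.0, 0.1), _metrics("b", "S2", 1.0, 0.1)
            )

    def test_degenerate_sessions_flagged_not_raised(self):
        p = build_profile(
            _metrics("a", "S1", 0.0, 0.2), _metrics("a", "S2", 0.0, 0.1)
        )
        assert math.isnan(p.time_sir_b)
        assert any("undefined" in f for f in p.flags)
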