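"""Gliding-window speeds, persistence, profiles and event maps."""

import numpy as np
import pytest

from granuletrack import (LinkingParams, classify, event_and_growth_maps,
                          fluorescence_profile, local_speeds,
                          merge_count_vs_fluorescence, persistence,
                          summarize_track, track_spots)
from granuletrack.core import TrackPath

from conftest import truth_to_spots

DT = 20.0  # s/frame


def path(xy, fluo=None):
    xy = np.asarray(xy, dtype=float)
    return TrackPath(np.arange(len(xy)), xy, fluo)


class TestLocalSpeeds:
    def test_constant_velocity_line(self):
        # 0.5 µm/min along x: one frame step = 0.5/3 µm
        xy = [(0.5 / 3.0 * k, 0.0) for k in range(20)]
        prof = local_speeds(path(xy), DT)
        assert len(prof) == 20 - 7
        assert prof.local_track_speed == pytest.approx([0.5] * len(prof))
        assert prof.local_advance_speed == pytest.approx([0.5] * len(prof))
        assert prof.speed_ratio == pytest.approx([1.0] * len(prof))
        # overall track speed of a constant-velocity track equals the
        # local track speed at every point
        s = summarize_track(path(xy), DT)
        assert s.overall_track_speed == pytest.approx(0.5)

    def test_zigzag_has_zero_advance(self):
        xy = [(0.1 * (k % 2), 0.0) for k in range(21)]
        prof = local_speeds(path(xy), DT)
        # 8-spot window: 7 steps, net displacement 0.1 (odd step count)
        assert np.all(prof.local_advance_speed <= 0.1 / (7 * DT / 60) + 1e-9)
        assert np.all(prof.speed_ratio < 0.15)

    def test_profile_matches_bruteforce_recomputation(self, rng):
        xy = np.cumsum(rng.normal(0, 0.1, size=(30, 2)), axis=0)
        t = path(xy)
        prof = local_speeds(t, DT)
        win_min = 7 * DT / 60.0
        for k, centre in enumerate(range(3, 30 - 4)):
            seg = xy[centre - 3:centre + 5]
            track = sum(np.linalg.norm(seg[i + 1] - seg[i])
                        for i in range(7)) / win_min
            adv = np.linalg.norm(seg[-1] - seg[0]) / win_min
            assert prof.local_track_speed[k] == pytest.approx(track)
            assert prof.local_advance_speed[k] == pytest.approx(adv)

    def test_short_track_gives_empty_profile(self):
        prof = local_speeds(path([(0, 0)] * 7), DT)
        assert len(prof) == 0

    def test_advance_never_exceeds_track_speed(self, rng):
        for _ in range(20):
            xy = np.cumsum(rng.normal(0, 0.2, size=(25, 2)), axis=0)
            prof = local_speeds(path(xy), DT)
            assert np.all(prof.local_advance_speed
                          <= prof.local_track_speed + 1e-12)
            ok = np.isfinite(prof.speed_ratio)
            assert np.all((prof.speed_ratio[ok] >= 0)
                          & (prof.speed_ratio[ok] <= 1 + 1e-12))


class TestPersistence:
    def test_straight_path_is_one(self):
        assert persistence(path([(k, 0) for k in range(10)])) == \
            pytest.approx(1.0)

    def test_l_path_is_five_sevenths(self):
        p = path([(0, 0), (3, 0), (3, 4)])
        assert persistence(p) == pytest.approx(5.0 / 7.0)

    def test_closed_loop_is_zero(self):
        p = path([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert persistence(p) == pytest.approx(0.0)

    @pytest.mark.parametrize("angle", [0.3, 1.2, 2.9])
    def test_invariant_under_rigid_motion(self, angle, rng):
        xy = np.cumsum(rng.normal(0, 0.3, size=(15, 2)), axis=0)
        c, s = np.cos(angle), np.sin(angle)
        rot = xy @ np.array([[c, -s], [s, c]]) + [3.7, -1.2]
        assert persistence(path(rot)) == pytest.approx(
            persistence(path(xy)), rel=1e-9)

    def test_zero_path_is_nan(self):
        assert np.isnan(persistence(path([(1, 1), (1, 1), (1, 1)])))


class TestFluorescenceProfile:
    def test_triangular_profile_aligns_peak_at_zero(self):
        fluo = np.concatenate([np.linspace(0.1, 1.0, 11),
                               np.linspace(0.9, 0.0, 10)])
        t = path(np.zeros((21, 2)), fluo * 500)
        prof = fluorescence_profile([t], DT)
        peak = prof.loc[prof["t_min"] == 0.0]
        assert len(peak) == 1
        assert peak["mean"].iloc[0] == pytest.approx(1.0)

    def test_identical_tracks_have_zero_sd(self):
        fluo = np.concatenate([np.linspace(0.1, 1.0, 8),
                               np.linspace(0.8, 0.1, 7)])
        tracks = [path(np.zeros((15, 2)), fluo) for _ in range(2)]
        prof = fluorescence_profile(tracks, DT)
        assert np.all(prof["sd"] == 0.0)
        assert np.all(prof["n"] == 2)

    def test_simulator_cohort_shows_slow_growth_fast_decay(self, small_movie):
        """The mean peak-aligned profile mirrors the generating law:
        gradual sigmoidal rise, faster near-linear fall."""
        tracks = [g.as_track_path() for g in small_movie.truth
                  if g.end_reason == "dissolved"
                  and g.death_frame - g.birth_frame >= 8]
        assert len(tracks) >= 5
        prof = fluorescence_profile(tracks, DT)
        t = prof["t_min"].to_numpy()
        m = prof["mean"].to_numpy()
        peak_val = m[np.argmin(np.abs(t))]
        assert peak_val == pytest.approx(1.0, abs=0.05)
        # compare growth vs decay rate on the window where every track
        # contributes (the tails suffer survivorship distortion)
        n = prof["n"].to_numpy()
        full = n == n.max()
        t_lo = t[full].min()
        t_hi = t[full].max()
        T = min(-t_lo, t_hi)
        assert T > 0
        m_before = m[np.argmin(np.abs(t + T))]
        m_after = m[np.argmin(np.abs(t - T))]
        rise = peak_val - m_before
        fall = peak_val - m_after
        assert fall > rise  # dissolution is faster than growth


class TestEventMaps:
    def _graph(self, movie):
        spots, _ = truth_to_spots(movie)
        g = track_spots(spots, LinkingParams(), quality_threshold=None)
        classify(g, DT)
        return g

    def test_solo_track_has_one_appear_one_disappear(self):
        from granuletrack.tracking import TrackGraph
        from granuletrack.detect import Spot
        g = TrackGraph()
        for f in range(12):
            g.add_spot(f, Spot(f, 0.1 * f, 0.0, 10.0, 100.0, 0.5))
            if f:
                g.add_edge(f - 1, f, "link")
        events, growth = event_and_growth_maps(g)
        assert list(events["kind"]) == ["appear", "disappear"]
        assert len(growth) == 11

    def test_merge_events_at_target_positions(self, small_movie):
        g = self._graph(small_movie)
        events, _ = event_and_growth_maps(g)
        merges = events[events["kind"] == "merge"]
        assert len(merges) == len(g.merge_edges())
        target_pos = {(round(g.spot(v).x, 6), round(g.spot(v).y, 6))
                      for _, v in g.merge_edges()}
        got = {(round(r.x_um, 6), round(r.y_um, 6))
               for r in merges.itertuples()}
        assert got == target_pos

    def test_appear_outer_disappear_inner(self, small_movie):
        g = self._graph(small_movie)
        cfg = small_movie.config
        centre = (small_movie.stack.shape[1] - 1) / 2 * cfg.pixel_size
        events, _ = event_and_growth_maps(g)
        interior = events[(events["frame"] > 0)
                          & (events["frame"] < cfg.n_frames - 1)]

        def radius(row):
            return np.hypot(row.x_um - centre, row.y_um - centre)

        appear_r = [radius(r) for r in
                    interior[interior["kind"] == "appear"].itertuples()]
        disappear_r = [radius(r) for r in
                       interior[interior["kind"] == "disappear"].itertuples()]
        boundary = cfg.zone_inner_radius + cfg.zone_width / 3.0
        assert appear_r and disappear_r
        assert np.mean(np.array(appear_r) >= boundary - 1e-6) >= 0.9
        assert np.mean(np.array(disappear_r) <= boundary + 1e-6) >= 0.9


class TestMergeVsFluorescence:
    def test_counts_and_linearity(self, small_movie):
        spots, _ = truth_to_spots(small_movie)
        g = track_spots(spots, LinkingParams(), quality_threshold=None)
        total, n_merges = merge_count_vs_fluorescence(g)
        assert n_merges == len(g.merge_edges())
        # doubling intensities doubles the fluorescence, not the merges
        doubled = [[type(s)(s.frame, s.x, s.y, s.quality,
                            2 * s.fluorescence, s.radius) for s in fr]
                   for fr in spots]
        g2 = track_spots(doubled, LinkingParams(), quality_threshold=None)
        total2, n2 = merge_count_vs_fluorescence(g2)
        assert total2 == pytest.approx(2 * total, rel=1e-9)
        assert n2 == n_merges

    def test_merge_rate_increases_with_density(self):
        from granuletrack import SimulationConfig, simulate
        base = dict(cell_radius=12.0, zone_width=8.0, mean_lifetime=10.0,
                    lifetime_sd=1.5, n_frames=40, rng_seed=9)
        low = simulate(SimulationConfig(nucleation_rate=1.0, **base))
        high = simulate(SimulationConfig(nucleation_rate=10.0, **base))
        n_low = sum(g.merged_into is not None for g in low.truth)
        n_high = sum(g.merged_into is not None for g in high.truth)
        assert n_high > n_low
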