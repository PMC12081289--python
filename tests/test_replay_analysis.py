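"""Rate maps, event segmentation, Bayesian decoding, change-map statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from compmap import replay_analysis as ana
from compmap import synthetic_population as syn


def _uniform_track(duration=60.0, dt=0.02, arena=200.0, seed=0):
    rng = np.random.default_rng(seed)
    cfg = syn.PopulationConfig(arena_cm=arena)
    return syn.simulate_foraging_track(cfg, rng, duration_s=duration, dt_s=dt)


class TestRateMaps:
    def test_single_bin_spikes_give_single_peak(self):
        track = _uniform_track(duration=1200.0, arena=100.0)
        # spikes whenever the animal is near one target bin
        target = np.array([50.0, 50.0])
        near = (
            np.hypot(track.x_cm - target[0], track.y_cm - target[1]) < 4.0
        )
        spikes = pd.DataFrame({"cell": 0, "time_s": track.time_s[near].values})
        assert len(spikes) >= 3
        rm = ana.compute_ratemap(spikes, track, arena_cm=100.0)
        peak = np.unravel_index(np.nanargmax(rm.rate), rm.rate.shape)
        peak_cm = (np.array(peak[::-1]) + 0.5) * rm.bin_cm
        assert np.linalg.norm(peak_cm - target) < 10.0

    def test_homogeneous_poisson_rate_recovered(self, rng):
        """A constant-rate cell's map is flat at its true rate (+-3 s.e.)."""
        track = _uniform_track(duration=600.0, arena=50.0, seed=1)
        rate_true = 8.0
        n = rng.poisson(rate_true * 600.0)
        spikes = pd.DataFrame(
            {"cell": 0, "time_s": np.sort(rng.uniform(0, 600.0, n))}
        )
        rm = ana.compute_ratemap(spikes, track, arena_cm=50.0)
        vals = rm.rate[rm.mask]
        assert len(vals) > 100
        assert abs(np.mean(vals) - rate_true) < 1.0

    def test_ratio_invariance_under_doubling(self):
        track = _uniform_track(duration=100.0, seed=2)
        spikes = pd.DataFrame(
            {"cell": 0, "time_s": np.linspace(1, 99, 300)}
        )
        rm1 = ana.compute_ratemap(spikes, track)
        track2 = pd.concat(
            [track, track.assign(time_s=track.time_s + 100.0)],
            ignore_index=True,
        )
        spikes2 = pd.concat(
            [spikes, spikes.assign(time_s=spikes.time_s + 100.0)],
            ignore_index=True,
        )
        rm2 = ana.compute_ratemap(spikes2, track2)
        both = rm1.mask & rm2.mask
        assert np.allclose(rm1.rate[both], rm2.rate[both], atol=1e-6)

    def test_empty_filter_raises(self):
        track = pd.DataFrame(
            {"time_s": [0.0, 1.0, 2.0], "x_cm": [50.0] * 3, "y_cm": [50.0] * 3}
        )  # stationary: speed 0 < 5 cm/s
        spikes = pd.DataFrame({"cell": 0, "time_s": [0.5]})
        with pytest.raises(ValueError):
            ana.compute_ratemap(spikes, track)


class TestPopulationRate:
    def test_no_spikes_all_zero(self):
        pr = ana.population_rate(np.array([]), (0.0, 1.0))
        assert np.all(pr.rate == 0)

    def test_single_spike_kernel_mass_one(self):
        pr = ana.population_rate(np.array([0.5]), (0.0, 1.0))
        assert np.isclose(pr.rate.sum(), 1.0, atol=1e-6)

    def test_matches_direct_convolution_oracle(self, rng):
        ts = np.sort(rng.uniform(0, 2.0, 200))
        pr = ana.population_rate(ts, (0.0, 2.0))
        counts, _ = np.histogram(ts, bins=2000, range=(0.0, 2.0))
        oracle = gaussian_filter(counts.astype(float), 10.0, mode="constant")
        assert np.allclose(pr.rate, oracle)


class TestEventDetection:
    def _burst_rate(self):
        """Silence, then a burst of spikes around t = 1.0 s."""
        rng = np.random.default_rng(0)
        baseline = rng.uniform(0.0, 2.0, 60)  # sparse background
        burst = 1.0 + rng.uniform(-0.05, 0.05, 400)
        return ana.population_rate(
            np.sort(np.concatenate([baseline, burst])), (0.0, 2.0)
        )

    def test_window_covers_burst(self):
        pr = self._burst_rate()
        events = ana.detect_replay_events(pr, [1.0])
        assert len(events) == 1
        ev = events[0]
        assert ev.start_s < 1.0 < ev.end_s
        assert ev.end_s - ev.start_s < 0.5

    def test_two_distant_ripples_two_disjoint_events(self):
        rng = np.random.default_rng(1)
        spikes = np.concatenate(
            [
                1.0 + rng.uniform(-0.05, 0.05, 300),
                3.0 + rng.uniform(-0.05, 0.05, 300),
                rng.uniform(0, 4, 80),
            ]
        )
        pr = ana.population_rate(np.sort(spikes), (0.0, 4.0))
        events = ana.detect_replay_events(pr, [1.0, 3.0])
        assert len(events) == 2
        assert events[0].end_s < events[1].start_s

    def test_silent_ripple_rejected(self):
        pr = ana.population_rate(np.array([0.1]), (0.0, 2.0))
        assert ana.detect_replay_events(pr, [1.5]) == []

    def test_boundaries_match_bruteforce_scan(self):
        pr = self._burst_rate()
        (ev,) = ana.detect_replay_events(pr, [1.0])
        r = pr.rate
        i_rip = int(round((1.0 - pr.t0) / pr.dt))
        npre = int(round(0.5 / pr.dt))
        pre = r[i_rip - npre : i_rip]
        thr_pre = pre[pre > 0].mean()
        post = r[i_rip : i_rip + npre]
        thr_post = post[post > 0].mean()
        i = i_rip
        while i > 0 and r[i - 1] > thr_pre:
            i -= 1
        j = i_rip
        while j < len(r) - 1 and r[j + 1] >= thr_post:
            j += 1
        assert np.isclose(ev.start_s, pr.t0 + i * pr.dt)
        assert np.isclose(ev.end_s, pr.t0 + (j + 1) * pr.dt)


class TestBayesianDecoding:
    def test_uniform_maps_give_uniform_posterior(self):
        maps = np.full((3, 5, 5), 4.0)
        post = ana.bayesian_decode(np.array([1, 0, 2]), maps, tau=0.02)
        assert np.allclose(post, 1.0 / 25)

    def test_single_field_cell_pins_posterior(self):
        maps = np.full((2, 4, 4), 0.1)
        maps[0, 2, 3] = 50.0
        post = ana.bayesian_decode(np.array([3, 0]), maps, tau=0.02)
        assert np.unravel_index(np.argmax(post), post.shape) == (2, 3)

    def test_matches_direct_formula_on_toy_problem(self, rng):
        """Posterior equals F / sum(F) evaluated naively on a 5-bin problem."""
        maps = rng.uniform(0.5, 30.0, size=(4, 1, 5))
        counts = np.array([2, 0, 1, 3])
        tau = 0.02
        post = ana.bayesian_decode(counts, maps, tau)
        F = np.ones(5)
        for i in range(4):
            F *= maps[i, 0] ** counts[i]
        F *= np.exp(-tau * maps.sum(axis=0)[0])
        assert np.allclose(post[0], F / F.sum(), rtol=1e-9)

    def test_posterior_normalized_tightly(self, rng):
        maps = rng.uniform(0.0, 20.0, size=(10, 20, 20))
        post = ana.bayesian_decode(rng.poisson(1.0, 10), maps, 0.02)
        assert abs(post.sum() - 1.0) < 1e-9


class TestEventDecoding:
    def test_window_centers_advance_5ms(self, full_session, full_population):
        _, pop = full_population
        sess = full_session
        ev = sess.events[sess.events.n_steps == 20].iloc[0]
        sp = sess.spikes[sess.spikes.replay_id == ev.replay_id]
        dec = ana.Decoder(pop.ratemaps(1))
        t0 = float(ev.time_s)
        traj = dec.decode_event(sp, t0, t0 + 0.1)
        assert np.allclose(np.diff(traj.centers_s), 0.005)

    def test_excluding_silent_cell_changes_nothing(self, full_session, full_population):
        _, pop = full_population
        sess = full_session
        ev = sess.events[sess.events.n_steps == 20].iloc[0]
        sp = sess.spikes[sess.spikes.replay_id == ev.replay_id]
        silent = next(
            c for c in range(pop.n_cells) if c not in set(sp.cell.values)
        )
        dec = ana.Decoder(pop.ratemaps(1))
        t0 = float(ev.time_s)
        full = dec.decode_event(sp, t0, t0 + 0.1)
        loo = dec.decode_event(sp, t0, t0 + 0.1, exclude=silent)
        assert np.allclose(full.positions_cm, loo.positions_cm)

    def test_short_event_raises(self, full_session, full_population):
        _, pop = full_population
        dec = ana.Decoder(pop.ratemaps(1))
        with pytest.raises(ValueError):
            dec.decode_event(full_session.spikes.iloc[:0], 0.0, 0.01)

    def test_decoded_trajectory_tracks_ground_truth(
        self, full_session, full_population
    ):
        """Median decode error is below the conjunctive field width."""
        _, pop = full_population
        sess = full_session
        dec = ana.Decoder(pop.ratemaps(1))
        errs = []
        for _, ev in sess.events.iterrows():
            rid = int(ev.replay_id)
            sp = sess.spikes[sess.spikes.replay_id == rid]
            t0 = float(ev.time_s)
            t1 = t0 + float(ev.n_steps) * 0.005
            if len(sp) < 5 or t1 - t0 < 0.02:
                continue
            traj = dec.decode_event(sp, t0, t1)
            gt = sess.trajectories[sess.trajectories.replay_id == rid]
            gx = np.interp(traj.centers_s, gt.t_s.values, gt.x_cm.values)
            gy = np.interp(traj.centers_s, gt.t_s.values, gt.y_cm.values)
            errs.extend(
                np.hypot(
                    traj.positions_cm[:, 0] - gx, traj.positions_cm[:, 1] - gy
                )
            )
        assert np.median(errs) < 15.0

    def test_leave_one_out_removes_own_field_pull(
        self, full_session, full_population
    ):
        """Excluding a spiking neuron never pulls the decode *toward* its
        field: relative to the full decode, the leave-one-out decode moves
        away from (or stays at) the excluded cell's field on average,
        reflecting removal of that cell's own evidence."""
        _, pop = full_population
        sess = full_session
        dec = ana.Decoder(pop.ratemaps(1))
        shifts = []
        maps = pop.ratemaps(1)
        for _, ev in sess.events.iloc[:30].iterrows():
            rid = int(ev.replay_id)
            sp = sess.spikes[sess.spikes.replay_id == rid]
            t0 = float(ev.time_s)
            t1 = t0 + float(ev.n_steps) * 0.005
            if len(sp) < 5 or t1 - t0 < 0.02:
                continue
            base = dec.decode_event(sp, t0, t1)
            for cell in np.unique(sp.cell.values)[:3]:
                loo = dec.decode_event(sp, t0, t1, exclude=int(cell))
                peak = np.unravel_index(np.argmax(maps[cell]), maps[cell].shape)
                peak_cm = (np.array(peak[::-1]) + 0.5) * 2.0
                d_base = np.linalg.norm(base.positions_cm - peak_cm, axis=1)
                d_loo = np.linalg.norm(loo.positions_cm - peak_cm, axis=1)
                shifts.append(np.mean(d_loo - d_base))
        shifts = np.array(shifts)
        sem = shifts.std(ddof=1) / np.sqrt(len(shifts))
        assert shifts.mean() > -2 * sem  # not attracted to the field


class TestInterpolation:
    def _traj(self):
        return ana.DecodedTrajectory(
            np.array([0.0, 0.005, 0.010]),
            np.array([[0.0, 0.0], [10.0, 4.0], [20.0, 8.0]]),
        )

    def test_at_window_center(self):
        pos, clamped = ana.interpolate_spike_location(0.005, self._traj())
        assert np.allclose(pos, (10.0, 4.0)) and not clamped

    def test_midpoint_between_centers(self):
        pos, _ = ana.interpolate_spike_location(0.0025, self._traj())
        assert np.allclose(pos, (5.0, 2.0))

    def test_hand_computed_cases(self):
        for t, expect in [(0.001, (2.0, 0.8)), (0.006, (12.0, 4.8)),
                          (0.009, (18.0, 7.2))]:
            pos, _ = ana.interpolate_spike_location(t, self._traj())
            assert np.allclose(pos, expect)

    def test_outside_span_clamped_and_flagged(self):
        pos, clamped = ana.interpolate_spike_location(0.02, self._traj())
        assert clamped and np.allclose(pos, (20.0, 8.0))


class TestChangeAlignment:
    def test_identical_before_after_zero_change(self):
        change = np.zeros((20, 20))
        canvas = ana.spike_aligned_change(change, [(10.0, 10.0)], 2.0)
        assert np.nansum(np.abs(canvas)) == 0.0

    def test_translation_bookkeeping(self, rng):
        change = rng.uniform(size=(10, 10))
        x, y = 7.0, 3.0  # falls in bin (3, 1)
        canvas = ana.align_on_spike(change, (x, y), 2.0)
        center = 9
        assert canvas[center, center] == change[1, 3]
        # a neighboring value keeps its relative position
        assert canvas[center + 2, center - 1] == change[3, 2]

    def test_multiple_spikes_averaged_first(self, rng):
        change = rng.uniform(size=(10, 10))
        c1 = ana.spike_aligned_change(change, [(5.0, 5.0)], 2.0)
        c2 = ana.spike_aligned_change(change, [(9.0, 5.0)], 2.0)
        both = ana.spike_aligned_change(change, [(5.0, 5.0), (9.0, 5.0)], 2.0)
        stacked = ana.nanmean_stack([c1, c2])
        v = np.isfinite(both) & np.isfinite(stacked)
        assert np.allclose(both[v], stacked[v])


class TestClassification:
    def test_constructed_home_event(self):
        traj = np.column_stack([np.linspace(60, 160, 20), np.full(20, 60.0)])
        assert ana.classify_replay_event(traj, (60, 60), (62, 60)) == "home"

    def test_elsewhere_event(self):
        traj = np.column_stack([np.linspace(120, 210, 20), np.full(20, 150.0)])
        assert (
            ana.classify_replay_event(traj, (60, 60), (120, 150)) == "elsewhere"
        )

    def test_near_home_pass_excluded_when_animal_away(self):
        """Trajectory passing 20 cm from home while the animal sits far away
        violates the elsewhere 30 cm rule and fails the home 10 cm rule."""
        traj = np.column_stack([np.linspace(80, 180, 20), np.full(20, 60.0)])
        assert ana.classify_replay_event(traj, (60, 60), (150, 150)) == "excluded"

    def test_local_trajectory_excluded(self):
        traj = np.column_stack([np.full(10, 70.0), np.full(10, 60.0)])
        assert ana.classify_replay_event(traj, (60, 60), (62, 60)) == "excluded"


class TestMatchedControls:
    def test_identical_distribution_near_perfect_match(self, rng):
        home = rng.uniform(0, 3000, 40)
        elsewhere = np.concatenate([home, rng.uniform(0, 3000, 60)])
        idx = ana.match_controls(home, elsewhere, rng, n_samples=2000)
        lo, hi = 0, 3000
        edges = np.linspace(
            min(home.min(), elsewhere.min()),
            max(home.max(), elsewhere.max()) + 1e-9,
            6,
        )
        h1, _ = np.histogram(home, bins=edges)
        h2, _ = np.histogram(elsewhere[idx], bins=edges)
        assert np.corrcoef(h1, h2)[0, 1] > 0.9

    def test_matched_beats_random_sample_on_skewed_times(self, rng):
        home = rng.uniform(0, 1000, 30)
        elsewhere = np.concatenate(
            [rng.uniform(2000, 3000, 200), rng.uniform(0, 1000, 40)]
        )
        edges = np.linspace(0, 3000 + 1e-9, 6)
        h_home, _ = np.histogram(home, bins=edges)
        idx = ana.match_controls(home, elsewhere, rng, n_samples=2000)
        h_m, _ = np.histogram(elsewhere[idx], bins=edges)
        rand_idx = rng.choice(len(elsewhere), size=30, replace=False)
        h_r, _ = np.histogram(elsewhere[rand_idx], bins=edges)
        r_matched = np.corrcoef(h_home, h_m)[0, 1]
        r_random = np.corrcoef(h_home, h_r)[0, 1]
        assert r_matched >= r_random

    def test_seeded_reproducible(self, rng):
        home = rng.uniform(0, 100, 10)
        elsewhere = rng.uniform(0, 100, 50)
        i1 = ana.match_controls(
            home, elsewhere, np.random.default_rng(3), n_samples=500
        )
        i2 = ana.match_controls(
            home, elsewhere, np.random.default_rng(3), n_samples=500
        )
        assert np.array_equal(i1, i2)

    def test_too_few_elsewhere_raises(self, rng):
        with pytest.raises(ValueError):
            ana.match_controls(np.arange(10.0), np.arange(5.0), rng)


class TestSummaries:
    def test_zero_maps_zero_summary(self):
        canvases = [np.zeros((39, 39))]
        s = ana.summarize_changes(canvases, bin_cm=2.0)
        assert s.roi_mean == 0.0
        assert np.allclose(s.profiles, 0.0)

    def test_delta_at_origin_decays_with_radius(self):
        canvas = np.zeros((39, 39))
        canvas[19, 19] = 10.0
        s = ana.summarize_changes([canvas], bin_cm=2.0)
        assert s.roi_mean > 0
        assert np.nanmax(s.profiles[0]) <= canvas.max()
        assert np.all(np.nan_to_num(s.profiles[0][5:]) == 0.0)

    def test_spokes_match_nearest_bin_oracle(self, rng):
        canvas = rng.uniform(size=(39, 39))
        s = ana.summarize_changes([canvas], bin_cm=2.0, n_angles=4, n_steps=8)
        center = 19
        for k, radius in enumerate(s.radii_cm):
            vals = []
            for ang in np.linspace(0, 2 * np.pi, 4, endpoint=False):
                i = int(np.rint(center + radius * np.cos(ang) / 2.0))
                j = int(np.rint(center + radius * np.sin(ang) / 2.0))
                i, j = np.clip(i, 0, 38), np.clip(j, 0, 38)
                vals.append(canvas[j, i])
            assert np.isclose(s.profiles[0][k], np.mean(vals))


class TestHomeShiftCorrelation:
    def test_identical_homes_correlation_one(self, rng):
        m = rng.uniform(size=(30, 30))
        r = ana.home_shift_correlation(m, (20.0, 20.0), (20.0, 20.0))
        assert np.isclose(r, 1.0)

    def test_simulated_landmark_negative(self):
        """A field that moved with the home produces anticorrelation."""
        nb = 50
        yy, xx = np.mgrid[0:nb, 0:nb]

        def bump(cx, cy):
            return np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 9.0))

        old_home, new_home = (20.0, 20.0), (60.0, 70.0)
        vec = np.array([10.0, 5.0])  # bins
        change = bump(
            new_home[0] / 2 + vec[0], new_home[1] / 2 + vec[1]
        ) - bump(old_home[0] / 2 + vec[0], old_home[1] / 2 + vec[1])
        r = ana.home_shift_correlation(change, new_home, old_home)
        assert r < -0.1

    def test_noise_only_near_zero(self, rng):
        rs = []
        for _ in range(20):
            m = rng.standard_normal((40, 40))
            rs.append(ana.home_shift_correlation(m, (30.0, 30.0), (50.0, 20.0)))
        assert abs(np.mean(rs)) < 0.1


class TestOverlap:
    def test_no_spikes_zero_overlap(self):
        overlap, n, corr = ana.replay_change_overlap(np.ones((20, 20)), [])
        assert overlap == 0.0 and n == 0

    def test_coincident_beats_disjoint(self, rng):
        nb = 40
        change = np.zeros((nb, nb))
        change[10, 10] = 5.0
        spikes_near = [(21.0, 21.0)] * 4  # bin (10, 10)
        spikes_far = [(61.0, 61.0)] * 4
        o_near, _, c_near = ana.replay_change_overlap(change, spikes_near)
        o_far, _, c_far = ana.replay_change_overlap(change, spikes_far)
        assert o_near > o_far
        assert c_near > c_far

    def test_overlap_matches_bruteforce(self, rng):
        change = rng.standard_normal((20, 20))
        locs = rng.uniform(0, 40, (6, 2))
        overlap, n, _ = ana.replay_change_overlap(change, locs)
        spike_map = np.zeros((20, 20))
        for xy in locs:
            spike_map[int(xy[1] // 2), int(xy[0] // 2)] += 1
        spike_map = gaussian_filter(spike_map, 2.0, mode="constant")
        assert np.isclose(overlap, np.mean(np.abs(change) * spike_map))
        assert n == 6


class TestNonlocalDoorSpikes:
    def _setup(self, rng):
        track = pd.DataFrame(
            {
                "time_s": np.arange(0, 20, 0.02),
                "x_cm": np.full(1000, 50.0),
                "y_cm": np.full(1000, 50.0),
            }
        )  # sitting still at (50, 50)
        door = (52.0, 50.0)
        return track, door

    def test_spike_in_own_field_not_flagged(self, rng):
        track, door = self._setup(rng)
        mask = np.zeros((50, 50), dtype=bool)
        mask[25, 25] = True  # field at the animal's location
        spikes = pd.DataFrame({"cell": [0], "time_s": [5.0]})
        out, ind = ana.nonlocal_door_spikes(
            spikes, track, [door], {0: mask}, bin_cm=2.0
        )
        assert not out.nonlocal_door_spike.iloc[0]
        assert not ind.loc[0]

    def test_far_from_door_not_flagged(self, rng):
        track, _ = self._setup(rng)
        spikes = pd.DataFrame({"cell": [0], "time_s": [5.0]})
        out, _ = ana.nonlocal_door_spikes(
            spikes, track, [(70.0, 50.0)], {0: np.zeros((50, 50), bool)}
        )
        assert not out.nonlocal_door_spike.iloc[0]

    def test_valid_nonlocal_spike_flagged(self, rng):
        track, door = self._setup(rng)
        spikes = pd.DataFrame({"cell": [0], "time_s": [5.0]})
        out, ind = ana.nonlocal_door_spikes(
            spikes, track, [door], {0: np.zeros((50, 50), bool)}
        )
        assert out.nonlocal_door_spike.iloc[0]
        assert ind.loc[0]

    def test_regression_recovers_replay_effect(self, rng):
        """Cells that replayed get new fields more often; the regression
        coefficient on the replay indicator comes out positive."""
        n = 400
        replayed = rng.random(n) < 0.5
        mean_rate = rng.uniform(0.5, 5.0, n)
        p_new = 0.1 + 0.4 * replayed
        new_field = rng.random(n) < p_new
        coef, tval, p = ana.replay_newfield_regression(
            new_field, replayed, mean_rate
        )
        assert coef > 0.2
        assert p < 0.01


class TestSessionPipeline:
    def test_tiny_session_pipeline_runs(self, tiny_fixture, rng):
        pop, session = tiny_fixture
        res = ana.analyze_synthetic_session(session, rng)
        assert set(res.canvases) <= {"home", "elsewhere", "matched"}
        assert len(res.events) > 0
        for lab, summ in res.summaries.items():
            assert np.isfinite(summ.roi_mean)
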