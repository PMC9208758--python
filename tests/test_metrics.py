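"""Trial-metric tests: performance closed forms, normalisation endpoints,
nearest miss and unintended hits against brute-force window scans, the
direct-movement rule, three-stage characteristic forces and the learning
correlation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from munit_task.core import SpikeTrain
from munit_task.engine import (BufferConfig, run_session, run_trial,
                               standard_targets)
from munit_task.metrics import (classify_direct, evaluate_performance,
                                learning_correlation, nearest_miss,
                                performance_bounds, performance_normalized,
                                performance_raw, session_metrics,
                                stage_forces, unintended_hits)
from test_engine import stream_from_positions


def make_trial(positions, cfg, geoms, target="TI"):
    return run_trial(stream_from_positions(np.asarray(positions, float), cfg),
                     geoms[target], cfg)


class TestPerformanceRaw:
    def test_origin_hold_closed_form(self, cfg, geoms):
        # (d/dmax)^2 + (phi/phimax)^2 = (1/sqrt(2))^2 + 1 = 1.5 per buffer
        trial = make_trial(np.zeros((160, 2)), cfg, geoms, "TI")
        assert performance_raw(trial, geoms["TI"]) == pytest.approx(240.0)

    def test_at_center_scores_zero(self, cfg, geoms):
        pos = np.tile(geoms["TI"].center, (20, 1))
        trial = make_trial(pos, cfg, geoms, "TI")
        assert performance_raw(trial, geoms["TI"]) == pytest.approx(0.0)

    def test_single_buffer_on_axis(self, cfg, geoms):
        trial = make_trial([[0.5, 0.0]], cfg, geoms, "TI")
        assert performance_raw(trial, geoms["TI"]) == pytest.approx(
            (0.5 / np.sqrt(2)) ** 2)

    def test_rss_variant_is_root_per_buffer(self, cfg, geoms):
        trial = make_trial(np.zeros((10, 2)), cfg, geoms, "TI")
        raw = performance_raw(trial, geoms["TI"], variant="rss")
        assert raw == pytest.approx(10 * np.sqrt(1.5))

    def test_appending_off_center_buffer_increases_raw(self, cfg, geoms):
        rng = np.random.default_rng(0)
        base = rng.uniform(-0.2, 1.2, (30, 2))
        for _ in range(20):
            extra = rng.uniform(-0.2, 1.2, 2)
            if np.allclose(extra, geoms["TI"].center):
                continue
            t1 = make_trial(base, cfg, geoms, "TI")
            t2 = make_trial(np.vstack([base, extra]), cfg, geoms, "TI")
            assert performance_raw(t2, geoms["TI"]) > \
                performance_raw(t1, geoms["TI"])


class TestPerformanceBounds:
    def test_worst_closed_forms(self, cfg, geoms):
        _, worst_ti = performance_bounds(geoms["TI"], cfg)
        _, worst_tii = performance_bounds(geoms["TII"], cfg)
        _, worst_tiii = performance_bounds(geoms["TIII"], cfg)
        assert worst_ti == pytest.approx(240.0)
        assert worst_tii == pytest.approx(320.0)
        assert worst_tiii == pytest.approx(240.0)

    def test_best_hits_within_support_plus_hold(self, cfg, geoms):
        for geom in geoms.values():
            best, worst = performance_bounds(geom, cfg)
            assert 0.0 <= best < worst

    def test_normalisation_endpoints(self, cfg, geoms):
        geom = geoms["TI"]
        bounds = performance_bounds(geom, cfg)
        origin = make_trial(np.zeros((160, 2)), cfg, geoms, "TI")
        assert performance_normalized(performance_raw(origin, geom),
                                      bounds) == pytest.approx(0.0)
        assert performance_normalized(bounds[0], bounds) == 1.0
        mid = 0.5 * (bounds[0] + bounds[1])
        assert performance_normalized(mid, bounds) == pytest.approx(0.5)

    def test_ideal_trajectory_normalises_to_one(self, cfg, geoms):
        for tid, geom in geoms.items():
            rates = np.tile(np.asarray(geom.center), (200, 1))
            from munit_task.engine import cursor_positions
            stream = cursor_positions(rates, (1.0, 1.0), (1.0, 1.0), cfg)
            trial = run_trial(stream, geom, cfg)
            res = evaluate_performance(trial, geom, cfg)
            assert trial.target_hit
            assert res.normalized == pytest.approx(1.0)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            performance_normalized(1.0, (2.0, 2.0))


def brute_nearest_miss(positions, center, hold):
    best, best_d = None, np.inf
    for i in range(len(positions) - hold + 1):
        m = positions[i:i + hold].mean(axis=0)
        d = np.hypot(*(m - center))
        if d < best_d - 1e-15:
            best, best_d = m, d
    return best


class TestNearestMiss:
    def test_constant_stream(self, cfg, geoms):
        trial = make_trial(np.tile([0.5, 0.0], (30, 1)), cfg, geoms, "TI")
        nm = nearest_miss(trial, geoms["TI"], cfg)
        assert np.allclose(nm, [0.5, 0.0])

    def test_far_then_near(self, cfg, geoms):
        pos = np.tile([0.1, 0.0], (40, 1))
        pos[25:] = [0.7, 0.0]
        trial = make_trial(pos, cfg, geoms, "TI")
        nm = nearest_miss(trial, geoms["TI"], cfg)
        assert np.allclose(nm, [0.7, 0.0])

    def test_hit_trial_rejected(self, cfg, geoms):
        pos = np.tile(geoms["TI"].center, (20, 1))
        trial = make_trial(pos, cfg, geoms, "TI")
        with pytest.raises(ValueError):
            nearest_miss(trial, geoms["TI"], cfg)

    def test_short_trial_absent(self, cfg, geoms):
        trial = make_trial(np.zeros((3, 2)), cfg, geoms, "TI")
        assert nearest_miss(trial, geoms["TI"], cfg) is None

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        cfg = BufferConfig()
        geoms = standard_targets()
        rng = np.random.default_rng(seed)
        n = int(rng.integers(7, 60))
        pos = rng.uniform(-0.3, 0.8, (n, 2))  # keep clear of the target
        trial = make_trial(pos, cfg, geoms, "TI")
        if trial.target_hit:
            return
        nm = nearest_miss(trial, geoms["TI"], cfg)
        ref = brute_nearest_miss(trial.positions, geoms["TI"].center_arr,
                                 cfg.hold_buffers)
        assert np.allclose(nm, ref)


def brute_unintended(in_region, hold):
    count = run = 0
    for b in list(in_region) + [False]:
        if b:
            run += 1
        else:
            if run >= hold:
                count += 1
            run = 0
    return count


class TestUnintendedHits:
    def test_short_excursion_not_counted(self, cfg, geoms):
        pos = np.zeros((40, 2))
        pos[10:16] = geoms["TII"].center  # 6 buffers only
        trial = make_trial(pos, cfg, geoms, "TI")
        counts = unintended_hits(trial, geoms, cfg)
        assert counts["TII"]["target"] == 0

    def test_reentries_counted_separately(self, cfg, geoms):
        pos = np.zeros((60, 2))
        pos[10:17] = geoms["TII"].center
        pos[30:38] = geoms["TII"].center
        trial = make_trial(pos, cfg, geoms, "TI")
        counts = unintended_hits(trial, geoms, cfg)
        assert counts["TII"]["target"] == 2
        assert counts["TII"]["angle"] == 2

    def test_wedge_crossing_en_route(self, cfg, geoms):
        # passing through the TII wedge for 10 buffers on the way to TIII
        pos = np.zeros((60, 2))
        pos[10:20] = (0.5, 0.5)
        pos[30:] = geoms["TIII"].center
        trial = make_trial(pos, cfg, geoms, "TIII")
        counts = unintended_hits(trial, geoms, cfg)
        assert counts["TII"]["angle"] >= 1
        assert counts["TII"]["target"] == 0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        cfg = BufferConfig()
        geoms = standard_targets()
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 80))
        pos = rng.uniform(-0.3, 1.3, (n, 2))
        trial = make_trial(pos, cfg, geoms, "TIII")
        if trial.target_hit:
            pos = trial.positions  # compare on the recorded slice
        counts = unintended_hits(trial, geoms, cfg)
        from munit_task.engine import point_region_test, REGION_TARGET
        for tid in ("TI", "TII"):
            inside = [point_region_test(p, geoms[tid]) == REGION_TARGET
                      for p in trial.positions]
            assert counts[tid]["target"] == brute_unintended(
                inside, cfg.hold_buffers)


class TestClassifyDirect:
    def test_ti_direct_iff_mu2_silent(self, cfg, geoms):
        pos = np.tile(geoms["TI"].center, (20, 1))
        trial = make_trial(pos, cfg, geoms, "TI")
        silent = SpikeTrain("mu2", np.array([]))
        active = SpikeTrain("mu2", np.array([0.2]))
        mu1 = SpikeTrain("mu1", np.arange(0.0, 3.0, 0.1))
        assert classify_direct(trial, (mu1, silent)) is True
        assert classify_direct(trial, (mu1, active)) is False

    def test_tiii_single_mu1_spike_breaks_directness(self, cfg, geoms):
        pos = np.tile(geoms["TIII"].center, (20, 1))
        trial = make_trial(pos, cfg, geoms, "TIII")
        mu1 = SpikeTrain("mu1", np.array([0.3]))
        mu2 = SpikeTrain("mu2", np.arange(0.0, 3.0, 0.1))
        assert classify_direct(trial, (mu1, mu2)) is False

    def test_not_applicable_cases(self, cfg, geoms):
        pos = np.tile(geoms["TII"].center, (20, 1))
        trial = make_trial(pos, cfg, geoms, "TII")
        tr = (SpikeTrain("a", np.array([])), SpikeTrain("b", np.array([])))
        assert classify_direct(trial, tr) is None
        miss = make_trial(np.zeros((20, 2)), cfg, geoms, "TI")
        assert classify_direct(miss, tr) is None


class TestStageForces:
    def test_three_stage_session_recovers_levels(self, cfg, reversed_pair):
        from munit_task.synth import three_stage_policy
        prof = three_stage_policy(reversed_pair)
        sess = run_session(reversed_pair, cfg, seed=3, repeats=3,
                           drive_fs=512.0)
        rows = [stage_forces(st_, cfg) for st_ in sess.trials
                if st_.trial.target_id == "TIII" and st_.trial.target_hit]
        rows = [r for r in rows if r is not None]
        assert rows, "no indirect TIII hits in the session"
        l1, l2, l3 = prof.levels
        for sf in rows:
            assert sf.f1 == pytest.approx(l1, abs=0.3)
            assert sf.f2 == pytest.approx(l2, abs=0.3)
            assert sf.f1 > sf.f3 > sf.f2  # stage ordering of the forces

    def test_absent_without_both_active_epoch(self, cfg, geoms, reversed_pair):
        # direct-looking trial: MU1 never fires, no both-active epoch
        sess = run_session(reversed_pair, cfg, seed=3, repeats=1,
                           drive_fs=512.0)
        st_ = next(s for s in sess.trials if s.trial.target_id == "TIII")
        import dataclasses
        silent = SpikeTrain(st_.trains[0].unit_id, np.array([]))
        from munit_task.engine import buffer_rates, cursor_positions
        rates = np.stack(
            [buffer_rates(silent, cfg, st_.drive.duration),
             buffer_rates(st_.trains[1], cfg, st_.drive.duration)], axis=1)
        stream = cursor_positions(rates, sess.ref_rates, sess.gains, cfg)
        mutated = dataclasses.replace(st_, stream=stream)
        assert stage_forces(mutated, cfg) is None


class TestLearningCorrelation:
    def test_monotone_extremes(self):
        assert learning_correlation(np.linspace(0, 1, 10)) == pytest.approx(1.0)
        assert learning_correlation(np.linspace(1, 0, 10)) == pytest.approx(-1.0)

    def test_null_distribution(self):
        rng = np.random.default_rng(0)
        rho = learning_correlation(rng.permutation(1000).astype(float))
        assert abs(rho) < 0.1

    def test_constant_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert learning_correlation([0.5, 0.5, 0.5]) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            learning_correlation([0.1, 0.2])


def test_session_metrics_table(cfg, reversed_pair):
    sess = run_session(reversed_pair, cfg, seed=2, repeats=2, drive_fs=512.0)
    df = session_metrics(sess, standard_targets())
    assert len(df) == 6
    assert set(df["target"]) == {"TI", "TII", "TIII"}
    assert df["normalized"].between(0, 1).all()
    # direct TIII never occurs for an orderly-recruited pair
    tiii = df[df["target"] == "TIII"]["direct"].dropna()
    assert not tiii.astype(bool).any()
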