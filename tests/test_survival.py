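import numpy as np
import pytest

from smtrack import (
    AcquisitionMetadata,
    MotionState,
    SimulationParams,
    SurvivalCurve,
    Track,
    TrackSet,
    build_survival,
    classify_bound,
    correct_photobleaching,
    derive_kinetics,
    fit_dwell_models,
    simulate_tracks,
)
from conftest import FRAME_DT, curve_from_dwell_frames, stationary_track


def trackset(tracks, n_frames=100):
    return TrackSet(tracks, AcquisitionMetadata(exposure=FRAME_DT, n_frames=n_frames))


class TestClassifyBound:
    def test_stationary_track_one_segment(self):
        ts = trackset([stationary_track(n=10)], n_frames=100)
        segs = classify_bound(ts, r_max=0.22, n_min=3)
        assert len(segs) == 1
        s = segs[0]
        assert s.start_frame == 0 and s.end_frame == 9
        assert s.dwell == pytest.approx(1.8)
        assert not s.censored_at_movie_end  # movie continues past frame 9

    def test_segment_reaching_movie_end_censored(self):
        ts = trackset([stationary_track(n=10)], n_frames=10)
        (s,) = classify_bound(ts, 0.22, 3)
        assert s.censored_at_movie_end

    def test_fast_brownian_spurious_rate_matches_oracle(self):
        """Fast Brownian motion produces only rare, short spurious bound
        calls, at the rate a brute-force sliding-window recount gives."""
        p = SimulationParams(
            n_molecules=300,
            states=(MotionState("diffusing", 1.0),),
            n_frames=30,
            frame_exposure=FRAME_DT,
            nucleus_radius=50.0,
            seed=21,
        )
        ts, _ = simulate_tracks(p)
        segs = classify_bound(ts, r_max=0.2, n_min=3)
        # independent oracle: count 3-frame windows clustered within r_max
        oracle = 0
        for tr in ts:
            pts = np.column_stack([tr.x, tr.y])
            for k in range(len(tr) - 2):
                w = pts[k : k + 3]
                if np.linalg.norm(w - w.mean(0), axis=1).max() <= 0.2:
                    oracle += 1
        # greedy maximal runs never exceed the sliding-window count
        assert len(segs) <= oracle
        assert 0.5 * oracle <= len(segs) + 5
        # spurious calls are rare (a fraction of a call per track) and short
        assert len(segs) < 0.5 * len(ts)
        assert max((s.n_frames for s in segs), default=0) <= 5

    def test_alternating_mobility_segments_only_stationary_runs(self):
        """5 stationary + 5 mobile frames alternating: segments cover only
        the stationary runs."""
        rng = np.random.default_rng(0)
        xs, ys = [], []
        pos = np.zeros(2)
        for block in range(4):
            if block % 2 == 0:
                # hold a fresh position for the whole stationary block
                pos = pos + rng.normal(0, 2.0, 2) if block else pos
                for _ in range(5):
                    xs.append(pos[0]), ys.append(pos[1])
            else:
                for _ in range(5):
                    pos = pos + rng.normal(0, 2.0, 2)  # steps >> r_max
                    xs.append(pos[0]), ys.append(pos[1])
        frames = np.arange(20)
        ts = trackset([Track(0, frames, frames * FRAME_DT, xs, ys)], n_frames=100)
        segs = classify_bound(ts, 0.22, 3)
        assert len(segs) == 2
        assert segs[0].start_frame == 0 and segs[0].end_frame == 4
        assert segs[1].start_frame == 10 and segs[1].end_frame == 14

    def test_invalid_r_max(self):
        with pytest.raises(ValueError):
            classify_bound(trackset([stationary_track()]), r_max=0.0)


class TestBuildSurvival:
    def test_counting_matches_hand_computation(self):
        """Dwells of 1, 2, 3 frame-intervals give raw S = 1, 2/3, 1/3."""
        tracks = [stationary_track(i, n=n) for i, n in enumerate([2, 3, 4])]
        ts = trackset(tracks, n_frames=100)
        segs = classify_bound(ts, 0.22, n_min=2)
        curve = build_survival(segs, ts)
        np.testing.assert_allclose(curve.times, [0.2, 0.4, 0.6])
        np.testing.assert_allclose(curve.S / curve.C_eq, [1, 2 / 3, 1 / 3])

    def test_c_eq_bound_detections_over_total(self):
        """One particle bound 4 frames out of 8 total detections: C_eq = 1/2."""
        bound = stationary_track(0, n=4)
        rng = np.random.default_rng(1)
        frames = np.arange(4)
        mobile = Track(1, frames, frames * FRAME_DT, rng.uniform(0, 5, 4), rng.uniform(0, 5, 4))
        ts = trackset([bound, mobile], n_frames=100)
        segs = classify_bound(ts, 0.22, 3)
        curve = build_survival(segs, ts)
        assert curve.C_eq == pytest.approx(0.5)
        assert curve.S[0] == pytest.approx(0.5)

    def test_everything_bound_flat_at_one(self):
        ts = trackset([stationary_track(i, n=10) for i in range(3)], n_frames=10)
        curve = build_survival(classify_bound(ts, 0.22, 3), ts)
        assert curve.C_eq == pytest.approx(1.0)
        np.testing.assert_allclose(curve.S, 1.0)

    def test_empty_segments_error(self):
        ts = trackset([stationary_track()])
        with pytest.raises(ValueError, match="bound"):
            build_survival([], ts)

    def test_survival_matches_quadratic_recount(self):
        """S(t) equals a naive O(n^2) recount over random segments."""
        rng = np.random.default_rng(7)
        tracks = [stationary_track(i, n=int(n)) for i, n in enumerate(rng.integers(3, 40, 100))]
        ts = trackset(tracks, n_frames=200)
        segs = classify_bound(ts, 0.22, 3)
        curve = build_survival(segs, ts)
        for t, s in zip(curve.times, curve.S / curve.C_eq):
            brute = sum(1 for a in segs if a.dwell >= t - 1e-9) / len(segs)
            assert s == pytest.approx(brute)

    def test_uncorrected_survival_nonincreasing_in_unit_interval(self):
        rng = np.random.default_rng(8)
        tracks = [stationary_track(i, n=int(n)) for i, n in enumerate(rng.integers(3, 30, 50))]
        ts = trackset(tracks, n_frames=200)
        curve = build_survival(classify_bound(ts, 0.22, 3), ts)
        assert np.all(np.diff(curve.S) <= 1e-12)
        assert 0 <= curve.S[-1] and curve.S[0] <= curve.C_eq + 1e-12


def synthetic_curve(S, c_eq, n0=10_000, dt=FRAME_DT):
    """Noiseless survival curve with counts shadowing S (for fit tests)."""
    counts = np.maximum(np.rint(n0 * S / S[0]), 1.0)
    return SurvivalCurve(
        times=np.arange(1, len(S) + 1) * dt,
        S=c_eq * S / S[0],
        counts=counts,
        n0=n0,
        C_eq=c_eq,
        frame_interval=dt,
    )


class TestCorrectPhotobleaching:
    def test_whole_reference_self_correction_is_flat(self):
        t = np.arange(1, 200) * FRAME_DT
        S = 0.5 * np.exp(-t / 1) + 0.5 * np.exp(-t / 20)
        curve = synthetic_curve(S, c_eq=0.8)
        corr = correct_photobleaching(curve, "whole_reference", curve)
        np.testing.assert_allclose(corr.S, corr.S[0], rtol=1e-12)
        assert corr.S[0] == pytest.approx(0.8)
        assert corr.correction == "whole_reference"

    def test_immobile_fraction_recovers_stable_component(self):
        """Reference 0.5 e^{-t} + 0.5 e^{-t/20}; a species decaying purely
        as e^{-t/20} corrects to a flat curve (noiseless)."""
        t = np.arange(1, 200) * FRAME_DT
        ref = synthetic_curve(0.5 * np.exp(-t / 1) + 0.5 * np.exp(-t / 20), c_eq=1.0)
        target = synthetic_curve(np.exp(-t / 20), c_eq=1.0)
        corr = correct_photobleaching(target, "immobile_fraction", ref, seed=0)
        assert corr.provenance["reference_tau_slow_s"] == pytest.approx(20.0, rel=1e-4)
        assert np.max(np.abs(corr.S - corr.S[0])) < 1e-6

    def test_intrinsic_correction_flattens_pure_bleaching(self, immobile_bleached_trackset):
        """Immobile molecules bleaching at 0.05/exposure: intrinsic-corrected
        survival is flat within counting noise."""
        ts, _ = immobile_bleached_trackset
        segs = classify_bound(ts, 0.22, 3)
        curve = build_survival(segs, ts)
        corr = correct_photobleaching(curve, "intrinsic")
        lam = corr.provenance["bleach_rate_per_exposure"]
        assert lam == pytest.approx(-np.log(1 - 0.05), rel=0.05)
        good = corr.counts >= 30
        dev = np.abs(corr.S[good] - corr.S[0]) / corr.S[0]
        # 95% envelope of binomial noise after exponential re-inflation
        assert np.quantile(dev, 0.5) < 0.05 and dev.max() < 0.5

    def test_reference_shorter_than_target_rejected(self):
        t = np.arange(1, 100) * FRAME_DT
        target = synthetic_curve(np.exp(-t / 5), c_eq=0.5)
        ref = synthetic_curve(np.exp(-np.arange(1, 50) * FRAME_DT / 5), c_eq=0.5)
        with pytest.raises(ValueError, match="shorter"):
            correct_photobleaching(target, "whole_reference", ref)

    def test_unseparated_slow_component_warns(self):
        t = np.arange(1, 200) * FRAME_DT
        ref = synthetic_curve(0.5 * np.exp(-t / 8) + 0.5 * np.exp(-t / 11), c_eq=1.0)
        target = synthetic_curve(np.exp(-t / 10), c_eq=1.0)
        corr = correct_photobleaching(target, "immobile_fraction", ref, seed=0)
        assert any("not separated" in w for w in corr.provenance["warnings"])

    def test_unknown_method_rejected(self):
        t = np.arange(1, 50) * FRAME_DT
        curve = synthetic_curve(np.exp(-t / 5), 0.5)
        with pytest.raises(ValueError):
            correct_photobleaching(curve, "magic")


class TestFitDwellModels:
    def test_noiseless_biexponential_recovered_to_four_digits(self):
        t = np.arange(1, 301) * FRAME_DT
        S = 0.6 * np.exp(-t / 2) + 0.4 * np.exp(-t / 10)
        curve = synthetic_curve(S, c_eq=0.46)
        fits, best = fit_dwell_models(curve, seed=0)
        by = {f.family: f for f in fits}
        assert best.family == "exp_2"
        assert by["exp_2"].taus == pytest.approx((2.0, 10.0), rel=1e-4)
        assert by["exp_2"].fractions == pytest.approx((0.6, 0.4), rel=1e-4)
        assert by["exp_2"].bic < by["exp_1"].bic
        assert by["exp_2"].bic < by["power_law"].bic

    def test_pure_exponential_samples_select_exp_1(self):
        rng = np.random.default_rng(31)
        kd = np.floor(rng.exponential(5.0, 5000) / FRAME_DT).astype(int)
        curve = curve_from_dwell_frames(np.minimum(kd, 600))
        _, best = fit_dwell_models(curve, seed=0)
        assert best.family == "exp_1"

    def test_hybrid_samples_select_hybrid(self):
        rng = np.random.default_rng(32)
        n = 5000
        is_exp = rng.random(n) < 0.6
        u = np.where(is_exp, rng.exponential(1.5, n), FRAME_DT * (rng.pareto(0.5, n) + 1))
        kd = np.minimum(np.floor(u / FRAME_DT).astype(int), 600)
        curve = curve_from_dwell_frames(kd)
        _, best = fit_dwell_models(curve, seed=0)
        assert best.family == "power_plus_exp"

    def test_too_few_points_rejected(self):
        t = np.arange(1, 6) * FRAME_DT
        curve = synthetic_curve(np.exp(-t / 5), 0.5)
        with pytest.raises(ValueError, match="8"):
            fit_dwell_models(curve)


class TestDeriveKinetics:
    def biexp_fit(self, f_ns, f_s, tau_ns, tau_s):
        from smtrack.survival import DwellModelFit

        return DwellModelFit(
            family="exp_2",
            params={},
            fractions=(f_ns, f_s),
            taus=(tau_ns, tau_s),
            bic=0.0,
            n_points=10,
            rss_weighted=0.0,
        )

    def test_equal_fractions_two_trials(self):
        kin = derive_kinetics(self.biexp_fit(0.5, 0.5, 1.0, 9.0), C_eq=0.3)
        assert kin.n_trials == pytest.approx(2.0)

    def test_worked_substitution(self):
        """F_NS=0.75, F_S=0.25, tau 1 s / 9 s, C_eq=0.25: tau_res = 3 s,
        tau_search = 9 s, k_on* = 1/9."""
        kin = derive_kinetics(self.biexp_fit(0.75, 0.25, 1.0, 9.0), C_eq=0.25)
        assert kin.tau_res == pytest.approx(3.0)
        assert kin.tau_search == pytest.approx(9.0)
        assert kin.k_on_star == pytest.approx(1 / 9)
        assert kin.n_trials == pytest.approx(4.0)
        assert kin.k_off_NS == pytest.approx(1.0)
        assert kin.k_off_S == pytest.approx(1 / 9)

    def test_balanced_occupancy_search_equals_residence(self):
        kin = derive_kinetics(self.biexp_fit(0.6, 0.4, 2.0, 10.0), C_eq=0.5)
        assert kin.tau_search == pytest.approx(kin.tau_res)

    def test_tau_res_is_convex_combination(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            f = rng.uniform(0.05, 0.95)
            t1, t2 = sorted(rng.uniform(0.5, 30, 2))
            kin = derive_kinetics(self.biexp_fit(f, 1 - f, t1, t2), C_eq=0.4)
            assert t1 - 1e-9 <= kin.tau_res <= t2 + 1e-9

    def test_power_law_fit_refused(self):
        from smtrack.survival import DwellModelFit

        fit = DwellModelFit("power_law", {"A": 1, "beta": 0.5}, (1.0,), (), 0, 10, 0)
        with pytest.raises(ValueError, match="[Pp]ower [Ll]aw"):
            derive_kinetics(fit, C_eq=0.5)

    def test_degenerate_c_eq_rejected(self):
        fit = self.biexp_fit(0.5, 0.5, 1.0, 9.0)
        for c in (0.0, 1.0):
            with pytest.raises(ValueError):
                derive_kinetics(fit, C_eq=c)

    def test_k_on_only_with_s_eq(self):
        fit = self.biexp_fit(0.5, 0.5, 1.0, 9.0)
        assert derive_kinetics(fit, C_eq=0.5).k_on is None
        kin = derive_kinetics(fit, C_eq=0.5, S_eq=0.2)
        assert kin.k_on == pytest.approx(kin.k_on_star / 0.2)
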