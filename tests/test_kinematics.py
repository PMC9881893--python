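import numpy as np
import pandas as pd
import pytest

from vswim.extraction import AlignedBout, compute_speed, extract_bouts, extract_ibis, select_epochs
from vswim.kinematics import (
    analyze_repeats,
    angular_velocity_summary,
    binned_average,
    bout_features,
    compare_profiles,
    features_table,
    fit_bout_timing,
    fit_fin_body,
    fit_righting,
    fit_steering,
)
from vswim.models import QuadraticVertexRegression, SlopeInterceptRegression
from vswim.synth import trace_to_records


def _make_bout(pitch, x=None, z=None, speed=None, fps=100.0, peak_speed=10.0, repeat_id="r0"):
    n_pre, n_post = round(0.5 * fps), round(0.3 * fps)
    n = n_pre + n_post + 1
    t = (np.arange(n) - n_pre) * 1000.0 / fps
    pitch = np.broadcast_to(np.asarray(pitch, dtype=float), n).copy()
    if speed is None:
        speed = np.zeros(n)
        speed[np.abs(t) <= 100.0] = peak_speed
    x = np.zeros(n) if x is None else np.asarray(x, dtype=float)
    z = np.zeros(n) if z is None else np.asarray(z, dtype=float)
    return AlignedBout(times_ms=t, speed=speed, pitch=pitch, x=x, z=z,
                       peak_speed=peak_speed, t_peak=0.0, epoch_id=0, repeat_id=repeat_id)


class TestBoutFeatures:
    def test_horizontal_motion_with_constant_pitch(self):
        n = 81
        b = _make_bout(pitch=10.0, x=np.arange(n) * 0.1)
        f = bout_features(b)
        assert f.steering_rotation == 0.0
        assert f.trajectory == 0.0
        assert f.attack_angle == -10.0
        assert f.trajectory_deviation == -10.0

    def test_vertical_ascent_trajectory_limit(self):
        n = 81
        b = _make_bout(pitch=90.0, z=np.arange(n) * 0.1)
        f = bout_features(b)
        assert f.trajectory == pytest.approx(90.0)

    def test_heading_invariance_of_trajectory(self):
        n = 81
        climb_right = bout_features(_make_bout(0.0, x=np.arange(n) * 0.1, z=np.arange(n) * 0.1))
        climb_left = bout_features(_make_bout(0.0, x=-np.arange(n) * 0.1, z=np.arange(n) * 0.1))
        assert climb_right.trajectory == pytest.approx(45.0)
        assert climb_left.trajectory == pytest.approx(45.0)

    def test_noise_free_features_equal_latents(self, quiet_session, quiet_profile):
        fr = quiet_profile.frame_rate
        series = compute_speed(trace_to_records(quiet_session), frame_rate=fr)
        kept, _ = select_epochs(series, frame_rate=fr)
        bouts = extract_bouts(kept, frame_rate=fr)
        feats = features_table(bouts, srr_time_ms=quiet_profile.angvel_peak_lead)
        gt = quiet_session.ground_truth
        assert len(feats) == len(gt)
        by_time = {round(g.onset_time, 4): g for g in gt}
        for i, b in enumerate(bouts):
            g = by_time[round(b.t_peak, 4)]
            assert feats.initial_pitch[i] == pytest.approx(g.initial_pitch, abs=0.5)
            assert feats.pitch_at_peak[i] == pytest.approx(g.pitch_at_peak, abs=0.5)
            assert feats.trajectory[i] == pytest.approx(g.trajectory, abs=0.5)
            assert feats.righting_rotation[i] == pytest.approx(g.righting_rotation, abs=0.5)
            assert feats.steering_related_rotation[i] == pytest.approx(
                g.steering_related_rotation, abs=0.5)
            assert feats.attack_angle[i] == pytest.approx(g.attack_angle, abs=0.5)


class TestLinearFits:
    def test_ols_matches_closed_form_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.1, 2.9, 4.2, 5.8, 9.1])
        fit = SlopeInterceptRegression().fit(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert fit.slope_ == pytest.approx(sxy / sxx, abs=1e-10)
        assert fit.intercept_ == pytest.approx(y.mean() - (sxy / sxx) * x.mean(), abs=1e-10)
        assert fit.r_squared_ == pytest.approx(fit.pearson_r_**2, abs=1e-12)

    def test_identity_data_gives_unit_gain(self):
        x = np.linspace(-20, 20, 50)
        df = pd.DataFrame({"trajectory": x, "pitch_at_peak": x})
        fit = fit_steering(df)
        assert fit.steering_gain_ == pytest.approx(1.0, abs=1e-12)
        assert fit.pearson_r_ == pytest.approx(1.0, abs=1e-12)

    def test_righting_line_noise_free(self):
        x = np.array([-20.0, -5.0, 0.0, 10.0, 30.0])
        df = pd.DataFrame({"initial_pitch": x, "righting_rotation": -0.2 * (x - 10.0)})
        fit = fit_righting(df)
        assert fit.righting_gain_ == pytest.approx(0.2, abs=1e-12)
        assert fit.set_point_ == pytest.approx(10.0, abs=1e-10)
        # x-intercept identity
        assert fit.slope_ * fit.set_point_ + fit.intercept_ == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ols_on_four_points(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        # by hand: sxx=5, sxy=4 -> slope 0.8, intercept 1.3
        fit = SlopeInterceptRegression().fit(x, y)
        assert fit.slope_ == pytest.approx(0.8, abs=1e-12)
        assert fit.intercept_ == pytest.approx(1.3, abs=1e-12)

    def test_non_corrective_righting_warns(self):
        df = pd.DataFrame({"initial_pitch": [0.0, 1.0, 2.0], "righting_rotation": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="non-corrective"):
            fit_righting(df)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            SlopeInterceptRegression().fit(np.ones(5), np.arange(5.0))


class TestParabolaFit:
    def test_noise_free_vertex_form_recovered_exactly(self):
        x = np.linspace(-30, 40, 25)
        y = 0.001 * (x - 10.0) ** 2 + 0.5
        fit = QuadraticVertexRegression().fit(x, y)
        assert fit.a_ == pytest.approx(0.001, abs=1e-12)
        assert fit.b_ == pytest.approx(10.0, abs=1e-8)
        assert fit.c_ == pytest.approx(0.5, abs=1e-10)
        assert fit.sensitivity_mhz_ == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-30, 40, 20)
        y = 0.0012 * (x - 8.0) ** 2 + 0.5 + rng.normal(0, 0.2, 20)
        fit = QuadraticVertexRegression().fit(x, y)

        def sse(a, b, c):
            return np.sum((y - (a * (x - b) ** 2 + c)) ** 2)

        best = min(
            ((a, b, c) for a in np.linspace(0.0005, 0.002, 31)
             for b in np.linspace(4, 12, 33) for c in np.linspace(0.3, 0.8, 26)),
            key=lambda p: sse(*p),
        )
        assert fit.a_ == pytest.approx(best[0], abs=5e-5)
        assert fit.b_ == pytest.approx(best[1], abs=0.25)
        assert fit.c_ == pytest.approx(best[2], abs=0.02)
        assert sse(fit.a_, fit.b_, fit.c_) <= sse(*best) + 1e-9

    def test_degenerate_pitch_spread_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_bout_timing(pd.DataFrame({"mean_pitch": [1.0, 1.0, 2.0],
                                          "bout_frequency": [1.0, 1.0, 1.0]}))


class TestFinBody:
    def _features(self, x, y, speed=10.0, steering=None):
        n = len(x)
        return pd.DataFrame({
            "steering_related_rotation": x,
            "attack_angle": y,
            "steering_rotation": x if steering is None else steering,
            "peak_speed": np.full(n, speed),
        })

    def test_noise_free_logistic_ratio_and_derivative_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-6, 6, 400)
        y = -5.0 + 10.0 / (1.0 + np.exp(-2.0 * x))
        fit = fit_fin_body(self._features(x, y))
        assert fit.fin_body_ratio_ == pytest.approx(5.0, rel=1e-6)
        # numerical maximum of the fitted curve's derivative
        grid = np.linspace(-8, 8, 400001)
        slope = np.max(np.diff(fit.predict(grid)) / np.diff(grid))
        assert abs(slope - fit.fin_body_ratio_) / fit.fin_body_ratio_ < 1e-9 + 1e-7

    def test_slow_bouts_dropped_and_exclusion_rule_counted(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-6, 6, 60)
        y = -5.0 + 10.0 / (1.0 + np.exp(-1.0 * x)) + rng.normal(0, 0.2, 60)
        feats = self._features(x, y)
        # three constructed offenders: steering above the median, negative attack
        extra = pd.DataFrame({
            "steering_related_rotation": [5.0, 5.5, 6.0],
            "attack_angle": [-1.0, -2.0, -0.5],
            "steering_rotation": [50.0, 55.0, 60.0],
            "peak_speed": [10.0, 10.0, 10.0],
        })
        slow = self._features(x[:5], y[:5], speed=6.0)  # below the 7 mm/s cut
        fit = fit_fin_body(pd.concat([feats, extra, slow], ignore_index=True))
        assert fit.n_excluded_ == 3
        assert fit.n_used_ == 60

    def test_too_few_fast_bouts_rejected(self):
        feats = self._features(np.arange(5.0), np.arange(5.0), speed=6.0)
        with pytest.raises(ValueError, match="mm/s"):
            fit_fin_body(feats)


class TestAngularVelocity:
    def test_triangular_angular_velocity_peak_time(self):
        fps = 100.0
        n_pre = 50
        t = (np.arange(81) - n_pre) * 10.0  # ms
        av = np.maximum(0.0, 1.0 - np.abs(t + 40.0) / 100.0)  # peak at -40 ms
        pitch = np.cumsum(av) * 10.0 / 1000.0
        b = _make_bout(pitch=0.0, fps=fps)
        b.pitch = pitch
        summary = angular_velocity_summary([b], smoothing=1)
        assert summary.mean_peak_time == pytest.approx(40.0, abs=10.0 + 1e-9)

    def test_eleven_frame_moving_average_hand_checked(self):
        from vswim.kinematics import _smooth

        ramp = np.arange(40.0)
        sm = _smooth(ramp, 11)
        for i in (15, 20, 25):  # interior points: mean of i-5..i+5 = i
            assert sm[i] == pytest.approx(np.mean(ramp[i - 5 : i + 6]), abs=1e-12)

    def test_nose_down_bouts_are_sign_flipped(self):
        b_up = _make_bout(pitch=0.0)
        b_up.pitch = np.linspace(0.0, 10.0, 81)
        b_down = _make_bout(pitch=0.0)
        b_down.pitch = np.linspace(0.0, -10.0, 81)
        s = angular_velocity_summary([b_up, b_down], smoothing=1)
        trace = next(iter(s.median_traces.values()))
        assert trace[10] > 0  # both bouts contribute positive angular velocity

    def test_window_longer_than_bout_rejected(self):
        with pytest.raises(ValueError, match="smoothing window"):
            angular_velocity_summary([_make_bout(0.0)], smoothing=101)

    def test_session_peak_time_matches_generator_lead(self, quiet_session, quiet_profile):
        fr = quiet_profile.frame_rate
        series = compute_speed(trace_to_records(quiet_session), frame_rate=fr)
        kept, _ = select_epochs(series, frame_rate=fr)
        bouts = extract_bouts(kept, frame_rate=fr)
        s = angular_velocity_summary(bouts)
        assert abs(s.mean_peak_time - quiet_profile.angvel_peak_lead) <= 2000.0 / fr


class TestBinnedAverage:
    def test_constant_y_gives_constant_bins(self):
        x = np.linspace(0, 10, 50)
        out = binned_average(x, np.full(50, 3.0), 1.0)
        assert np.allclose(out["y_mean"], 3.0)

    def test_two_points_in_one_bin(self):
        out = binned_average([1.1, 1.9], [2.0, 4.0], 3.0)
        assert len(out) == 1
        assert out["y_mean"].iloc[0] == pytest.approx(3.0)

    def test_identity_data_bins_to_member_means(self):
        x = np.array([0.2, 0.8, 1.4, 1.6, 2.9])
        out = binned_average(x, x, 1.0)
        assert np.allclose(out["y_mean"], out["x_mean"])
        assert len(out) == 3  # empty bins omitted


class TestRepeatsAndComparison:
    def _synthetic_repeat(self, rid, seed):
        from vswim.profiles import make_profile
        from vswim.synth import generate_relationship_samples, relationship_params

        p = make_profile("7dpf")
        rng = np.random.default_rng(seed)
        n = 600
        xs, ys = generate_relationship_samples("steering", relationship_params(p, "steering"), n, rng)
        xr, yr = generate_relationship_samples("righting", relationship_params(p, "righting"), n, rng)
        xf, yf = generate_relationship_samples("finbody", relationship_params(p, "finbody"), n, rng)
        feats = pd.DataFrame({
            "trajectory": xs, "pitch_at_peak": ys,
            "initial_pitch": xr, "righting_rotation": yr,
            "steering_related_rotation": xf, "attack_angle": yf,
            "steering_rotation": 2 * xf,
            "peak_speed": np.full(n, 12.0),
            "repeat_id": rid,
        })
        xt, yt = generate_relationship_samples("timing", relationship_params(p, "timing"), n, rng)
        ibis = pd.DataFrame({"mean_pitch": xt, "bout_frequency": yt, "repeat_id": rid})
        return feats, ibis

    def test_per_repeat_means_match_report(self):
        fa, ia = self._synthetic_repeat("r0", 1)
        fb, ib = self._synthetic_repeat("r1", 2)
        feats = pd.concat([fa, fb], ignore_index=True)
        ibis = pd.concat([ia, ib], ignore_index=True)
        report = analyze_repeats(feats, ibis, condition="7dpf-like")
        means = report.parameter_means()
        per = report.per_repeat
        assert means["steering_gain"] == pytest.approx(per["steering_gain"].mean())
        assert report.summary.loc[report.summary.parameter == "steering_gain", "n_repeats"].iloc[0] == 2
        # recovered near generating values
        assert means["steering_gain"] == pytest.approx(0.67, abs=0.05)
        assert means["righting_gain"] == pytest.approx(0.18, abs=0.05)

    def test_single_repeat_reports_zero_sd(self):
        fa, ia = self._synthetic_repeat("r0", 3)
        report = analyze_repeats(fa, ia)
        sd = dict(zip(report.summary["parameter"], report.summary["sd"]))
        assert sd["steering_gain"] == 0.0

    def test_identical_reports_compare_to_zero(self):
        ref = {"steering_gain": 0.67, "sensitivity": 1.06}
        table = compare_profiles(ref, dict(ref))
        assert np.allclose(table["percent_change"], 0.0)

    def test_zero_reference_flagged(self):
        with pytest.warns(UserWarning, match="zero"):
            table = compare_profiles({"a": 0.0}, {"a": 1.0})
        assert np.isnan(table["percent_change"].iloc[0])
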