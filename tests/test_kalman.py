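import numpy as np
import pytest

from _oracles import ar1_slope, joint_gaussian_scalar
from mtsr.kalman import (StateSpaceParams, default_initial_params, em_fit,
                         kalman_filter, mlk_predict, rts_smooth)


def random_scalar_system(rng):
    return StateSpaceParams(F=rng.uniform(-1.2, 1.2), H=rng.uniform(0.5, 2.0),
                            Q=rng.uniform(0.05, 2.0), R=rng.uniform(0.05, 2.0),
                            mu0=[rng.normal()], Sigma0=rng.uniform(0.1, 3.0))


def check_against_oracle(theta, y, tol=1e-8):
    filt = kalman_filter(y, theta)
    sm = rts_smooth(filt, theta)
    ora = joint_gaussian_scalar(theta, y)
    assert np.allclose(filt.x_filt[:, 0], ora["filt_mean"], atol=tol)
    assert np.allclose(filt.P_filt[:, 0, 0], ora["filt_var"], atol=tol)
    assert np.allclose(sm.x_smooth[:, 0], ora["smooth_mean"], atol=tol)
    assert np.allclose(sm.P_smooth[:, 0, 0], ora["smooth_var"], atol=tol)
    assert np.allclose(sm.P_cross[1:, 0, 0], ora["smooth_lag1"][1:], atol=tol)
    assert filt.loglik == pytest.approx(ora["loglik"], abs=tol)


def test_filter_smoother_match_joint_gaussian_oracle():
    """Recursions agree with dense brute-force conditioning for N <= 6."""
    rng = np.random.default_rng(20240601)
    for trial in range(12):
        theta = random_scalar_system(rng)
        n = int(rng.integers(2, 7))
        y = rng.normal(size=n) * 3
        check_against_oracle(theta, y)


def test_matrix_path_matches_scalar_path():
    """A 2-D block of two independent scalar systems reproduces two scalar runs."""
    rng = np.random.default_rng(3)
    t1 = random_scalar_system(rng)
    t2 = random_scalar_system(rng)
    y1, y2 = rng.normal(size=8), rng.normal(size=8)

    def b(a, c):
        return np.diag([float(np.atleast_2d(a)[0, 0]), float(np.atleast_2d(c)[0, 0])])

    theta = StateSpaceParams(F=b(t1.F, t2.F), H=b(t1.H, t2.H), Q=b(t1.Q, t2.Q),
                             R=b(t1.R, t2.R), mu0=[t1.mu0[0], t2.mu0[0]],
                             Sigma0=b(t1.Sigma0, t2.Sigma0))
    filt = kalman_filter(np.column_stack([y1, y2]), theta)
    sm = rts_smooth(filt, theta)
    f1, f2 = kalman_filter(y1, t1), kalman_filter(y2, t2)
    s1, s2 = rts_smooth(f1, t1), rts_smooth(f2, t2)
    assert np.allclose(filt.x_filt[:, 0], f1.x_filt[:, 0], atol=1e-10)
    assert np.allclose(filt.x_filt[:, 1], f2.x_filt[:, 0], atol=1e-10)
    assert np.allclose(sm.x_smooth[:, 0], s1.x_smooth[:, 0], atol=1e-10)
    assert np.allclose(sm.x_smooth[:, 1], s2.x_smooth[:, 0], atol=1e-10)
    assert filt.loglik == pytest.approx(f1.loglik + f2.loglik, abs=1e-8)


def test_first_innovation_uses_prior():
    theta = StateSpaceParams(F=1.0, H=2.0, Q=1.0, R=1.0, mu0=[3.0], Sigma0=1.0)
    filt = kalman_filter([10.0, 11.0], theta)
    assert filt.innovations[0, 0] == pytest.approx(10.0 - 2.0 * 3.0)


def test_static_model_filter_is_running_mean():
    """F=1, Q=0, diffuse prior: the filter averages the observations."""
    theta = StateSpaceParams(F=1.0, H=1.0, Q=0.0, R=1.0, mu0=[0.0], Sigma0=1e12)
    y = np.array([4.0, 6.0, 8.0])
    filt = kalman_filter(y, theta)
    assert filt.x_filt[2, 0] == pytest.approx(6.0, abs=1e-6)
    sm = rts_smooth(filt, theta)
    # with no process noise every smoothed state equals the final estimate
    assert np.allclose(sm.x_smooth[:, 0], filt.x_filt[2, 0], atol=1e-6)


def test_small_R_tracks_observations():
    theta = StateSpaceParams(F=1.0, H=1.0, Q=1.0, R=1e-12, mu0=[0.0], Sigma0=1.0)
    y = np.sin(np.arange(20.0))
    filt = kalman_filter(y, theta)
    assert np.allclose(filt.x_filt[:, 0], y, atol=1e-5)


def test_smoothing_reduces_variance_and_matches_filter_at_end():
    rng = np.random.default_rng(12)
    theta = random_scalar_system(rng)
    y = rng.normal(size=30)
    filt = kalman_filter(y, theta)
    sm = rts_smooth(filt, theta)
    assert sm.x_smooth[-1, 0] == pytest.approx(filt.x_filt[-1, 0])
    assert np.all(sm.P_smooth[:, 0, 0] <= filt.P_filt[:, 0, 0] + 1e-10)


def test_filter_input_validation():
    theta = StateSpaceParams(F=1.0, H=1.0, Q=1.0, R=1.0, mu0=[0.0], Sigma0=1.0)
    with pytest.raises(ValueError):
        kalman_filter([np.nan, 1.0], theta)
    with pytest.raises(ValueError):
        StateSpaceParams(F=1.0, H=1.0, Q=1.0, R=0.0, mu0=[0.0], Sigma0=1.0)
    with pytest.raises(ValueError):
        StateSpaceParams(F=1.0, H=1.0, Q=-1.0, R=1.0, mu0=[0.0], Sigma0=1.0)


def simulate_ar1(f, q, r, n, seed):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, np.sqrt(q / (1 - f**2)))
    for i in range(1, n):
        x[i] = f * x[i - 1] + rng.normal(0.0, np.sqrt(q))
    return x + rng.normal(0.0, np.sqrt(r), n)


def test_em_loglik_monotone_and_converges():
    y = simulate_ar1(0.9, 0.3, 0.3, 300, seed=2)
    res = em_fit(y)
    diffs = np.diff(res.logliks)
    assert np.all(diffs >= -1e-9 * (1 + np.abs(res.logliks[:-1])))
    assert res.converged
    assert res.params.Q[0, 0] > 0 and res.params.R[0, 0] > 0
    assert len(res.prediction) == 300


def test_em_slope_tracks_ar1_regression():
    """Fitted F should sit near the lag-1 regression slope of a clean AR(1)."""
    y = simulate_ar1(0.85, 0.5, 1e-4, 1500, seed=8)
    res = em_fit(y, max_iter=200)
    assert float(res.params.F[0, 0]) == pytest.approx(ar1_slope(y), abs=0.05)


def test_em_parameter_recovery_fixed_seed():
    """Recovery at N = 2000; bounds are 3 Monte-Carlo SDs measured from
    replicate fits of this exact generator (F: 0.026, Q: 0.055, R: 0.035)."""
    y = simulate_ar1(0.8, 0.5, 0.3, 2000, seed=424242)
    res = em_fit(y, max_iter=200, tol=1e-8)
    assert float(res.params.F[0, 0]) == pytest.approx(0.8, abs=0.078)
    assert float(res.params.Q[0, 0]) == pytest.approx(0.5, abs=0.166)
    assert float(res.params.R[0, 0]) == pytest.approx(0.3, abs=0.106)


def test_em_requires_three_observations():
    with pytest.raises(ValueError):
        em_fit(np.array([1.0, 2.0]))


def test_default_initial_params_scale_aware():
    y = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
    theta = default_initial_params(y)
    assert theta.mu0[0] == pytest.approx(1.0)
    assert float(theta.Q[0, 0]) == pytest.approx(float(np.var(np.diff(y))) / 2)


def test_mlk_predict_shapes_and_determinism():
    rng = np.random.default_rng(5)
    frames = [rng.normal(size=60).cumsum() for _ in range(4)]
    preds = mlk_predict(frames)
    again = mlk_predict(frames)
    assert len(preds) == 4
    for p, q in zip(preds, again):
        assert np.array_equal(p, q)
        assert len(p) == 60


def test_mlk_predict_annotates_failing_frame():
    frames = [np.arange(10.0), np.full(10, np.nan)]
    with pytest.raises(RuntimeError, match="frame 2"):
        mlk_predict(frames)
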