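"""Independent reference computations used to check the implementation.

The linear-Gaussian oracle builds the full joint distribution of states
and observations by direct covariance propagation and conditions it with
dense matrix algebra — no recursions — so agreement with the Kalman
filter/smoother is a genuine cross-check, feasible for short records.
"""

from __future__ import annotations

import numpy as np


def joint_gaussian_scalar(theta, y):
    """Exact posterior moments of a scalar linear-Gaussian system.

    Returns a dict with filtered means/variances (x_t | y_0..y_t),
    smoothed means/variances (x_t | all y), smoothed lag-one
    cross-covariances, and the marginal log-likelihood of y.
    """
    y = np.asarray(y, dtype=float).ravel()
    N = len(y)
    f = float(np.atleast_2d(theta.F)[0, 0])
    h = float(np.atleast_2d(theta.H)[0, 0])
    q = float(np.atleast_2d(theta.Q)[0, 0])
    r = float(np.atleast_2d(theta.R)[0, 0])
    mu0 = float(np.atleast_1d(theta.mu0)[0])
    s0 = float(np.atleast_2d(theta.Sigma0)[0, 0])

    # prior mean and covariance of (x_0, ..., x_{N-1})
    m = np.array([mu0 * f**t for t in range(N)])
    S = np.empty((N, N))
    for t in range(N):
        for u in range(N):
            v = f**t * s0 * f**u
            for j in range(1, min(t, u) + 1):
                v += f ** (t - j) * q * f ** (u - j)
            S[t, u] = v

    C_yy = h * S * h + r * np.eye(N)
    C_xy = S * h

    def condition(t_obs):
        """Posterior of all states given y[:t_obs]."""
        idx = np.arange(t_obs)
        A = C_xy[:, idx]
        B = C_yy[np.ix_(idx, idx)]
        gain = A @ np.linalg.inv(B)
        mean = m + gain @ (y[idx] - h * m[idx])
        cov = S - gain @ A.T
        return mean, cov

    filt_mean = np.empty(N)
    filt_var = np.empty(N)
    for t in range(N):
        mean, cov = condition(t + 1)
        filt_mean[t] = mean[t]
        filt_var[t] = cov[t, t]
    sm_mean, sm_cov = condition(N)

    sign, logdet = np.linalg.slogdet(C_yy)
    resid = y - h * m
    loglik = -0.5 * (N * np.log(2 * np.pi) + logdet
                     + float(resid @ np.linalg.inv(C_yy) @ resid))
    return {
        "filt_mean": filt_mean,
        "filt_var": filt_var,
        "smooth_mean": sm_mean,
        "smooth_var": np.diag(sm_cov).copy(),
        "smooth_lag1": np.array([sm_cov[t, t - 1] if t else 0.0
                                 for t in range(N)]),
        "loglik": loglik,
    }


def ar1_slope(y):
    """Least-squares slope of y_n on y_{n-1} (no intercept removal of trend)."""
    y = np.asarray(y, dtype=float).ravel()
    a, b = y[:-1], y[1:]
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / (a @ a))
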