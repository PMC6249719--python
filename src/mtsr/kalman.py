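"""Kalman filtering, RTS smoothing and EM maximum-likelihood estimation.

The interpolated microtubule frames are modelled as observations of a
linear-Gaussian dynamic system

    x_{n+1} = F x_n + w_n,   w_n ~ N(0, Q)
    y_n     = H x_n + v_n,   v_n ~ N(0, R)

with Gaussian initial state (mu0, Sigma0).  The forward (filter) pass
produces the innovations and the negative log-likelihood; the backward
Rauch-Tung-Striebel pass produces fixed-interval smoothed moments and
lag-one cross-covariances; EM alternates these sufficient statistics with
closed-form parameter updates.  The smoothed state sequence of each frame
is its maximum-likelihood Kalman (MLK) prediction.

All quantities are handled as matrices so vector states work, but the
microtubule signal is one-dimensional and the scalar case is the tested
default.  H is held fixed (identity) during EM: with scalar states the
pair (H, F, Q, R) is not identifiable under similarity scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StateSpaceParams",
    "FilterResult",
    "SmootherResult",
    "EMResult",
    "kalman_filter",
    "rts_smooth",
    "em_fit",
    "mlk_predict",
    "default_initial_params",
]

_LOG2PI = math.log(2.0 * math.pi)


def _as_matrix(a, name: str) -> np.ndarray:
    m = np.atleast_2d(np.asarray(a, dtype=float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    return m


@dataclass
class StateSpaceParams:
    """Parameters theta = (F, H, Q, R, mu0, Sigma0) of the linear system."""

    F: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    mu0: np.ndarray
    Sigma0: np.ndarray

    def __post_init__(self) -> None:
        self.F = _as_matrix(self.F, "F")
        self.H = _as_matrix(self.H, "H")
        self.Q = _as_matrix(self.Q, "Q")
        self.R = _as_matrix(self.R, "R")
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        self.Sigma0 = _as_matrix(self.Sigma0, "Sigma0")
        k = self.F.shape[0]
        if self.Q.shape[0] != k or self.Sigma0.shape[0] != k or len(self.mu0) != k:
            raise ValueError("inconsistent state dimensions")
        if self.H.shape[0] != self.R.shape[0]:
            raise ValueError("inconsistent observation dimensions")
        for name in ("Q", "R", "Sigma0"):
            m = getattr(self, name)
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
        if np.linalg.eigvalsh((self.R + self.R.T) / 2).min() <= 0:
            raise ValueError("R must be positive definite")

    @property
    def state_dim(self) -> int:
        return self.F.shape[0]


@dataclass
class FilterResult:
    """Forward-pass moments, innovations and the negative log-likelihood."""

    x_pred: np.ndarray       # x_{n|n-1}, shape (N, k)
    P_pred: np.ndarray       # Sigma_{n|n-1}, shape (N, k, k)
    x_filt: np.ndarray       # x_{n|n}
    P_filt: np.ndarray       # Sigma_{n|n}
    innovations: np.ndarray  # e_n
    innovation_cov: np.ndarray  # Sigma_{e_n}
    gains: np.ndarray        # K_n
    P_cross_filt: np.ndarray  # Sigma_{n,n-1|n} = (I - K_n H) F Sigma_{n-1|n-1}
    loglik: float            # observed-data log-likelihood L
    y: np.ndarray = field(repr=False, default=None)

    @property
    def neg_loglik(self) -> float:
        """J = -L, the negative log-likelihood the filter minimizes."""
        return -self.loglik


@dataclass
class SmootherResult:
    """Backward-pass (fixed-interval) moments."""

    x_smooth: np.ndarray     # x_{n|N}
    P_smooth: np.ndarray     # Sigma_{n|N}
    P_cross: np.ndarray      # Sigma_{n,n-1|N}, entry 0 unused
    gains: np.ndarray        # A_n (backward gains), entry 0 unused


@dataclass
class EMResult:
    """Fitted parameters, objective trace and the smoothed prediction."""

    params: StateSpaceParams
    logliks: list[float]
    n_iter: int
    converged: bool
    prediction: np.ndarray   # smoothed state sequence (MLK prediction)


def _sym(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def kalman_filter(y: np.ndarray, theta: StateSpaceParams) -> FilterResult:
    """Run the forward Kalman recursions over observations ``y``.

    The first step predicts from the prior (e_1 = y_1 - H mu0).  Raises
    ``FloatingPointError`` naming the step if an innovation covariance is
    not positive definite.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    N = y.shape[0]
    if N < 1 or not np.all(np.isfinite(y)):
        raise ValueError("observations must be finite and non-empty")
    k = theta.state_dim
    m = theta.H.shape[0]
    if k == 1 and m == 1:
        return _kalman_filter_scalar(y, theta)
    F, H, Q, R = theta.F, theta.H, theta.Q, theta.R
    I = np.eye(k)

    x_pred = np.zeros((N, k))
    P_pred = np.zeros((N, k, k))
    x_filt = np.zeros((N, k))
    P_filt = np.zeros((N, k, k))
    e = np.zeros((N, m))
    S = np.zeros((N, m, m))
    K = np.zeros((N, k, m))
    P_cross = np.zeros((N, k, k))

    loglik = 0.0
    xp, Pp = theta.mu0.copy(), theta.Sigma0.copy()
    for n in range(N):
        x_pred[n], P_pred[n] = xp, _sym(Pp)
        e[n] = y[n] - H @ xp
        S[n] = _sym(H @ P_pred[n] @ H.T + R)
        sign, logdet = np.linalg.slogdet(S[n])
        if sign <= 0:
            raise FloatingPointError(
                f"innovation covariance not positive definite at step {n}")
        Sinv = np.linalg.inv(S[n])
        K[n] = P_pred[n] @ H.T @ Sinv
        x_filt[n] = x_pred[n] + K[n] @ e[n]
        P_filt[n] = _sym(P_pred[n] - K[n] @ S[n] @ K[n].T)
        loglik += -0.5 * (m * _LOG2PI + logdet + float(e[n] @ Sinv @ e[n]))
        if n >= 1:
            P_cross[n] = (I - K[n] @ H) @ F @ P_filt[n - 1]
        xp = F @ x_filt[n]
        Pp = F @ P_filt[n] @ F.T + Q
    return FilterResult(x_pred=x_pred, P_pred=P_pred, x_filt=x_filt,
                        P_filt=P_filt, innovations=e, innovation_cov=S,
                        gains=K, P_cross_filt=P_cross, loglik=loglik, y=y)


def _kalman_filter_scalar(y: np.ndarray, theta: StateSpaceParams) -> FilterResult:
    """Plain-float forward pass for the 1-D system (same recursions)."""
    yv = y[:, 0]
    N = len(yv)
    f = float(theta.F[0, 0])
    h = float(theta.H[0, 0])
    q = float(theta.Q[0, 0])
    r = float(theta.R[0, 0])
    x_pred = np.empty(N)
    P_pred = np.empty(N)
    x_filt = np.empty(N)
    P_filt = np.empty(N)
    e = np.empty(N)
    S = np.empty(N)
    K = np.empty(N)
    P_cross = np.zeros(N)
    loglik = 0.0
    xp = float(theta.mu0[0])
    Pp = float(theta.Sigma0[0, 0])
    for n in range(N):
        x_pred[n], P_pred[n] = xp, Pp
        e[n] = yv[n] - h * xp
        S[n] = h * Pp * h + r
        if S[n] <= 0:
            raise FloatingPointError(
                f"innovation covariance not positive definite at step {n}")
        K[n] = Pp * h / S[n]
        x_filt[n] = xp + K[n] * e[n]
        P_filt[n] = Pp - K[n] * S[n] * K[n]
        loglik += -0.5 * (_LOG2PI + math.log(S[n]) + e[n] * e[n] / S[n])
        if n >= 1:
            P_cross[n] = (1.0 - K[n] * h) * f * P_filt[n - 1]
        xp = f * x_filt[n]
        Pp = f * P_filt[n] * f + q
    shape3 = (N, 1, 1)
    return FilterResult(x_pred=x_pred[:, None], P_pred=P_pred.reshape(shape3),
                        x_filt=x_filt[:, None], P_filt=P_filt.reshape(shape3),
                        innovations=e[:, None],
                        innovation_cov=S.reshape(shape3),
                        gains=K.reshape(shape3),
                        P_cross_filt=P_cross.reshape(shape3),
                        loglik=loglik, y=y)


def rts_smooth(filt: FilterResult, theta: StateSpaceParams) -> SmootherResult:
    """Backward Rauch-Tung-Striebel fixed-interval smoothing.

    The lag-one cross-covariance uses the identity
    Sigma_{n,n-1|N} = Sigma_{n|N} Sigma_{n|n}^{-1} Sigma_{n,n-1|n},
    with Sigma_{n,n-1|n} taken from the forward pass.  Singular predicted
    covariances fall back to the pseudo-inverse.
    """
    N, k = filt.x_filt.shape
    if k == 1:
        return _rts_smooth_scalar(filt, theta)
    F = theta.F
    x_s = filt.x_filt.copy()
    P_s = filt.P_filt.copy()
    A = np.zeros((N, k, k))
    P_cross = np.zeros((N, k, k))

    for n in range(N - 1, 0, -1):
        try:
            Pinv = np.linalg.inv(filt.P_pred[n])
        except np.linalg.LinAlgError:
            Pinv = np.linalg.pinv(filt.P_pred[n])
        A[n] = filt.P_filt[n - 1] @ F.T @ Pinv
        x_s[n - 1] = filt.x_filt[n - 1] + A[n] @ (x_s[n] - filt.x_pred[n])
        P_s[n - 1] = _sym(filt.P_filt[n - 1]
                          + A[n] @ (P_s[n] - filt.P_pred[n]) @ A[n].T)
        Pf_inv = np.linalg.pinv(filt.P_filt[n])
        P_cross[n] = P_s[n] @ Pf_inv @ filt.P_cross_filt[n]
    return SmootherResult(x_smooth=x_s, P_smooth=P_s, P_cross=P_cross, gains=A)


def _rts_smooth_scalar(filt: FilterResult, theta: StateSpaceParams) -> SmootherResult:
    """Plain-float backward pass for the 1-D system."""
    N = filt.x_filt.shape[0]
    f = float(theta.F[0, 0])
    xf = filt.x_filt[:, 0]
    Pf = filt.P_filt[:, 0, 0]
    xp = filt.x_pred[:, 0]
    Pp = filt.P_pred[:, 0, 0]
    Pcf = filt.P_cross_filt[:, 0, 0]
    x_s = xf.copy()
    P_s = Pf.copy()
    A = np.zeros(N)
    P_cross = np.zeros(N)
    for n in range(N - 1, 0, -1):
        A[n] = Pf[n - 1] * f / Pp[n] if Pp[n] != 0 else 0.0
        x_s[n - 1] = xf[n - 1] + A[n] * (x_s[n] - xp[n])
        P_s[n - 1] = Pf[n - 1] + A[n] * (P_s[n] - Pp[n]) * A[n]
        P_cross[n] = P_s[n] / Pf[n] * Pcf[n] if Pf[n] != 0 else 0.0
    shape3 = (N, 1, 1)
    return SmootherResult(x_smooth=x_s[:, None], P_smooth=P_s.reshape(shape3),
                          P_cross=P_cross.reshape(shape3),
                          gains=A.reshape(shape3))


def default_initial_params(y: np.ndarray) -> StateSpaceParams:
    """Scale-aware EM starting point for a scalar series.

    F = 1 (random walk), Q = R = var(diff(y))/2 (the one-step increment
    variance split evenly between process and measurement noise),
    mu0 = y_1, Sigma0 = var(y).
    """
    y = np.asarray(y, dtype=float).ravel()
    dv = float(np.var(np.diff(y)))
    dv = max(dv, 1e-8)
    s0 = max(float(np.var(y)), 1e-8)
    return StateSpaceParams(F=1.0, H=1.0, Q=dv / 2, R=dv / 2,
                            mu0=[y[0]], Sigma0=s0)


_VAR_FLOOR = 1e-12


def em_fit(y: np.ndarray, theta0: StateSpaceParams | None = None,
           max_iter: int = 100, tol: float = 1e-6) -> EMResult:
    """Fit (F, Q, R, mu0, Sigma0) by EM, H held fixed.

    E-step: Kalman filter + RTS smoother sufficient statistics.  M-step:
    the closed-form updates from the smoothed first and second moments.
    Stops when the relative change of the observed-data log-likelihood
    falls below ``tol``; the likelihood trace must be non-decreasing (a
    decrease beyond numerical slack raises ``RuntimeError``).
    """
    y = np.asarray(y, dtype=float)
    y2d = y[:, None] if y.ndim == 1 else y
    N = y2d.shape[0]
    if N < 3:
        raise ValueError("EM needs at least 3 observations")
    theta = theta0 if theta0 is not None else default_initial_params(y2d.ravel())
    k = theta.state_dim
    H = theta.H

    logliks: list[float] = []
    converged = False
    smoothed = None
    for it in range(max_iter):
        filt = kalman_filter(y2d, theta)
        sm = rts_smooth(filt, theta)
        smoothed = sm
        logliks.append(filt.loglik)
        if len(logliks) >= 2:
            prev, cur = logliks[-2], logliks[-1]
            if cur < prev - 1e-9 * (1.0 + abs(prev)):
                raise RuntimeError(
                    f"EM objective decreased at iteration {it}: "
                    f"{prev} -> {cur}; trace={logliks}")
            if abs(cur - prev) <= tol * (1.0 + abs(prev)):
                converged = True
                break

        xs, Ps, Pc = sm.x_smooth, sm.P_smooth, sm.P_cross
        # smoothed second moments E[x_n x_n^T | Y] and E[x_n x_{n-1}^T | Y]
        Exx = Ps + np.einsum("ni,nj->nij", xs, xs)
        Excross = Pc[1:] + np.einsum("ni,nj->nij", xs[1:], xs[:-1])
        A = Exx[:-1].sum(axis=0)
        B = Excross.sum(axis=0)
        C = Exx[1:].sum(axis=0)

        F_new = B @ np.linalg.inv(A)
        Q_new = _sym((C - F_new @ B.T) / (N - 1))
        resid = y2d - xs @ H.T
        R_new = _sym((resid.T @ resid
                      + H @ Ps.sum(axis=0) @ H.T) / N)
        # variance floors prevent degenerate collapse
        Q_new += _VAR_FLOOR * np.eye(k)
        R_new += _VAR_FLOOR * np.eye(H.shape[0])
        mu0_new = xs[0].copy()
        Sigma0_new = _sym(Ps[0]) + _VAR_FLOOR * np.eye(k)
        theta = StateSpaceParams(F=F_new, H=H, Q=Q_new, R=R_new,
                                 mu0=mu0_new, Sigma0=Sigma0_new)

    if not converged:
        # make the returned prediction consistent with the final parameters
        filt = kalman_filter(y2d, theta)
        smoothed = rts_smooth(filt, theta)
    prediction = smoothed.x_smooth[:, 0] if k == 1 else smoothed.x_smooth
    return EMResult(params=theta, logliks=logliks, n_iter=len(logliks),
                    converged=converged, prediction=prediction)


def mlk_predict(frames, em_config: dict | None = None) -> list[np.ndarray]:
    """EM-fit each interpolated frame and return its smoothed prediction.

    ``frames`` is a FrameDictionary (or any object with an ``interpolated``
    list of equal-length signals).  Each frame is fitted independently,
    giving the d+1 maximum-likelihood Kalman predictions.
    """
    cfg = dict(em_config or {})
    interpolated = getattr(frames, "interpolated", frames)
    predictions = []
    for idx, y in enumerate(interpolated):
        try:
            res = em_fit(np.asarray(y, dtype=float), **cfg)
        except Exception as exc:  # noqa: BLE001 - annotate with frame index
            raise RuntimeError(f"EM failed on frame {idx + 1}: {exc}") from exc
        predictions.append(res.prediction)
    return predictions
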