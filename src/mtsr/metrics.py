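"""Reconstruction-quality metrics: signal-to-noise ratio and RMSE."""

from __future__ import annotations

import numpy as np

__all__ = ["snr_db", "rmse", "SNR_CAP_DB"]

SNR_CAP_DB = 300.0


def _check(x, xhat) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    xhat = np.asarray(xhat, dtype=float).ravel()
    if x.shape != xhat.shape or x.size == 0:
        raise ValueError("reference and estimate must have equal nonzero length")
    return x, xhat


def snr_db(x, xhat, cap: float = SNR_CAP_DB) -> float:
    """10 log10 of signal power over error power, in dB.

    A zero-error estimate is reported at the ``cap`` (default 300 dB)
    instead of infinity.
    """
    x, xhat = _check(x, xhat)
    err = float(((x - xhat) ** 2).sum())
    if err == 0.0:
        return cap
    return min(cap, 10.0 * np.log10(float((x**2).sum()) / err))


def rmse(x, xhat) -> float:
    """Root mean squared error, in the units of the signal."""
    x, xhat = _check(x, xhat)
    return float(np.sqrt(np.mean((x - xhat) ** 2)))
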