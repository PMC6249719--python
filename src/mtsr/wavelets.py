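"""Wavelet decomposition and energy-packing-efficiency peak detection.

Transitions between growth, pause and shrinkage show up as large detail
coefficients at the finest wavelet scale, where the time bins are
narrowest.  The fused signal is decomposed with an orthogonal Daubechies
wavelet (db2 by default, periodized boundaries) and the finest-level
coefficients are ranked by energy; the minimal set whose cumulative
energy reaches a stated fraction (85% by default) of the total

    E_TOT = sum(swc^2),      E_TH >= threshold * E_TOT

is retained, and each retained coefficient is mapped back to a sample
position, giving the candidate transition points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = ["WaveletDecomp", "PeakSet", "dwt", "idwt", "epe_peaks"]

DEFAULT_WAVELET = "db2"
DEFAULT_LEVELS = 8
DEFAULT_EPE_THRESHOLD = 0.85
# Boundary handling matters for trending length records: periodization
# creates an artificial end-to-start jump and reflection creates an
# artificial slope flip, and either spurious kink can dwarf every real
# transition coefficient and starve the EPE budget.  Linear-extrapolation
# ("smooth") padding is annihilated by the two vanishing moments of db2,
# so it is the default; periodization remains available (it is the
# energy-conserving orthogonal choice).
DEFAULT_MODE = "smooth"


@dataclass
class WaveletDecomp:
    """Multilevel DWT coefficients of a length-N signal."""

    approx: np.ndarray            # c_{j0}(k), coarsest approximation
    details: list[np.ndarray]     # d_j(k), finest level first
    wavelet: str
    levels: int                   # effective decomposition depth
    requested_levels: int
    mode: str
    signal_length: int

    @property
    def finest_details(self) -> np.ndarray:
        """Detail coefficients at the narrowest time bins (level 1)."""
        return self.details[0]


@dataclass
class PeakSet:
    """EPE-selected transition-point candidates."""

    positions: np.ndarray         # 0-based sample indices, sorted unique
    coefficient_indices: np.ndarray  # retained finest-level indices
    retained_coefficients: np.ndarray  # their swc values
    e_tot: float
    e_th: float
    threshold: float


def max_feasible_level(n: int, wavelet: str) -> int:
    """Largest strict dyadic depth: floor(log2(n / (Lf - 1)))."""
    return pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)


def dwt(x: np.ndarray, wavelet: str = DEFAULT_WAVELET,
        levels: int = DEFAULT_LEVELS, mode: str = DEFAULT_MODE) -> WaveletDecomp:
    """Multilevel discrete wavelet transform.

    The requested depth is capped at the maximum the signal length and
    filter length support (a 165-sample record cannot sustain 8 strict
    dyadic levels with db2); a warning reports the effective depth.
    """
    # force a writable contiguous copy: pywt rejects read-only buffers
    # (pandas .to_numpy() may hand back one)
    x = np.array(x, dtype=float).ravel()
    try:
        wav = pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet!r}") from exc
    if len(x) < wav.dec_len:
        raise ValueError("signal shorter than the wavelet filter")
    cap = max_feasible_level(len(x), wavelet)
    eff = min(levels, cap)
    if eff < levels:
        warnings.warn(f"requested {levels} levels but N={len(x)} with {wavelet} "
                      f"supports only {eff}; using {eff}")
    coeffs = pywt.wavedec(x, wav, mode=mode, level=eff)
    return WaveletDecomp(approx=coeffs[0], details=list(coeffs[:0:-1]),
                         wavelet=wavelet, levels=eff, requested_levels=levels,
                         mode=mode, signal_length=len(x))


def idwt(decomp: WaveletDecomp) -> np.ndarray:
    """Inverse multilevel transform; reproduces the input signal."""
    coeffs = [decomp.approx] + decomp.details[::-1]
    x = pywt.waverec(coeffs, decomp.wavelet, mode=decomp.mode)
    return x[: decomp.signal_length]


def _coef_to_sample(k: np.ndarray, n: int, mode: str) -> np.ndarray:
    # empirical alignment of a level-1 db-family coefficient with the
    # sample it responds to: 2k under symmetric padding (the extra edge
    # coefficients clip onto the record ends), 2k+1 under periodization
    if mode == "periodization":
        return np.minimum(2 * k + 1, n - 1)
    return np.clip(2 * k, 0, n - 1)


def epe_peaks(decomp: WaveletDecomp,
              threshold: float = DEFAULT_EPE_THRESHOLD) -> PeakSet:
    """Energy-packing-efficiency selection of finest-level coefficients.

    Coefficients are sorted by squared magnitude (descending, ties by
    lower index) and the shortest prefix whose cumulative energy reaches
    ``threshold`` of the total is retained; retained indices are mapped to
    sample positions, de-duplicated and sorted.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    swc = np.asarray(decomp.finest_details, dtype=float)
    if swc.size == 0:
        raise ValueError("finest-level details are empty")
    energies = swc**2
    e_tot = float(energies.sum())
    if e_tot == 0.0:
        warnings.warn("all finest-level coefficients are zero; no peaks")
        empty = np.array([], dtype=int)
        return PeakSet(positions=empty, coefficient_indices=empty,
                       retained_coefficients=np.array([]), e_tot=0.0,
                       e_th=0.0, threshold=threshold)
    order = np.lexsort((np.arange(swc.size), -energies))
    cum = np.cumsum(energies[order])
    m = int(np.searchsorted(cum, threshold * e_tot - 1e-12)) + 1
    keep = np.sort(order[:m])
    positions = np.unique(_coef_to_sample(keep, decomp.signal_length,
                                          decomp.mode))
    return PeakSet(positions=positions, coefficient_indices=keep,
                   retained_coefficients=swc[keep], e_tot=e_tot,
                   e_th=float(cum[m - 1]), threshold=threshold)
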