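"""Fusion of the d+1 Kalman-predicted signals into one final prediction.

Two strategies are provided.  Correlation-patch fusion (MLK-R) tiles the
record into windows of w samples, computes all pairwise Pearson
correlations between the candidate signals on each tile, and copies the
patch from the most mutually consistent pair — correlation above a
threshold (default R > 0.90) and minimal absolute difference — falling
back to the per-sample mean across signals where no pair qualifies.
PCA + mutual-information fusion (MLK-MI) projects the candidate signals
onto principal components, ranks component pairs by the mutual
information of their score vectors, keeps the first two distinct
components so ranked, reconstructs the signals from those components
only, and averages the reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil, sqrt

import numpy as np

__all__ = [
    "PatchConfig",
    "FusedSignal",
    "PCASpace",
    "pearson_r",
    "mlk_r_fuse",
    "pca_fit",
    "mutual_information",
    "mutual_information_from_pmf",
    "mlk_mi_fuse",
]


@dataclass(frozen=True)
class PatchConfig:
    """Sliding-window settings for correlation-patch fusion."""

    window_w: int = 4
    r_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.window_w < 2:
            raise ValueError("window_w must be >= 2")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")


@dataclass
class FusedSignal:
    """Final fused prediction with per-sample provenance tags."""

    values: np.ndarray
    provenance: np.ndarray  # 'patch-copied' / 'mean-fallback' / 'pca-mi'


@dataclass
class PCASpace:
    """Principal-component decomposition of the stacked signals."""

    scores: np.ndarray   # A, N x m
    weights: np.ndarray  # B, m x m orthonormal columns
    means: np.ndarray    # column means removed before projection
    variances: np.ndarray  # per-component score variances, descending


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation; NaN when either patch is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("patches must have equal length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = sqrt(float(ac @ ac) * float(bc @ bc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def _stack(signals) -> np.ndarray:
    X = np.column_stack([np.asarray(s, dtype=float).ravel() for s in signals])
    if X.shape[1] < 2:
        raise ValueError("need at least 2 signals")
    return X


def mlk_r_fuse(signals, cfg: PatchConfig = PatchConfig()) -> FusedSignal:
    """Correlation-coefficient patch fusion of the candidate signals.

    Non-overlapping tiles of ``cfg.window_w`` samples; on each full tile
    the pair (p, q) with Pearson R above the threshold and smallest
    summed absolute difference wins and signal p's patch is copied (ties
    broken by the lexicographically smallest pair).  Tiles with no
    qualifying pair — and the final partial tile — use the per-sample
    mean of all signals.
    """
    X = _stack(signals)
    N, m = X.shape
    w = cfg.window_w
    fused = np.empty(N)
    prov = np.empty(N, dtype=object)
    mean_all = X.mean(axis=1)
    for start in range(0, N, w):
        stop = start + w
        if stop > N:  # partial tail tile
            fused[start:N] = mean_all[start:N]
            prov[start:N] = "mean-fallback"
            break
        best = None  # (diff, p, q)
        for p, q in combinations(range(m), 2):
            r = pearson_r(X[start:stop, p], X[start:stop, q])
            if np.isnan(r) or r <= cfg.r_threshold:
                continue
            diff = float(np.abs(X[start:stop, p] - X[start:stop, q]).sum())
            if best is None or (diff, p, q) < best:
                best = (diff, p, q)
        if best is None:
            fused[start:stop] = mean_all[start:stop]
            prov[start:stop] = "mean-fallback"
        else:
            fused[start:stop] = X[start:stop, best[1]]
            prov[start:stop] = "patch-copied"
    return FusedSignal(values=fused, provenance=prov)


def pca_fit(signals) -> PCASpace:
    """PCA of the signals-as-columns matrix, components by falling variance.

    Column means are removed; the weight matrix B has orthonormal columns
    (eigenvectors of the column covariance) with a deterministic sign
    convention, and scores A = centered data @ B.
    """
    X = _stack(signals)
    N, m = X.shape
    if N <= m:
        raise ValueError("need more time points than signals")
    means = X.mean(axis=0)
    Xc = X - means
    if not np.any(Xc):
        warnings.warn("zero-variance input to PCA; components are degenerate")
    # SVD is the numerically stable eigendecomposition of the covariance
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=True)
    B = Vt.T
    # fix signs so the largest-magnitude loading of each component is positive
    for j in range(m):
        lead = np.argmax(np.abs(B[:, j]))
        if B[lead, j] < 0:
            B[:, j] = -B[:, j]
    A = Xc @ B
    variances = np.zeros(m)
    variances[: len(svals)] = svals**2 / N
    return PCASpace(scores=A, weights=B, means=means, variances=variances)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information_from_pmf(joint: np.ndarray) -> float:
    """Mutual information (bits) of an exactly known joint pmf."""
    joint = np.asarray(joint, dtype=float)
    if joint.min() < 0 or not np.isclose(joint.sum(), 1.0):
        raise ValueError("joint must be a probability mass function")
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    return _entropy_bits(px) + _entropy_bits(py) - _entropy_bits(joint.ravel())


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Histogram estimate of I(X, Y) = H(X) + H(Y) - H(X, Y), in bits.

    Equal-width binning over each variable's range; ``bins`` applies to
    both axes.  I(x, x) reduces to the entropy of x's histogram.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if len(x) != len(y) or len(x) < bins:
        raise ValueError("x and y must have equal length >= bins")
    counts, _, _ = np.histogram2d(x, y, bins=bins)
    return mutual_information_from_pmf(counts / counts.sum())


def default_mi_bins(n: int) -> int:
    """Square-root rule for the histogram bin count."""
    return max(2, ceil(sqrt(n)))


def mlk_mi_fuse(signals, bins: int | None = None) -> FusedSignal:
    """PCA + mutual-information fusion of the candidate signals.

    Ranks all pairs of principal-component score vectors by mutual
    information, takes the first two distinct components in that ranking,
    reconstructs the signal matrix from those components alone and
    averages the reconstructed columns.  If every pairwise MI is
    (numerically) zero the two highest-variance components are used
    instead, with a warning.
    """
    X = _stack(signals)
    N, m = X.shape
    if m < 3:
        raise ValueError("need at least 3 signals so two distinct components exist")
    if bins is None:
        bins = default_mi_bins(N)
    space = pca_fit(signals)
    pairs = []
    for i, j in combinations(range(m), 2):
        mi = mutual_information(space.scores[:, i], space.scores[:, j], bins)
        pairs.append((mi, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    if all(p[0] <= 1e-12 for p in pairs):
        warnings.warn("all pairwise component MI ~ 0; "
                      "falling back to the two highest-variance components")
        selected = [0, 1]
    else:
        selected = []
        for _, i, j in pairs:
            for comp in (i, j):
                if comp not in selected:
                    selected.append(comp)
                if len(selected) == 2:
                    break
            if len(selected) == 2:
                break
    sel = np.array(selected[:2])
    recon = space.scores[:, sel] @ space.weights[:, sel].T + space.means
    fused = recon.mean(axis=1)
    return FusedSignal(values=fused,
                       provenance=np.full(N, "pca-mi", dtype=object))
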