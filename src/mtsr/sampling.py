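"""Non-uniform downsampling and the interlaced frame dictionary.

The observed microtubule record is assumed to be a non-uniformly
subsampled version of an underlying length-N signal.  Reconstruction
starts from piecewise-linear interpolation of the retained samples (the
NL-I baseline) and then builds a dictionary of d additional low-resolution
frames by interlaced decimation of the interpolated signal, each frame
shifted by a constant offset eps_i and wrapped modulo N:

    x_li(n) = { x(mod(k*d + eps_i, N)) : k = 0..s-1 },   eps_i = i + 1,

for i = 2..d+1, with s = floor(N/d) samples per frame and frame 1 being
the base low-resolution signal itself.  Every frame is re-interpolated to
full length, giving the d+1 observation series the Kalman stage fits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LowResFrame",
    "FrameDictionary",
    "nonuniform_downsample",
    "frame_size",
    "interlaced_frames",
    "piecewise_linear_interpolate",
    "build_frame_dictionary",
]


@dataclass
class LowResFrame:
    """A subsampled view of a length-N signal: sorted indices and values."""

    indices: np.ndarray      # 0-based positions into the length-N grid
    values: np.ndarray       # signal values at those positions
    source_length: int       # N
    shift: int | None = None  # eps_i for interlaced frames; None for the base

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.indices) != len(self.values):
            raise ValueError("indices and values must have equal length")
        if len(self.indices) and (self.indices.min() < 0
                                  or self.indices.max() >= self.source_length):
            raise ValueError("indices out of range [0, N-1]")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("indices must be strictly increasing")


@dataclass
class FrameDictionary:
    """The d+1 low-resolution frames and their interpolated versions."""

    frames: list[LowResFrame]
    interpolated: list[np.ndarray]
    d: int

    def __post_init__(self) -> None:
        if len(self.frames) != self.d + 1 or len(self.interpolated) != self.d + 1:
            raise ValueError("expected d+1 frames and interpolations")


def frame_size(N: int, d: int) -> int:
    """Samples per frame, s = floor(N/d)."""
    if d <= 0:
        raise ValueError("resolution factor d must be >= 1")
    if N <= 0:
        raise ValueError("N must be >= 1")
    return N // d


def nonuniform_downsample(x: np.ndarray, s: int, seed: int) -> LowResFrame:
    """Keep ``s`` samples of ``x`` at random positions, endpoints forced.

    Emulates non-uniform data loss: a seeded uniform random subset of s
    distinct indices, always including 0 and N-1 so the interpolation
    support spans the whole record.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)
    if not 2 <= s <= N:
        raise ValueError(f"need 2 <= s <= N, got s={s}, N={N}")
    rng = np.random.default_rng(seed)
    interior = rng.choice(np.arange(1, N - 1), size=s - 2, replace=False)
    idx = np.sort(np.concatenate(([0], interior, [N - 1]))).astype(int)
    return LowResFrame(indices=idx, values=x[idx], source_length=N)


def interlaced_frames(x_h: np.ndarray, d: int) -> list[LowResFrame]:
    """Frames 2..d+1 by shifted decimation (wrapping modulo N) of ``x_h``."""
    x_h = np.asarray(x_h, dtype=float)
    N = len(x_h)
    if d < 1:
        raise ValueError("d must be >= 1")
    s = frame_size(N, d)
    frames = []
    for i in range(2, d + 2):
        eps = i + 1
        raw = (np.arange(s) * d + eps) % N
        idx = np.sort(raw)
        frames.append(LowResFrame(indices=idx, values=x_h[idx],
                                  source_length=N, shift=eps))
    return frames


def piecewise_linear_interpolate(frame: LowResFrame) -> np.ndarray:
    """Interpolate a frame to full length N.

    Linear between consecutive known samples; flat (nearest-value)
    extrapolation outside the sampled support.
    """
    if len(frame.indices) < 2:
        raise ValueError("interpolation needs at least 2 samples")
    grid = np.arange(frame.source_length)
    return np.interp(grid, frame.indices, frame.values)


def build_frame_dictionary(base: LowResFrame, d: int) -> FrameDictionary:
    """Assemble the full dictionary from the base low-resolution frame.

    Interpolates the base frame to length N, derives the d interlaced
    frames from that interpolated signal and interpolates each of them.
    """
    x_h = piecewise_linear_interpolate(base)
    frames = [base] + interlaced_frames(x_h, d)
    interpolated = [x_h] + [piecewise_linear_interpolate(f) for f in frames[1:]]
    return FrameDictionary(frames=frames, interpolated=interpolated, d=d)


def write_frame_dictionary(fd: FrameDictionary, outdir: str | Path,
                           seed: int | None = None) -> None:
    """Serialize frames as per-frame CSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    N = fd.frames[0].source_length
    for k, frame in enumerate(fd.frames, start=1):
        pd.DataFrame({"index": frame.indices, "length_um": frame.values}
                     ).to_csv(outdir / f"frame_{k}.csv", index=False)
    manifest = {"N": N, "d": fd.d, "s": frame_size(N, fd.d),
                "eps": [f.shift for f in fd.frames], "seed": seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
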