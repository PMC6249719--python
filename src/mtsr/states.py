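"""Three-state encoding of a reconstructed signal and parameter estimation.

The detected transition points split the record into segments.  Each
segment gets a least-squares slope and a net length change and is
labelled growth, pause or shrinkage by the experimental thresholds used
for the original recordings: growth requires an increase of at least
0.2 um at a rate of at least 0.15 um/min, shrinkage a decrease of at
least 0.2 um at a rate of at least 0.3 um/min, anything else is an
attenuation (pause) phase.  From the labelled record the six transition
rates are estimated as exit counts over time spent in the source state
(the continuous-time Markov-chain maximum-likelihood estimator), the
speeds as duration-weighted mean segment slopes, and the average length
as the signal mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Optional

import numpy as np
import pandas as pd

from .tmn import STATES
from .wavelets import PeakSet

__all__ = [
    "ClassificationThresholds",
    "Segment",
    "EncodedStates",
    "EstimatedParams",
    "encode_states",
    "encoded_from_labels",
    "transition_counts",
    "estimate_transition_rates",
    "estimate_velocities",
    "average_length",
    "estimate_params",
]


@dataclass(frozen=True)
class ClassificationThresholds:
    """Phase-classification thresholds (experimental conventions)."""

    min_delta: float = 0.2          # um net change required for g or s
    min_growth_rate: float = 0.15   # um/min
    min_shrink_rate: float = 0.3    # um/min
    attenuation_span: int = 6       # samples defining an attenuation window

    def __post_init__(self) -> None:
        if min(self.min_delta, self.min_growth_rate, self.min_shrink_rate) <= 0 \
                or self.attenuation_span <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class Segment:
    start: int           # first sample of the segment
    end: int             # last sample owned by the segment (inclusive)
    slope: float         # um/min, least-squares over start..boundary
    delta: float         # um net change over the segment span
    label: str           # g / p / s

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1


@dataclass
class EncodedStates:
    """Per-sample phase labels and the segment list that produced them."""

    labels: np.ndarray
    segments: list[Segment]
    dt: float  # seconds


def _ls_slope(y: np.ndarray, dt_min: float) -> float:
    """Least-squares slope in um/min of samples spaced dt_min minutes."""
    n = len(y)
    if n < 2:
        return 0.0
    t = np.arange(n) * dt_min
    t = t - t.mean()
    return float((t @ (y - y.mean())) / (t @ t))


def _classify(delta: float, slope: float, thr: ClassificationThresholds) -> str:
    if delta >= thr.min_delta and slope >= thr.min_growth_rate:
        return "g"
    if delta <= -thr.min_delta and slope <= -thr.min_shrink_rate:
        return "s"
    return "p"


def encode_states(x: np.ndarray, peaks: PeakSet | np.ndarray, dt: float,
                  thr: ClassificationThresholds = ClassificationThresholds(),
                  ) -> EncodedStates:
    """Split ``x`` at the detected peaks and label each segment g/p/s.

    Segment boundaries are the peak positions plus both record endpoints.
    Slopes and net changes are measured on the boundary-inclusive span
    (consecutive segments share the boundary sample, so even one-sample
    segments have a defined slope), while the per-sample labels partition
    the record: each segment owns samples from its start up to, but not
    including, the next boundary.  An empty peak set yields a single
    segment classified on its own slope.
    """
    x = np.asarray(x, dtype=float).ravel()
    if dt <= 0:
        raise ValueError("dt must be positive")
    N = len(x)
    positions = peaks.positions if isinstance(peaks, PeakSet) else np.asarray(peaks)
    bounds = np.unique(np.concatenate(([0], positions, [N - 1]))).astype(int)
    bounds = bounds[(bounds >= 0) & (bounds <= N - 1)]
    dt_min = dt / 60.0

    segments: list[Segment] = []
    labels = np.empty(N, dtype="<U1")
    for j in range(len(bounds) - 1):
        a, b = bounds[j], bounds[j + 1]
        span = x[a:b + 1]
        slope = _ls_slope(span, dt_min)
        delta = float(span[-1] - span[0])
        label = _classify(delta, slope, thr)
        own_end = b - 1 if j < len(bounds) - 2 else N - 1
        segments.append(Segment(start=a, end=own_end, slope=slope,
                                delta=delta, label=label))
        labels[a:own_end + 1] = label
    if len(bounds) == 1:  # degenerate single-point record
        slope = _ls_slope(x, dt_min)
        segments = [Segment(0, N - 1, slope, float(x[-1] - x[0]),
                            _classify(float(x[-1] - x[0]), slope, thr))]
        labels[:] = segments[0].label
    return EncodedStates(labels=labels, segments=segments, dt=dt)


def encoded_from_labels(labels, dt: float) -> EncodedStates:
    """Build an EncodedStates from a per-sample label sequence.

    Convenience constructor for rate estimation on known (for instance
    simulated ground-truth) state sequences; segment slopes and deltas
    are not available and are recorded as zero.
    """
    labels = np.asarray(labels, dtype="<U1")
    if labels.size == 0:
        raise ValueError("empty label sequence")
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(Segment(start, i - 1, 0.0, 0.0, str(labels[start])))
            start = i
    return EncodedStates(labels=labels, segments=segments, dt=dt)


def _merged_runs(segments: list[Segment]) -> list[Segment]:
    """Merge consecutive same-label segments into maximal runs."""
    runs: list[Segment] = []
    for seg in segments:
        if runs and runs[-1].label == seg.label:
            prev = runs[-1]
            total = prev.n_samples + seg.n_samples
            slope = (prev.slope * prev.n_samples
                     + seg.slope * seg.n_samples) / total
            runs[-1] = Segment(prev.start, seg.end, slope,
                               prev.delta + seg.delta, prev.label)
        else:
            runs.append(Segment(seg.start, seg.end, seg.slope,
                                seg.delta, seg.label))
    return runs


def transition_counts(states: EncodedStates, dt: float | None = None,
                      ) -> tuple[dict[tuple[str, str], int], dict[str, float]]:
    """Raw i->j transition counts and minutes of exposure per state.

    Useful for pooling rate estimates across replicate records: sum the
    counts and exposures, then divide.
    """
    dt = states.dt if dt is None else dt
    runs = _merged_runs(states.segments)
    dt_min = dt / 60.0
    time_in = {s: 0.0 for s in STATES}
    counts = {(i, j): 0 for i in STATES for j in STATES if i != j}
    for k, run in enumerate(runs):
        time_in[run.label] += run.n_samples * dt_min
        if k + 1 < len(runs):
            counts[(run.label, runs[k + 1].label)] += 1
    return counts, time_in


def estimate_transition_rates(states: EncodedStates, dt: float | None = None,
                              ) -> dict[str, float]:
    """Count-over-exposure estimates of the six transition rates, min^-1.

    f_ij = (number of i -> j run boundaries) / (total minutes spent in i).
    Raises if a state has observed exits but zero recorded exposure.
    """
    counts, time_in = transition_counts(states, dt)
    rates: dict[str, float] = {}
    for (i, j), c in counts.items():
        if time_in[i] == 0.0:
            if c:
                raise ValueError(f"observed {i}->{j} exits with zero time in {i}")
            rates[f"f_{i}{j}"] = 0.0
        else:
            rates[f"f_{i}{j}"] = c / time_in[i]
    return rates


def estimate_velocities(x: np.ndarray, states: EncodedStates,
                        dt: float | None = None,
                        ) -> tuple[Optional[float], Optional[float]]:
    """Duration-weighted mean segment slopes: (v_g, v_s), um/min.

    v_s is returned as a positive speed.  A missing phase gives None for
    that speed rather than zero.
    """
    del x, dt  # slopes were fitted during encoding
    v: dict[str, Optional[float]] = {}
    for label in ("g", "s"):
        segs = [s for s in states.segments if s.label == label]
        if not segs:
            v[label] = None
            continue
        wts = np.array([s.n_samples for s in segs], dtype=float)
        slopes = np.array([s.slope for s in segs])
        v[label] = float((wts * slopes).sum() / wts.sum())
    v_g = v["g"]
    v_s = None if v["s"] is None else abs(v["s"])
    return v_g, v_s


def average_length(x: np.ndarray) -> float:
    """Arithmetic mean of the signal, um."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty signal")
    return float(x.mean())


@dataclass
class EstimatedParams:
    """The eight dynamic-instability parameters plus the mean length."""

    f_gp: float
    f_gs: float
    f_pg: float
    f_ps: float
    f_sg: float
    f_sp: float
    v_g: Optional[float]
    v_s: Optional[float]
    avgL: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        """One-row table in the conventional column order."""
        cols = ["f_sg", "f_gs", "f_sp", "f_ps", "f_gp", "f_pg",
                "v_s", "v_g", "avgL"]
        d = self.to_dict()
        return pd.DataFrame([{c: d[c] for c in cols}])


def estimate_params(x: np.ndarray, peaks: PeakSet | np.ndarray, dt: float,
                    thr: ClassificationThresholds = ClassificationThresholds(),
                    ) -> tuple[EstimatedParams, EncodedStates]:
    """Full estimation: encode, then rates, speeds and mean length."""
    enc = encode_states(x, peaks, dt, thr)
    rates = estimate_transition_rates(enc)
    v_g, v_s = estimate_velocities(x, enc)
    params = EstimatedParams(**rates, v_g=v_g, v_s=v_s,
                             avgL=average_length(x))
    return params, enc
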