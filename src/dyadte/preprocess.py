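"""Turn raw trial recordings into estimator-ready embedded series.

Transfer entropy conditions the target's next sample on finite histories
of both signals.  This module builds those delay vectors: for history
lengths ``m`` (source) and ``n`` (target) with tap spacing ``delay``,
the row for time ``t`` holds

    (y_{t+1},  y_t, y_{t-delay}, ..., y_{t-(n-1)delay},
               x_t, x_{t-delay}, ..., x_{t-(m-1)delay}),

so the future is exactly one sample ahead of the most recent tap.  Rows
exist only for ``t`` with complete histories and an available future
sample, hence the usable row count is

    rows = N - 1 - (max(m, n) - 1) * delay.

It also applies the initialization discard (the study drops the first
500 samples, 8.3 s at 60 Hz, of every 1-min trial) and resolves physical
gyro channels to persons using the seat metadata.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .trial import DyadTrial

__all__ = [
    "EstimatorConfig",
    "EmbeddedSeries",
    "discard_initialization",
    "embed",
    "resolve_channels",
    "n_embedded_rows",
]

#: initialization discard used throughout the study (samples at 60 Hz)
DEFAULT_DISCARD = 500


@dataclass(frozen=True)
class EstimatorConfig:
    """Free parameters of the transfer-entropy estimator.

    m, n : source / target history lengths (Markov orders).
    delay : samples between history taps.
    k : neighbour count for the Kraskov-style estimator.
    units : "bits" or "nats".
    discard_samples : initialization samples dropped from each trial.
    seed : seed for the estimator's tie-breaking noise.
    """

    m: int = 1
    n: int = 1
    delay: int = 1
    k: int = 4
    units: str = "bits"
    discard_samples: int = DEFAULT_DISCARD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.k < 1 or self.delay < 1:
            raise ValueError("m, n, k and delay must all be >= 1")
        if self.units not in ("bits", "nats"):
            raise ValueError("units must be 'bits' or 'nats'")
        if self.discard_samples < 0:
            raise ValueError("discard_samples must be >= 0")


@dataclass
class EmbeddedSeries:
    """Aligned delay vectors (source past, target past, target future).

    The raw series and the embedding orders are retained so estimators
    can apply consistent per-series transformations (the k-NN estimator
    rebuilds its tie-jitter at the series level, which keeps lagged or
    duplicated columns coherent).
    """

    source_past: np.ndarray  # (rows, m)
    target_past: np.ndarray  # (rows, n)
    target_future: np.ndarray  # (rows,)
    t_index: np.ndarray  # time index t of each row (0-based)
    source_series: np.ndarray | None = None
    target_series: np.ndarray | None = None
    delay: int = 1

    def __post_init__(self) -> None:
        r = len(self.target_future)
        if not (self.source_past.shape[0] == self.target_past.shape[0] == r == len(self.t_index)):
            raise ValueError("embedded blocks must have equal row counts")

    @property
    def n_rows(self) -> int:
        return len(self.target_future)


def n_embedded_rows(n_samples: int, m: int, n: int, delay: int = 1) -> int:
    """Usable rows for an ``n_samples``-long pair of series."""
    return n_samples - 1 - (max(m, n) - 1) * delay


def discard_initialization(trial: DyadTrial, discard_samples: int = DEFAULT_DISCARD) -> DyadTrial:
    """Drop the first ``discard_samples`` samples from every channel.

    The study discards the initial 8.3 s (500 samples at 60 Hz) of each
    trial for initialization reasons; a 3,600-sample trial then retains
    3,100 samples.  Absolute time stamps are preserved so that
    time-dependent targets (the rotating ellipse) stay aligned.
    """
    if discard_samples < 0:
        raise ValueError("discard_samples must be >= 0")
    if discard_samples >= trial.n_samples:
        raise ValueError(
            f"discarding {discard_samples} samples would empty a "
            f"{trial.n_samples}-sample trial"
        )
    if discard_samples == 0:
        return trial
    out = copy.copy(trial)
    out.gyro = trial.gyro[:, discard_samples:]
    out.ball_path = trial.ball_path[discard_samples:]
    out.time = trial.time[discard_samples:]
    out.meta = dict(trial.meta, discarded_samples=trial.meta.get("discarded_samples", 0) + discard_samples)
    return out


def embed(source, target, config: EstimatorConfig) -> EmbeddedSeries:
    """Build aligned delay vectors for one directed source -> target pair.

    Pure function of its inputs.  Raises on length mismatch, non-finite
    samples, or series too short to yield at least one row.
    """
    x = np.asarray(source, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("source and target must be one-dimensional")
    if len(x) != len(y):
        raise ValueError(f"length mismatch: source {len(x)} vs target {len(y)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite samples are not accepted")
    m, n, d = config.m, config.n, config.delay
    rows = n_embedded_rows(len(x), m, n, d)
    if rows < 1:
        raise ValueError(
            f"series of length {len(x)} too short for m={m}, n={n}, delay={d}"
        )
    t0 = (max(m, n) - 1) * d
    t = np.arange(t0, len(x) - 1)
    # column j of a past block is the value at t - j*delay (most recent first)
    src_cols = [x[t - j * d] for j in range(m)]
    tgt_cols = [y[t - j * d] for j in range(n)]
    return EmbeddedSeries(
        source_past=np.column_stack(src_cols),
        target_past=np.column_stack(tgt_cols),
        target_future=y[t + 1],
        t_index=t,
        source_series=x,
        target_series=y,
        delay=d,
    )


def resolve_channels(trial: DyadTrial) -> tuple[np.ndarray, np.ndarray]:
    """Map physical gyro channels to persons using the seat assignment.

    Channel 0 (transversal axis) is controlled from seat A, channel 1
    (longitudinal) from seat B.  Returns ``(person_A, person_B)`` series
    so all downstream quantities can be person-indexed across seat
    exchanges.  The seat-indexed view is simply ``trial.gyro`` itself.
    """
    seat = trial.seat_of_player_A
    if seat not in ("A", "B"):
        raise ValueError("trial is missing a valid seat_of_player_A")
    if seat == "A":
        return trial.gyro[0], trial.gyro[1]
    return trial.gyro[1], trial.gyro[0]
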