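"""Core data container for one dyadic trial, plus its on-disk CSV dialect.

A trial is one minute of joint play: two players each tilt one axis of a
tablet with rhythmic finger movements, and the combined tilt drives a
spring-anchored virtual ball that should ride a target line (a circle or a
slowly rotating ellipse).  The recording holds the two gyroscope channels
(angular velocity of the transversal and longitudinal tablet axes, one per
seat) sampled at 60 Hz together with the ball's screen path in centimetres.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TargetShape",
    "DyadTrial",
    "write_trial_csv",
    "read_trial_csv",
    "write_manifest",
    "read_manifest",
]

#: CSV columns required by the trial dialect, in canonical order.
TRIAL_CSV_COLUMNS = ["time_s", "gyro_a_rad_s", "gyro_b_rad_s", "ball_x_cm", "ball_y_cm"]


@dataclass(frozen=True)
class TargetShape:
    """Target line geometry on the tablet screen.

    Parameters
    ----------
    kind : {"circle", "ellipse"}
    radius : float, optional
        Circle radius in cm.  The study's circle has diameter 8.95 cm,
        i.e. radius 4.475 cm.
    semi_axes : tuple of float, optional
        Ellipse semi-axes (a, b) in cm.  The study's ellipse has axes
        lengths 10.94 and 8.47 cm, i.e. semi-axes 5.47 and 4.235 cm.
    rotation_rate : float
        Revolutions per minute of the ellipse (0 for the circle).  The
        study's ellipse rotates at 2.5 rev/min.
    line_width : float
        Width of the drawn target line in cm (0.29 cm in the study).
    """

    kind: str
    radius: float | None = None
    semi_axes: tuple[float, float] | None = None
    rotation_rate: float = 0.0
    line_width: float = 0.29

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "ellipse"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "circle":
            if self.radius is None or self.radius <= 0:
                raise ValueError("circle target needs a positive radius")
        else:
            if self.semi_axes is None or min(self.semi_axes) <= 0:
                raise ValueError("ellipse target needs positive semi-axes")

    @property
    def mean_radius(self) -> float:
        """Mean radius used to normalise tracking errors (cm)."""
        if self.kind == "circle":
            return float(self.radius)
        return float(0.5 * (self.semi_axes[0] + self.semi_axes[1]))

    @classmethod
    def study_circle(cls) -> "TargetShape":
        """The circular target of the first experiment (diameter 8.95 cm)."""
        return cls(kind="circle", radius=4.475)

    @classmethod
    def study_ellipse(cls) -> "TargetShape":
        """The rotating elliptic target of the second experiment."""
        return cls(kind="ellipse", semi_axes=(5.47, 4.235), rotation_rate=2.5)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.semi_axes is not None:
            d["semi_axes"] = list(self.semi_axes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TargetShape":
        d = dict(d)
        if d.get("semi_axes") is not None:
            d["semi_axes"] = tuple(d["semi_axes"])
        return cls(**d)


@dataclass
class DyadTrial:
    """One 1-min two-channel control recording with ball path and metadata.

    ``gyro`` holds the two angular-velocity channels in physical channel
    order: row 0 is the transversal axis (controlled from seat A), row 1
    the longitudinal axis (controlled from seat B).  ``seat_of_player_A``
    records which seat person A occupied, so analyses can be person-indexed
    regardless of seat exchanges.
    """

    pair_id: str
    trial_index: int  # 1-based
    seat_of_player_A: str  # "A" or "B"
    condition: str
    sample_rate: float
    gyro: np.ndarray  # shape (2, n_samples), rad/s
    ball_path: np.ndarray  # shape (n_samples, 2), cm
    target: TargetShape
    time: np.ndarray | None = None  # absolute time in s; kept through discards
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.ball_path = np.asarray(self.ball_path, dtype=float)
        if self.gyro.ndim != 2 or self.gyro.shape[0] != 2:
            raise ValueError("gyro must have shape (2, n_samples)")
        if self.ball_path.shape != (self.gyro.shape[1], 2):
            raise ValueError("ball_path length must match gyro channels")
        if self.seat_of_player_A not in ("A", "B"):
            raise ValueError("seat_of_player_A must be 'A' or 'B'")
        if self.time is None:
            self.time = np.arange(self.gyro.shape[1]) / self.sample_rate
        else:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != (self.gyro.shape[1],):
                raise ValueError("time length must match gyro channels")

    @property
    def n_samples(self) -> int:
        return self.gyro.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def write_trial_csv(trial: DyadTrial, path: str | pathlib.Path) -> None:
    """Write one trial in the five-column CSV dialect (header, '.' decimal)."""
    df = pd.DataFrame(
        {
            "time_s": trial.time,
            "gyro_a_rad_s": trial.gyro[0],
            "gyro_b_rad_s": trial.gyro[1],
            "ball_x_cm": trial.ball_path[:, 0],
            "ball_y_cm": trial.ball_path[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_trial_csv(
    path: str | pathlib.Path,
    *,
    pair_id: str = "?",
    trial_index: int = 1,
    seat_of_player_A: str = "A",
    condition: str = "none",
    sample_rate: float = 60.0,
    target: TargetShape | None = None,
) -> DyadTrial:
    """Read a trial CSV; extra columns are tolerated, the five named ones required."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path} is missing columns {missing}")
    if target is None:
        target = TargetShape.study_circle()
    return DyadTrial(
        pair_id=pair_id,
        trial_index=trial_index,
        seat_of_player_A=seat_of_player_A,
        condition=condition,
        sample_rate=sample_rate,
        gyro=np.vstack([df["gyro_a_rad_s"].to_numpy(), df["gyro_b_rad_s"].to_numpy()]),
        ball_path=np.column_stack([df["ball_x_cm"].to_numpy(), df["ball_y_cm"].to_numpy()]),
        target=target,
        time=df["time_s"].to_numpy(),
    )


def write_manifest(manifest: dict, path: str | pathlib.Path) -> None:
    """Write the dataset manifest (pairs, trials, seats, seeds, couplings) as JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)


def read_manifest(path: str | pathlib.Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
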