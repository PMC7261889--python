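"""Synthetic dyad generator for the tablet tetherball paradigm.

Two players produce rhythmic finger movements modelled as Kuramoto-type
phase oscillators with directional coupling:

    dphi_i/dt = omega_i + K_i * sin(phi_j - phi_i - Delta_i) + noise,

integrated with the Euler-Maruyama scheme at a fixed step of one sample
(1/60 s at the default rate).  ``K_i`` (``coupling_in``) is the strength
with which player ``i`` adjusts to the partner; a leader-follower dyad is
encoded purely as coupling asymmetry (the follower has the larger
``coupling_in``; equal coupling means "no leader").  The phase-lag offsets
``Delta_i`` are chosen so that the phase-locked state realises the task's
optimal 90-degree lag between the two axes.

Each player's tilt angle is ``theta_i = amplitude * sin(phi_i)``; the
emitted gyroscope channel is the realised tilt velocity ``theta_dot``
plus optional white measurement noise.  The virtual ball is a damped
spring to the screen centre driven by the two tilt angles:

    r_ddot = -spring_constant * r - damping * r_dot
             + tilt_gain * (theta_transversal, theta_longitudinal),

integrated with the semi-implicit (symplectic) Euler scheme at the same
step.  Default ball constants are chosen so a 0.1 rad tilt amplitude at
1 Hz settles on a limit cycle of roughly the circular target's radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trial import DyadTrial, TargetShape

__all__ = [
    "PlayerParams",
    "BallParams",
    "ExperimentSchedule",
    "IntegrationDivergedError",
    "simulate_trial",
    "simulate_experiment",
    "default_dyad_params",
    "linear_ramp",
]

#: default white measurement noise on the emitted gyroscope signal (rad/s)
DEFAULT_GYRO_NOISE_SD = 0.01


class IntegrationDivergedError(RuntimeError):
    """Raised when the trial integration produces non-finite state."""


@dataclass(frozen=True)
class PlayerParams:
    """One player's oscillator parameters.

    natural_frequency : rad/s — intrinsic finger-movement rate (default 1 Hz).
    amplitude : rad — peak tilt angle imparted to the tablet axis.
    coupling_in : 1/s — strength with which this player adjusts to the partner.
    phase_noise_sd : rad/sqrt(s) — intensity of the phase diffusion.
    initial_phase : rad.
    """

    natural_frequency: float = 2.0 * math.pi
    amplitude: float = 0.1
    coupling_in: float = 2.0
    phase_noise_sd: float = 0.15
    initial_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.coupling_in < 0:
            raise ValueError("coupling_in must be >= 0")
        if self.phase_noise_sd < 0:
            raise ValueError("phase_noise_sd must be >= 0")


@dataclass(frozen=True)
class BallParams:
    """Spring-anchored ball dynamics.

    spring_constant : 1/s^2 — restoring acceleration per cm of displacement.
    damping : 1/s.
    tilt_gain : cm/s^2 per rad — acceleration imparted per radian of tilt.
    """

    spring_constant: float = 9.0
    damping: float = 4.0
    tilt_gain: float = 1767.8
    initial_position: tuple[float, float] = (0.0, 0.0)
    initial_velocity: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.damping < 0:
            raise ValueError("damping must be >= 0")


def linear_ramp(start: float = 0.4, end: float = 1.0) -> Callable[[int], float]:
    """Monotone coupling multiplier emulating learning across trials.

    Returns a map ``(trial_index, n_trials) -> multiplier`` rising linearly
    from ``start`` at trial 1 to ``end`` at the final trial.
    """

    def ramp(trial_index: int, n_trials: int) -> float:
        if n_trials <= 1:
            return end
        frac = (trial_index - 1) / (n_trials - 1)
        return start + (end - start) * frac

    return ramp


@dataclass(frozen=True)
class ExperimentSchedule:
    """Trial/seat schedule of one experiment design.

    Design A: 15 trials, no seat exchange.  Design B: 30 trials, the
    players exchange seats after every five trials.
    """

    n_pairs: int
    trials_per_pair: int = 15
    seat_exchange_every: int | None = None
    learning_ramp: Callable[[int, int], float] | None = field(default=None)
    seed: int = 0
    condition: str = "none"

    @classmethod
    def design_A(cls, n_pairs: int, seed: int = 0, condition: str = "none") -> "ExperimentSchedule":
        return cls(n_pairs=n_pairs, trials_per_pair=15, seat_exchange_every=None,
                   learning_ramp=linear_ramp(), seed=seed, condition=condition)

    @classmethod
    def design_B(cls, n_pairs: int, seed: int = 0, condition: str = "none") -> "ExperimentSchedule":
        return cls(n_pairs=n_pairs, trials_per_pair=30, seat_exchange_every=5,
                   learning_ramp=linear_ramp(), seed=seed, condition=condition)

    def seat_of_player_A(self, trial_index: int) -> str:
        """Seat occupied by person A in the given 1-based trial."""
        if not self.seat_exchange_every:
            return "A"
        block = (trial_index - 1) // self.seat_exchange_every
        return "A" if block % 2 == 0 else "B"


def _integrate_dyad(
    p1: PlayerParams,
    p2: PlayerParams,
    ball: BallParams,
    duration: float,
    sample_rate: float,
    delta1: float,
    delta2: float,
    rng: np.random.Generator,
    gyro_noise_sd: float,
):
    """Integrate the coupled phase/ball system; returns (gyro1, gyro2, path).

    ``delta_i`` is player i's phase-lag offset toward the partner.  Player 1
    drives the ball's x (transversal) axis, player 2 the y (longitudinal)
    axis.  Euler-Maruyama for the phases, semi-implicit Euler for the ball.
    """
    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate))
    sqrt_dt = math.sqrt(dt)

    phi1, phi2 = p1.initial_phase, p2.initial_phase
    rx, ry = ball.initial_position
    vx, vy = ball.initial_velocity

    noise1 = rng.normal(0.0, p1.phase_noise_sd * sqrt_dt, size=n)
    noise2 = rng.normal(0.0, p2.phase_noise_sd * sqrt_dt, size=n)

    gyro1 = np.empty(n)
    gyro2 = np.empty(n)
    path = np.empty((n, 2))
    phases = np.empty((n, 2))

    for i in range(n):
        drift1 = p1.natural_frequency + p1.coupling_in * math.sin(phi2 - phi1 - delta1)
        drift2 = p2.natural_frequency + p2.coupling_in * math.sin(phi1 - phi2 - delta2)
        dphi1 = drift1 * dt + noise1[i]
        dphi2 = drift2 * dt + noise2[i]

        # tilt velocity by the chain rule with the drift phase rate: the
        # phase diffusion perturbs the movement itself (process noise) and
        # is not re-injected into the observation at 1/dt scale, matching a
        # gyroscope reading of smooth finger movement
        gyro1[i] = p1.amplitude * math.cos(phi1) * drift1
        gyro2[i] = p2.amplitude * math.cos(phi2) * drift2

        theta1 = p1.amplitude * math.sin(phi1)
        theta2 = p2.amplitude * math.sin(phi2)
        ax = -ball.spring_constant * rx - ball.damping * vx + ball.tilt_gain * theta1
        ay = -ball.spring_constant * ry - ball.damping * vy + ball.tilt_gain * theta2
        vx += ax * dt
        vy += ay * dt
        rx += vx * dt
        ry += vy * dt
        path[i, 0] = rx
        path[i, 1] = ry
        phases[i, 0] = phi1
        phases[i, 1] = phi2

        phi1 += dphi1
        phi2 += dphi2

        if not (math.isfinite(phi1) and math.isfinite(phi2) and math.isfinite(rx) and math.isfinite(ry)):
            raise IntegrationDivergedError(
                f"integration diverged at step {i} with players {p1}, {p2}, ball {ball}"
            )

    if gyro_noise_sd > 0:
        gyro1 = gyro1 + rng.normal(0.0, gyro_noise_sd, size=n)
        gyro2 = gyro2 + rng.normal(0.0, gyro_noise_sd, size=n)
    return gyro1, gyro2, path, phases


def simulate_trial(
    leader: PlayerParams,
    follower: PlayerParams,
    ball: BallParams | None = None,
    target: TargetShape | None = None,
    duration: float = 60.0,
    sample_rate: float = 60.0,
    target_phase_lag: float = math.pi / 2,
    seed: int = 0,
    *,
    gyro_noise_sd: float = DEFAULT_GYRO_NOISE_SD,
    pair_id: str = "pair",
    trial_index: int = 1,
    seat_of_player_A: str = "A",
    condition: str = "none",
) -> DyadTrial:
    """Simulate one trial; the leader drives the transversal (x) axis.

    ``target_phase_lag`` is the locked phase difference (leader ahead of
    follower) required by the task geometry; the offsets ``Delta_i`` are
    set so the locked state of the coupled system sits at that lag.
    Deterministic given ``seed``.
    """
    if duration <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample_rate must be positive")
    if ball is None:
        ball = BallParams()
    if target is None:
        target = TargetShape.study_circle()
    rng = np.random.default_rng(seed)
    # follower pulls toward (phi_leader - lag); leader (if coupled) toward
    # (phi_follower + lag)
    gyro1, gyro2, path, phases = _integrate_dyad(
        leader, follower, ball, duration, sample_rate,
        delta1=-target_phase_lag, delta2=target_phase_lag,
        rng=rng, gyro_noise_sd=gyro_noise_sd,
    )
    return DyadTrial(
        pair_id=pair_id,
        trial_index=trial_index,
        seat_of_player_A=seat_of_player_A,
        condition=condition,
        sample_rate=sample_rate,
        gyro=np.vstack([gyro1, gyro2]),
        ball_path=path,
        target=target,
        meta={"seed": seed, "leader_channel": 0, "phases": phases},
    )


def default_dyad_params(
    n_pairs: int,
    seed: int = 0,
    *,
    leader_gain: float = 4.0,
    base_coupling: float = 2.0,
    phase_noise_sd: float = 0.15,
    detuning_sd: float = 0.15,
    symmetric: bool = False,
) -> list[tuple[PlayerParams, PlayerParams]]:
    """Draw per-pair player parameters for a default cohort.

    The follower receives ``coupling_in = base_coupling``; the leader
    ``base_coupling / leader_gain`` (4:1 asymmetry by default).  Which
    person leads alternates across pairs.  ``symmetric=True`` gives both
    players the same coupling (no-leader ground truth).  Natural
    frequencies are jittered around 1 Hz by ``detuning_sd`` (rad/s).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_pairs):
        omega = 2.0 * math.pi + rng.normal(0.0, detuning_sd, size=2)
        phases = rng.uniform(0.0, 2.0 * math.pi, size=2)
        if symmetric:
            k = (base_coupling, base_coupling)
        elif i % 2 == 0:
            # person A leads: B adjusts strongly, A weakly
            k = (base_coupling / leader_gain, base_coupling)
        else:
            k = (base_coupling, base_coupling / leader_gain)
        pa = PlayerParams(natural_frequency=omega[0], coupling_in=k[0],
                          phase_noise_sd=phase_noise_sd, initial_phase=phases[0])
        pb = PlayerParams(natural_frequency=omega[1], coupling_in=k[1],
                          phase_noise_sd=phase_noise_sd, initial_phase=phases[1])
        out.append((pa, pb))
    return out


def simulate_experiment(
    schedule: ExperimentSchedule,
    dyad_params: Sequence[tuple[PlayerParams, PlayerParams]] | None = None,
    ball: BallParams | None = None,
    target: TargetShape | None = None,
    *,
    duration: float = 60.0,
    sample_rate: float = 60.0,
    gyro_noise_sd: float = DEFAULT_GYRO_NOISE_SD,
) -> tuple[list[DyadTrial], pd.DataFrame]:
    """Simulate a whole cohort: one trial per pair x trial index.

    Person A's and person B's oscillators persist across the experiment;
    a seat exchange only re-routes which tablet axis each person drives
    (channel swap).  The learning ramp scales both players' coupling by
    ``learning_ramp(trial_index, trials_per_pair)``.

    Returns the trial list and a ground-truth role table with one row per
    pair stating which person has the larger outgoing coupling.
    """
    if dyad_params is None:
        dyad_params = default_dyad_params(schedule.n_pairs, seed=schedule.seed)
    if len(dyad_params) != schedule.n_pairs:
        raise ValueError(
            f"schedule has {schedule.n_pairs} pairs but {len(dyad_params)} parameter sets given"
        )
    if ball is None:
        ball = BallParams()
    if target is None:
        target = TargetShape.study_circle()
    ramp = schedule.learning_ramp or (lambda t, n: 1.0)

    trials: list[DyadTrial] = []
    truth_rows = []
    root = np.random.SeedSequence([int(schedule.seed) & 0x7FFFFFFF, schedule.n_pairs])
    pair_seeds = root.spawn(schedule.n_pairs)

    for p, (pa, pb) in enumerate(dyad_params):
        pair_id = f"pair{p + 1:02d}"
        # outgoing influence of a player = partner's coupling_in
        if pb.coupling_in > pa.coupling_in:
            leader = "A"
        elif pa.coupling_in > pb.coupling_in:
            leader = "B"
        else:
            leader = "none"
        truth_rows.append(
            {"pair_id": pair_id, "true_leader": leader,
             "coupling_in_A": pa.coupling_in, "coupling_in_B": pb.coupling_in}
        )
        trial_seeds = pair_seeds[p].spawn(schedule.trials_per_pair)
        for t in range(1, schedule.trials_per_pair + 1):
            mult = ramp(t, schedule.trials_per_pair)
            pa_t = replace(pa, coupling_in=pa.coupling_in * mult)
            pb_t = replace(pb, coupling_in=pb.coupling_in * mult)
            seat = schedule.seat_of_player_A(t)
            rng = np.random.default_rng(trial_seeds[t - 1])
            # transversal (channel 0) is driven from seat A; the 90-degree
            # lag belongs to the axes, so the offsets do not flip with seats
            first, second = (pa_t, pb_t) if seat == "A" else (pb_t, pa_t)
            g1, g2, path, _ = _integrate_dyad(
                first, second, ball, duration, sample_rate,
                delta1=-math.pi / 2, delta2=math.pi / 2,
                rng=rng, gyro_noise_sd=gyro_noise_sd,
            )
            trials.append(
                DyadTrial(
                    pair_id=pair_id,
                    trial_index=t,
                    seat_of_player_A=seat,
                    condition=schedule.condition,
                    sample_rate=sample_rate,
                    gyro=np.vstack([g1, g2]),
                    ball_path=path,
                    target=target,
                    meta={"coupling_multiplier": mult, "true_leader": leader},
                )
            )
    return trials, pd.DataFrame(truth_rows)
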