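"""Pseudo-random target trajectories for the tracking task.

A target path is the sum of a few sinusoids per axis, which gives a
smooth, low-pass, unpredictable curve.  The geometric path is then
re-parameterized in time so that the tangential speed follows the
two-thirds power law, ``v(t) = K * kappa(t) ** (-1/3)`` with ``kappa``
the path curvature, the speed profile characteristic of natural drawing
and pursuit movements.  ``K`` is fixed by the requested duration so that
the realized mean speed is ~4 cm/s.

Trajectories with sharp turns (curvature above :data:`CURVATURE_CAP_CM`),
extreme instantaneous speeds, or paths leaving the workspace are rejected
and regenerated from a perturbed seed, standing in for the editorial
selection applied to the behavioral stimulus set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .task import BEHAVIOR_HZ, BIN_MS, TaskConfig

log = logging.getLogger(__name__)

MEAN_SPEED_CM_S = 4.0
DURATION_RANGE_S = (3.0, 10.0)
N_SINES = 4
FREQ_RANGE_HZ = (0.05, 0.4)

#: trajectories whose (rescaled) peak curvature exceeds this are rejected
CURVATURE_CAP_CM = 2.0  # cm^-1
#: curvature floor regularizing the power law at inflection points
CURVATURE_FLOOR_CM = 0.05  # cm^-1
#: admissible instantaneous speed band (cm/s)
SPEED_RANGE_CM_S = (1.0, 8.0)
#: the target path must stay within this radius of the screen center (cm)
WORKSPACE_RADIUS_CM = 5.5

_DENSE_N = 4096


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for one target trajectory.

    ``sine_terms`` holds, per axis, the (amplitude cm, frequency Hz,
    phase rad) triples of the generating sinusoids *after* workspace
    rescaling.  ``speed_gain`` is the constant ``K`` of the two-thirds
    power law reparameterization.
    """

    id: int
    sine_terms: tuple[tuple[tuple[float, float, float], ...], ...]
    duration_s: float
    start_position: tuple[float, float]
    speed_gain: float


def _sines(u: np.ndarray, terms, duration_s: float):
    """Evaluate a sum of sinusoids and its first two derivatives in u∈[0,1]."""
    pos = np.zeros_like(u)
    d1 = np.zeros_like(u)
    d2 = np.zeros_like(u)
    for amp, freq, phase in terms:
        w = 2.0 * np.pi * freq * duration_s  # rad per unit u
        arg = w * u + phase
        pos += amp * np.sin(arg)
        d1 += amp * w * np.cos(arg)
        d2 += -amp * w * w * np.sin(arg)
    return pos, d1, d2


def two_thirds_reparameterize(
    x: np.ndarray,
    y: np.ndarray,
    dx: np.ndarray,
    dy: np.ndarray,
    ddx: np.ndarray,
    ddy: np.ndarray,
    duration_s: float,
):
    """Time-reparameterize a geometric path by the two-thirds power law.

    Given a densely sampled path and its parametric derivatives, returns
    ``(t_of_u, speed_of_u, kappa, K)`` where ``t_of_u`` maps the dense
    parameter grid to time such that the tangential speed is
    ``K * max(kappa, floor) ** (-1/3)`` and the total duration equals
    ``duration_s``.
    """
    du_speed = np.hypot(dx, dy)
    if np.any(du_speed <= 0.0):
        raise ValueError("degenerate geometry: stationary point on path")
    kappa = np.abs(dx * ddy - dy * ddx) / du_speed**3
    kappa_reg = np.maximum(kappa, CURVATURE_FLOOR_CM)
    shape = kappa_reg ** (1.0 / 3.0)
    # T = (1/K) * \int kappa^(1/3) ds  =>  K fixed by the duration
    u = np.linspace(0.0, 1.0, len(x))
    integrand = shape * du_speed
    cum = np.concatenate(
        ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(u)))
    )
    K = cum[-1] / duration_s
    t_of_u = cum / K
    speed = K / shape
    return t_of_u, speed, kappa, K


def _round_to_bin_s(duration_s: float) -> float:
    return max(BIN_MS, round(duration_s * 1000.0 / BIN_MS) * BIN_MS) / 1000.0


def generate_trajectory(
    seed: int,
    config: TaskConfig | None = None,
    max_attempts: int = 500,
) -> tuple[TrajectorySpec, np.ndarray]:
    """Generate one target trajectory sampled at 200 Hz.

    Returns ``(spec, path)`` with ``path`` of shape (n, 2) in cm,
    screen-centered.  The duration is drawn uniformly in [3, 10] s
    (rounded to the 20-ms bin grid) and the sinusoid amplitudes are
    rescaled so the realized mean tangential speed is ~4 cm/s.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, _DENSE_N)
    for attempt in range(max_attempts):
        duration = _round_to_bin_s(rng.uniform(*DURATION_RANGE_S))
        terms = []
        for _axis in range(2):
            amps = rng.uniform(0.5, 2.0, N_SINES)
            freqs = rng.uniform(*FREQ_RANGE_HZ, N_SINES)
            phases = rng.uniform(0.0, 2.0 * np.pi, N_SINES)
            terms.append(tuple(zip(amps, freqs, phases)))
        x, dx, ddx = _sines(u, terms[0], duration)
        y, dy, ddy = _sines(u, terms[1], duration)
        # center the raw path on the screen
        x = x - x.mean()
        y = y - y.mean()

        du_speed = np.hypot(dx, dy)
        if np.min(du_speed) <= 1e-9:
            log.info("degenerate geometry at seed %s, regenerating", seed)
            continue
        seg = 0.5 * (du_speed[1:] + du_speed[:-1]) * np.diff(u)
        arclength = float(seg.sum())
        if arclength < 1e-6:
            log.info("zero-length path at seed %s, regenerating", seed)
            continue
        # rescale so arclength = mean_speed * duration
        scale = MEAN_SPEED_CM_S * duration / arclength
        x, y, dx, dy, ddx, ddy = (a * scale for a in (x, y, dx, dy, ddx, ddy))

        if np.max(np.hypot(x, y)) > WORKSPACE_RADIUS_CM:
            continue
        t_of_u, speed, kappa, gain = two_thirds_reparameterize(
            x, y, dx, dy, ddx, ddy, duration
        )
        if np.max(kappa) > CURVATURE_CAP_CM:
            continue
        lo, hi = SPEED_RANGE_CM_S
        if speed.min() < lo or speed.max() > hi:
            continue

        n = int(round(duration * BEHAVIOR_HZ))
        t_grid = np.arange(n) / BEHAVIOR_HZ
        px = np.interp(t_grid, t_of_u, x)
        py = np.interp(t_grid, t_of_u, y)
        path = np.column_stack([px, py])

        realized = path_mean_speed(path)
        if abs(realized - MEAN_SPEED_CM_S) > 0.1 * MEAN_SPEED_CM_S:
            continue

        spec = TrajectorySpec(
            id=int(seed),
            sine_terms=tuple(
                tuple((a * scale, f, p) for a, f, p in axis) for axis in terms
            ),
            duration_s=duration,
            start_position=(float(px[0]), float(py[0])),
            speed_gain=float(gain),
        )
        return spec, path
    raise RuntimeError(
        f"could not generate an admissible trajectory from seed {seed} "
        f"in {max_attempts} attempts"
    )


def path_mean_speed(path: np.ndarray, hz: int = BEHAVIOR_HZ) -> float:
    """Mean tangential speed (cm/s) of a sampled path, by direct differencing."""
    steps = np.hypot(*np.diff(path, axis=0).T)
    return float(steps.sum() / (len(path) - 1) * hz)


def trajectory_library(
    seed: int, n: int | None = None, config: TaskConfig | None = None
) -> list[tuple[TrajectorySpec, np.ndarray]]:
    """The a-priori set of target trajectories used throughout a study.

    Mirrors the paradigm's fixed set of ``config.n_trajectories`` paths
    from which each trial draws at random.
    """
    config = config or TaskConfig()
    n = config.n_trajectories if n is None else n
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    return [generate_trajectory(int(s), config) for s in child_seeds]
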