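"""Synthetic tracking behavior and ground-truth Purkinje-cell spike trains.

The simulated tracker is a second-order follower with two pathways: a
*predictive pursuit* pathway feeding forward the (always visible)
target's velocity and acceleration — aimed, under a hand-to-cursor
delay, at the target advanced by that delay, the trained compensation
that keeps the cursor inside the target — and a *corrective* PD term
driven by the cursor error as actually *seen*: perceived with a fixed
sensorimotor latency and, while the cursor is hidden inside the target,
replaced by a down-weighted proprioceptive estimate.  Smooth motor
noise enters as a low-pass-filtered random force plus a band-limited
positional tremor.  Because correction runs on the seen cursor, both
feedback manipulations mechanically degrade tracking, as observed
behaviorally.

Spike trains realize the encoding structure the analysis is built to
detect: an inhomogeneous Poisson rate carrying (i) a *leading* coupling
to the upcoming displayed position error, time-locked to the hand
movement that causes it, (ii) a *lagging* coupling to the cursor-
referenced position error gated by cursor visibility, and (iii)
independent couplings to hand position and velocity.  The visibility
gate applies to the lag coupling only: the lead pathway models a
motor-command-based prediction and is never gated.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .task import BASELINE, BEHAVIOR_HZ, BIN_MS, SPIKE_HZ, Condition, TaskConfig
from .trajectories import trajectory_library

__all__ = [
    "NoiseParams",
    "BehaviorTrial",
    "CellGroundTruth",
    "SpikeTrain",
    "CellRecording",
    "Session",
    "simulate_tracking",
    "generate_trial",
    "generate_spike_train",
    "instantaneous_rate",
    "sample_cell_truth",
    "sample_strong_pe_truth",
    "generate_session",
]


@dataclass(frozen=True)
class NoiseParams:
    """Tracking-controller parameters.

    Tracking noise has two smooth Gaussian components: a random force of
    RMS ``force_sd`` (cm/s^2, low-passed at ``noise_cutoff_hz``) driving
    the controller dynamics, and an additive band-limited positional
    tremor of RMS ``pos_sd`` (cm, low-passed at ``pos_cutoff_hz``) on the
    hand path itself, which gives the tracking error the broadband
    structure of real hand movement.  The controller corrects the seen
    cursor error with stiffness ``kp`` (1/s^2) and tracks target
    velocity with gain ``kv`` (1/s), a critically damped pair at natural
    frequency 4 rad/s; ``latency_ms`` is the sensorimotor latency of the
    corrective pathway.
    """

    force_sd: float = 6.0
    noise_cutoff_hz: float = 2.0
    pos_sd: float = 0.3
    pos_cutoff_hz: float = 3.5
    latency_ms: float = 150.0
    kp: float = 16.0
    kv: float = 8.0
    #: weight of the proprioceptive error estimate used while the cursor
    #: is invisible (hidden condition); < 1 degrades correction inside
    #: the target without opening the loop entirely
    prop_gain: float = 0.5


@dataclass
class BehaviorTrial:
    """One tracking trial sampled on the 200-Hz behavioral clock.

    ``cursor_xy[t] == hand_xy[t - delay]`` sample-exactly (the first hand
    sample is held during the initial delay).  Under the hidden-cursor
    condition ``visible[t]`` is False exactly when the cursor is strictly
    inside the target; in every other condition it is all True.
    """

    t_ms: np.ndarray
    target_xy: np.ndarray
    hand_xy: np.ndarray
    cursor_xy: np.ndarray
    visible: np.ndarray
    condition: Condition
    trial_index: int = 0
    session_index: int = 0

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        for name in ("target_xy", "hand_xy", "cursor_xy", "visible"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match the time grid")

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / BEHAVIOR_HZ


@dataclass(frozen=True)
class CellGroundTruth:
    """True couplings of a synthetic Purkinje cell.

    Latencies are positive ms: the lead coupling reads the *future*
    hand-locked prediction of the displayed position error,
    ``hand(t + lead_latency) − target(t + lead_latency + delay)`` (equal
    to hand − target in baseline); the lag coupling reads the *past*
    visible cursor-referenced error
    ``visible(t - lag) * PE_cursor(t - lag)``.  Kinematic couplings read
    hand position and velocity ``kin_lead_latency`` ms in the future and,
    when ``kin_lag_latency`` is positive, also ``kin_lag_latency`` ms in
    the past (gain split equally between the two components), modelling
    the predictive-plus-feedback kinematic encoding of these cells;
    kinematic couplings are hand-referenced and never gated.  Gains
    are (x, y) pairs in spikes/s per cm (or per cm/s for velocity).
    Latencies are drawn on the 20-ms grid so that true peaks are
    representable on the analysis lag grid.
    """

    baseline_rate: float
    lead_latency_ms: float
    lag_latency_ms: float
    lead_gain_xy: tuple[float, float]
    lag_gain_xy: tuple[float, float]
    pos_gain_xy: tuple[float, float]
    vel_gain_xy: tuple[float, float]
    kin_lead_latency_ms: float = 0.0
    kin_lag_latency_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        for lat in (self.lead_latency_ms, self.lag_latency_ms):
            if not (20.0 <= lat <= 480.0):
                raise ValueError("latencies must lie within [20, 480] ms")


@dataclass
class SpikeTrain:
    """Spike times (ms, 1-ms resolution, strictly increasing) for one trial."""

    spike_times_ms: np.ndarray
    trial_ref: int = 0

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times_ms, dtype=float)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "spike_times_ms", st)

    def __len__(self) -> int:
        return len(self.spike_times_ms)


@dataclass
class CellRecording:
    """One synthetic cell with its paired baseline and manipulation blocks."""

    truth: CellGroundTruth
    baseline: list[tuple[BehaviorTrial, SpikeTrain]]
    manipulation: list[tuple[BehaviorTrial, SpikeTrain]]


@dataclass
class Session:
    """A simulated recording study: per-cell paired trial blocks."""

    config: TaskConfig
    condition: Condition
    noise: NoiseParams
    seed: int
    cells: list[CellRecording]


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, cutoff_hz: float):
    """Gaussian force noise low-passed at ``cutoff_hz``, unit-RMS-normalized."""
    white = rng.standard_normal((n, 2))
    if sd == 0.0:
        return np.zeros((n, 2))
    b, a = signal.butter(2, cutoff_hz, fs=BEHAVIOR_HZ)
    smooth = signal.lfilter(b, a, white, axis=0)
    rms = np.sqrt(np.mean(smooth**2))
    if rms < 1e-12:
        return np.zeros((n, 2))
    return smooth * (sd / rms)


def simulate_tracking(
    target_path: np.ndarray,
    noise_params: NoiseParams,
    condition: Condition,
    seed: int,
    config: TaskConfig | None = None,
) -> BehaviorTrial:
    """Simulate hand tracking of a 200-Hz target path under one condition.

    The follower integrates hand acceleration
    ``a = a_tgt(t+d) + kv (v_tgt(t+d) - v_hand) - kp E_seen(t-Δ) + noise``
    with ``d`` the condition's cursor delay (pursuit anticipates the
    target; the aim-ahead is the trained delay compensation) and
    ``E_seen`` the cursor-minus-target error as perceived: delayed by the
    sensorimotor latency Δ and, when the cursor is invisible, replaced by
    the down-weighted proprioceptive hand-minus-target estimate.  With
    zero noise and zero latency the hand reproduces the target
    sample-exactly.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    tgt = np.asarray(target_path, dtype=float)
    n = len(tgt)
    dt = 1.0 / BEHAVIOR_HZ
    radius = config.target_radius_cm
    lat_samples = int(round(noise_params.latency_ms / 1000.0 * BEHAVIOR_HZ))
    delay_samples = int(round(condition.delay_ms / 1000.0 * BEHAVIOR_HZ))

    # discrete target velocity/acceleration consistent with Euler integration
    v_tgt = np.diff(tgt, axis=0, append=tgt[-1:]) / dt
    a_tgt = np.diff(v_tgt, axis=0, append=v_tgt[-1:]) / dt
    eta = _smooth_noise(rng, n, noise_params.force_sd, noise_params.noise_cutoff_hz)
    tremor = _smooth_noise(rng, n, noise_params.pos_sd, noise_params.pos_cutoff_hz)
    pnx, pny = tremor[:, 0].tolist(), tremor[:, 1].tolist()

    tx, ty = tgt[:, 0].tolist(), tgt[:, 1].tolist()
    vtx, vty = v_tgt[:, 0].tolist(), v_tgt[:, 1].tolist()
    atx, aty = a_tgt[:, 0].tolist(), a_tgt[:, 1].tolist()
    nx, ny = eta[:, 0].tolist(), eta[:, 1].tolist()

    hx_arr = [0.0] * n
    hy_arr = [0.0] * n
    cx_arr = [0.0] * n
    cy_arr = [0.0] * n
    ex_seen = [0.0] * n
    ey_seen = [0.0] * n
    visible = np.ones(n, dtype=bool)

    hx, hy = tx[0], ty[0]
    vhx, vhy = vtx[0], vty[0]
    kp, kv = noise_params.kp, noise_params.kv
    prop = noise_params.prop_gain
    r2 = radius * radius
    hide = condition.hide_inside

    for t in range(n):
        hx_arr[t] = hx + pnx[t]
        hy_arr[t] = hy + pny[t]
        j = t - delay_samples
        if j < 0:
            j = 0
        cx, cy = hx_arr[j], hy_arr[j]
        cx_arr[t] = cx
        cy_arr[t] = cy
        ex = cx - tx[t]
        ey = cy - ty[t]
        if hide and ex * ex + ey * ey < r2:
            # cursor invisible: the animal falls back on a weaker
            # proprioceptive estimate of the (hand-referenced) error
            visible[t] = False
            ex_seen[t] = prop * (hx_arr[t] - tx[t])
            ey_seen[t] = prop * (hy_arr[t] - ty[t])
        else:
            ex_seen[t] = ex
            ey_seen[t] = ey
        if t == n - 1:
            break
        i = t - lat_samples
        if i < 0:
            i = 0
            ecx = ecy = 0.0
        else:
            ecx, ecy = ex_seen[i], ey_seen[i]
        # The pursuit (feedforward) pathway is predictive: it anticipates
        # the smooth target with no perceptual lag and, under a cursor
        # delay, aims ahead by the session's known delay (the trained
        # compensation that keeps the *cursor* on the target).  Only the
        # corrective term is tied to the *seen* cursor error, perceived
        # with the sensorimotor latency.
        ia = t + delay_samples
        if ia > n - 1:
            ia = n - 1
        ax = atx[ia] + kv * (vtx[ia] - vhx) - kp * ecx + nx[t]
        ay = aty[ia] + kv * (vty[ia] - vhy) - kp * ecy + ny[t]
        hx += vhx * dt
        hy += vhy * dt
        vhx += ax * dt
        vhy += ay * dt

    t_ms = np.arange(n) * (1000.0 / BEHAVIOR_HZ)
    return BehaviorTrial(
        t_ms=t_ms,
        target_xy=tgt,
        hand_xy=np.column_stack([hx_arr, hy_arr]),
        cursor_xy=np.column_stack([cx_arr, cy_arr]),
        visible=visible,
        condition=condition,
    )


def longest_excursion_ms(trial: BehaviorTrial, config: TaskConfig) -> float:
    """Longest consecutive run (ms) with the cursor outside the target."""
    err = trial.cursor_xy - trial.target_xy
    outside = (err[:, 0] ** 2 + err[:, 1] ** 2) >= config.target_radius_cm**2
    edges = np.diff(np.concatenate(([0], outside.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    longest = int((ends - starts).max()) if starts.size else 0
    return longest * 1000.0 / BEHAVIOR_HZ


def _hold_samples(rng: np.random.Generator, config: TaskConfig) -> int:
    lo, hi = config.hold_range_ms
    ms = rng.uniform(lo, hi)
    ms = round(ms / BIN_MS) * BIN_MS
    return int(round(ms / 1000.0 * BEHAVIOR_HZ))


def generate_trial(
    target_path: np.ndarray,
    noise_params: NoiseParams,
    condition: Condition,
    seed: int,
    config: TaskConfig | None = None,
    max_retries: int = 20,
) -> BehaviorTrial:
    """Build a full trial (initial hold, tracking, final hold) that
    satisfies the 700-ms excursion rule, retrying with fresh noise.
    """
    config = config or TaskConfig()
    ss = np.random.SeedSequence(seed)
    for attempt, child in enumerate(ss.spawn(max_retries)):
        rng = np.random.default_rng(child)
        pre = _hold_samples(rng, config)
        post = _hold_samples(rng, config)
        full = np.concatenate(
            [
                np.repeat(target_path[:1], pre, axis=0),
                target_path,
                np.repeat(target_path[-1:], post, axis=0),
            ]
        )
        trial = simulate_tracking(
            full, noise_params, condition, int(rng.integers(2**31)), config
        )
        if longest_excursion_ms(trial, config) < config.excursion_limit_ms:
            return trial
    raise RuntimeError(
        f"trial violated the {config.excursion_limit_ms}-ms excursion rule in "
        f"{max_retries} attempts under noise settings {noise_params}"
    )


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------


def _upsample_1khz(values: np.ndarray, n_ms: int) -> np.ndarray:
    """Linear interpolation of a 200-Hz series onto 1-ms bin centers."""
    t200 = np.arange(len(values)) * (1000.0 / BEHAVIOR_HZ)
    t1k = np.arange(n_ms) + 0.5
    if values.ndim == 1:
        return np.interp(t1k, t200, values)
    return np.column_stack([np.interp(t1k, t200, values[:, k]) for k in range(values.shape[1])])


def _shift(arr: np.ndarray, k_ms: int) -> np.ndarray:
    """Shift so that out[t] = arr[t + k]; out-of-range samples contribute 0."""
    out = np.zeros_like(arr)
    if k_ms >= 0:
        if k_ms < len(arr):
            out[: len(arr) - k_ms] = arr[k_ms:]
    else:
        out[-k_ms:] = arr[: len(arr) + k_ms]
    return out


def instantaneous_rate(
    truth: CellGroundTruth,
    trial: BehaviorTrial,
    config: TaskConfig | None = None,
) -> np.ndarray:
    """Noiseless firing rate (spikes/s) on the 1-kHz spike clock."""
    config = config or TaskConfig()
    n_ms = int(round(trial.duration_ms))
    tgt = _upsample_1khz(trial.target_xy, n_ms)
    hand = _upsample_1khz(trial.hand_xy, n_ms)
    cur = _upsample_1khz(trial.cursor_xy, n_ms)
    vel = np.gradient(trial.hand_xy, 1.0 / BEHAVIOR_HZ, axis=0)
    vel = _upsample_1khz(vel, n_ms)
    vis200 = trial.visible.astype(float)
    idx = np.clip(((np.arange(n_ms) + 0.5) / (1000.0 / BEHAVIOR_HZ)).astype(int), 0, len(vis200) - 1)
    vis = vis200[idx]

    # The lead drive is the motor-locked prediction of the *displayed*
    # error: the hand position at t produces a cursor sample d ms later,
    # so the predicted on-screen error is hand(t) - target(t + d).  In
    # baseline (d = 0) this is simply hand - target.  The tail of the
    # trial where target(t + d) does not exist contributes zero.
    d = int(round(trial.condition.delay_ms))
    pe_hand = hand - _shift(tgt, d)
    if d > 0:
        pe_hand[-d:] = 0.0
    pe_cursor = cur - tgt
    lead = int(round(truth.lead_latency_ms))
    lag = int(round(truth.lag_latency_ms))
    kin_lead = int(round(truth.kin_lead_latency_ms))
    kin_lag = int(round(truth.kin_lag_latency_ms))
    # lead and (optional) lag kinematic components share the stated gain
    kin_shifts = [(kin_lead, 1.0)]
    if kin_lag > 0:
        kin_shifts = [(kin_lead, 0.5), (-kin_lag, 0.5)]

    rate = np.full(n_ms, truth.baseline_rate)
    for g, sig in zip(truth.lead_gain_xy, pe_hand.T):
        rate += g * _shift(sig, lead)
    gated = vis[:, None] * pe_cursor
    for g, sig in zip(truth.lag_gain_xy, gated.T):
        rate += g * _shift(sig, -lag)
    for shift, w in kin_shifts:
        for g, sig in zip(truth.pos_gain_xy, hand.T):
            rate += w * g * _shift(sig, shift)
        for g, sig in zip(truth.vel_gain_xy, vel.T):
            rate += w * g * _shift(sig, shift)
    return np.maximum(rate, 0.0)


def generate_spike_train(
    truth: CellGroundTruth,
    trial: BehaviorTrial,
    seed: int,
    config: TaskConfig | None = None,
) -> SpikeTrain:
    """Draw spikes from the rate model as an inhomogeneous Poisson process.

    On the 1-kHz clock, thinning reduces to an independent Bernoulli draw
    per 1-ms bin with probability ``rate / 1000`` (rates are far below
    the clock rate).  Spike times are the bin indices in ms.
    """
    rate = instantaneous_rate(truth, trial, config)
    if not np.any(rate > 0):
        warnings.warn("rate is zero everywhere; emitting an empty spike train")
    rng = np.random.default_rng(seed)
    hits = rng.random(len(rate)) < rate / SPIKE_HZ
    return SpikeTrain(spike_times_ms=np.nonzero(hits)[0].astype(float))


# ---------------------------------------------------------------------------
# populations and sessions
# ---------------------------------------------------------------------------

_GRID = BIN_MS  # ground-truth latencies live on the analysis grid


def sample_cell_truth(rng: np.random.Generator, seed: int = 0) -> CellGroundTruth:
    """Default synthetic Purkinje cell: lead + lag position-error couplings
    plus kinematic couplings at lead and lag latencies, with gains giving
    encoding strengths in the range seen in real recordings, where velocity
    encoding is common and robust while position encoding is distinctly
    rarer and weaker.
    """

    def _grid_uniform(lo: int, hi: int) -> float:
        return float(rng.integers(lo // _GRID, hi // _GRID + 1) * _GRID)

    def _gain_pair(lo: float, hi: float) -> tuple[float, float]:
        mag = rng.uniform(lo, hi)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        return (mag * np.cos(ang), mag * np.sin(ang))

    return CellGroundTruth(
        baseline_rate=float(rng.uniform(50.0, 80.0)),
        lead_latency_ms=_grid_uniform(60, 200),
        lag_latency_ms=_grid_uniform(280, 440),
        lead_gain_xy=_gain_pair(15.0, 30.0),
        lag_gain_xy=_gain_pair(15.0, 30.0),
        pos_gain_xy=_gain_pair(0.4, 1.2),
        vel_gain_xy=_gain_pair(1.5, 3.0),
        kin_lead_latency_ms=_grid_uniform(60, 160),
        kin_lag_latency_ms=_grid_uniform(220, 400),
        seed=seed,
    )


def sample_strong_pe_truth(rng: np.random.Generator, seed: int = 0) -> CellGroundTruth:
    """Position-error-dominant Purkinje cell: the regime above the
    documented recovery floor.

    PE coupling norms are 20–35 spikes/s/cm while kinematic couplings are
    kept weak (position ≤ 1.5 spikes/s/cm, velocity ≤ 0.7 spikes/s per
    cm/s).  Strong velocity couplings leak into the position-error
    regressions through tremor-velocity correlations and can displace the
    *absolute* lead-peak timing by one to three bins (the
    between-condition timing shift is unaffected); cells in this regime
    recover absolute lead and lag timings to within one 20-ms bin.
    """
    base = sample_cell_truth(rng, seed)
    d = base.__dict__.copy()
    for key, lo, hi in (
        ("lead_gain_xy", 20.0, 35.0),
        ("lag_gain_xy", 20.0, 35.0),
        ("pos_gain_xy", 0.5, 1.5),
        ("vel_gain_xy", 0.2, 0.7),
    ):
        g = np.asarray(d[key])
        norm = float(np.hypot(*g))
        d[key] = tuple(g / norm * rng.uniform(lo, hi))
    return CellGroundTruth(**d)


def generate_session(
    n_cells: int,
    n_trials_per_block: int,
    condition: Condition,
    seed: int,
    config: TaskConfig | None = None,
    noise: NoiseParams | None = None,
    truth_factory=None,
    library=None,
) -> Session:
    """Simulate a full study: per cell, a baseline block and a block under
    ``condition``, each of ``n_trials_per_block`` trials, with the fixed
    a-priori trajectory library shared by all cells.

    ``truth_factory(rng, seed) -> CellGroundTruth`` overrides the default
    cell sampler (used e.g. for pure-noise or lead-only populations).
    ``library`` (from :func:`~tracklag.trajectories.trajectory_library`)
    supplies a pre-built a-priori trajectory set, mirroring the paradigm's
    single fixed set across recording sessions; by default a library is
    built from a seed derived from ``seed``.
    """
    if n_trials_per_block < 1:
        raise ValueError("n_trials_per_block must be >= 1")
    config = config or TaskConfig()
    noise = noise or NoiseParams()
    truth_factory = truth_factory or sample_cell_truth

    root = np.random.SeedSequence(seed)
    lib_seed, cells_seed = root.spawn(2)
    if library is None:
        library = trajectory_library(
            int(lib_seed.generate_state(1)[0] % (2**31)), config=config
        )
    paths = [path for _spec, path in library]

    cells = []
    for c, cell_ss in enumerate(cells_seed.spawn(max(n_cells, 0))):
        rng = np.random.default_rng(cell_ss)
        truth = truth_factory(rng, seed=c)
        blocks: dict[str, list] = {}
        for block_name, cond in (("baseline", BASELINE), ("manipulation", condition)):
            trials = []
            for k in range(n_trials_per_block):
                path = paths[rng.integers(len(paths))]
                trial = generate_trial(
                    path, noise, cond, int(rng.integers(2**31)), config
                )
                trial.trial_index = k
                trial.session_index = c
                spikes = generate_spike_train(
                    truth, trial, int(rng.integers(2**31)), config
                )
                spikes.trial_ref = k
                trials.append((trial, spikes))
            blocks[block_name] = trials
        cells.append(
            CellRecording(
                truth=truth,
                baseline=blocks["baseline"],
                manipulation=blocks["manipulation"],
            )
        )
    return Session(config=config, condition=condition, noise=noise, seed=seed, cells=cells)
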