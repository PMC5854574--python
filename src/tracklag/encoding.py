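"""Residualized temporal regression of simple-spike firing on behavior.

The encoding question is answered in two OLS steps at every lag τ on a
20-ms grid from −500 to +500 ms (negative τ: firing leads behavior).
For a parameter pair of interest (position error, hand position, or hand
velocity), the mean-subtracted firing rate F(t+τ) is first regressed on
the four *other* behavioral parameters at time t; the residuals FR are
then regressed on the pair of interest, yielding R²(τ), the coefficient
pair (β₁, β₂), and the sensitivity √(β₁² + β₂²).

Significance is assessed against a trial-shuffle null: the assignment of
whole firing-rate trials to behavior trials is permuted (pairs truncated
to the shorter trial), the full profile recomputed, and the per-τ
threshold set at the null mean + 3 SD (upper side only, since R² ≥ 0).

Trials are pooled by concatenating samples; τ-shifted pairs that would
cross a trial boundary are dropped, never wrapped.  Internally each
two-step fit is solved from a single 8×8 Gram matrix, which makes the
100-shuffle null affordable; the arithmetic is exact OLS and is checked
against direct normal-equation solves in the test suite.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import KinematicsSeries, RateSeries
from .task import BIN_MS

__all__ = [
    "TAU_MS",
    "TauGrid",
    "PAIRS",
    "MAP_RANGES",
    "FiringMap",
    "EncodingProfile",
    "Peak",
    "PeakSet",
    "MatchedPair",
    "MatchedPeaks",
    "sensitivity",
    "residualize_firing",
    "regress_residuals",
    "temporal_profile",
    "shuffle_null",
    "analyze_block",
    "detect_peaks",
    "match_peaks",
    "restrict_inside_target",
    "build_firing_map",
]

#: the lag grid, ms; negative = firing leads behavior
TAU_MS = np.arange(-500, 501, BIN_MS)


@dataclass(frozen=True)
class TauGrid:
    """The −500…+500 ms lag grid in 20-ms steps (51 points)."""

    values: np.ndarray = field(default_factory=lambda: TAU_MS.copy())

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if len(v) < 3 or not np.all(np.diff(v) == BIN_MS):
            raise ValueError(f"tau grid step must be exactly {BIN_MS} ms")
        if not np.array_equal(v, -v[::-1]):
            raise ValueError("tau grid must be symmetric about 0")


#: parameter pair -> (nuisance columns, target columns)
PAIRS: dict[str, tuple[tuple[str, ...], tuple[str, str]]] = {
    "PE": (("X", "Y", "VX", "VY"), ("XE", "YE")),
    "position": (("XE", "YE", "VX", "VY"), ("X", "Y")),
    "velocity": (("XE", "YE", "X", "Y"), ("VX", "VY")),
}

#: half-range of the 8×8 firing-map workspace per pair
MAP_RANGES = {"PE": 2.0, "position": 6.0, "velocity": 12.0}
MAP_BINS = 8

_MIN_SAMPLES = 24


class CollinearityError(np.linalg.LinAlgError):
    pass


def sensitivity(beta_pair) -> float:
    """Overall sensitivity to a parameter pair: Euclidean norm of (β₁, β₂)."""
    b1, b2 = beta_pair
    return float(np.hypot(b1, b2))


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


def _design_matrix(kin: KinematicsSeries, pair: str) -> np.ndarray:
    """(n, 6) array: four nuisance columns then the two target columns."""
    nuisance, targets = PAIRS[pair]
    return np.column_stack([kin.column(c) for c in (*nuisance, *targets)])


def _rate_arrays(rates: list[RateSeries]) -> list[np.ndarray]:
    for r in rates:
        if r.stage != "mean_subtracted":
            raise ValueError("encoding expects mean-subtracted rate series")
    return [r.rate for r in rates]


def _check_columns(S: np.ndarray, pair: str) -> None:
    """Raise CollinearityError / degenerate-variance errors with column names."""
    nuisance, targets = PAIRS[pair]
    names = ("intercept", *nuisance, *targets)
    n = S[0, 0]
    var = np.diag(S)[1:7] / n - (S[0, 1:7] / n) ** 2
    for name, v in zip(names[1:], var):
        if v <= 1e-12:
            kind = "target" if name in targets else "nuisance"
            raise CollinearityError(f"degenerate variance in {kind} column {name!r}")
    # pairwise correlation check on the 6 behavior columns
    cov = S[1:7, 1:7] / n - np.outer(S[0, 1:7] / n, S[0, 1:7] / n)
    corr = cov / np.sqrt(np.outer(var, var))
    bad = [
        (names[1 + i], names[1 + j])
        for i in range(6)
        for j in range(i + 1, 6)
        if abs(corr[i, j]) > 1.0 - 1e-10
    ]
    if bad:
        raise CollinearityError(f"collinear behavior columns: {bad}")


def _two_step_from_gram(S: np.ndarray, want_betas: bool):
    """Exact two-step OLS (residualize on nuisance, regress on targets)
    from the 8×8 Gram of [1 | nuisance(4) | targets(2) | firing]."""
    A = slice(0, 5)
    H = np.array([0, 5, 6])
    beta1 = np.linalg.solve(S[A, A], S[A, 7])
    sse1 = max(S[7, 7] - S[A, 7] @ beta1, 0.0)
    h_fr = S[H, 7] - S[np.ix_(H, range(5))] @ beta1
    if sse1 <= 1e-12 * max(S[7, 7], 1.0):
        return 0.0, 0.0, 0.0
    beta2 = np.linalg.solve(S[np.ix_(H, H)], h_fr)
    r2 = float(np.clip((beta2 @ h_fr) / sse1, 0.0, 1.0))
    if want_betas:
        return r2, float(beta2[1]), float(beta2[2])
    return r2, 0.0, 0.0


def _gather(designs, rate_arrays, pairing, k, mask_idx):
    """Concatenated (design rows, firing values) for one lag and pairing.

    Behavior trial i is paired with firing trial pairing[i]; the pair is
    truncated to the shorter trial and the k-bin shift drops samples at
    the trial edge instead of wrapping.
    """
    rows_a, rows_y = [], []
    for i, j in enumerate(pairing):
        A = designs[i]
        y = rate_arrays[j]
        m = min(len(A), len(y))
        lo, hi = max(0, -k), m - max(0, k)
        if hi <= lo:
            continue
        if mask_idx is not None:
            idx = mask_idx[i]
            idx = idx[(idx >= lo) & (idx < hi)]
            if not idx.size:
                continue
            rows_a.append(A[idx])
            rows_y.append(y[idx + k])
        else:
            rows_a.append(A[lo:hi])
            rows_y.append(y[lo + k : hi + k])
    if not rows_a:
        return None, None
    return np.concatenate(rows_a), np.concatenate(rows_y)


def _profile_engine(
    designs,
    rate_arrays,
    pair: str,
    pairing,
    mask_idx=None,
    want_betas: bool = True,
    check: bool = True,
):
    """R² (and coefficient pair) at every τ of the grid."""
    ks = TAU_MS // BIN_MS
    r2 = np.zeros(len(ks))
    b1 = np.zeros(len(ks))
    b2 = np.zeros(len(ks))
    checked = not check
    for ik, k in enumerate(ks):
        X, y = _gather(designs, rate_arrays, pairing, int(k), mask_idx)
        if X is None or len(y) < _MIN_SAMPLES:
            raise ValueError(f"too few samples at tau = {TAU_MS[ik]} ms")
        S = np.empty((8, 8))
        S[0, 0] = len(y)
        S[0, 1:7] = S[1:7, 0] = X.sum(axis=0)
        S[0, 7] = S[7, 0] = y.sum()
        S[1:7, 1:7] = X.T @ X
        S[1:7, 7] = S[7, 1:7] = X.T @ y
        S[7, 7] = y @ y
        if not checked:
            _check_columns(S, pair)
            checked = True
        try:
            r2[ik], b1[ik], b2[ik] = _two_step_from_gram(S, want_betas)
        except np.linalg.LinAlgError:
            _check_columns(S, pair)
            raise
    return r2, b1, b2


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _pooled_rows(kins, lengths, pair, tau, mask_idx=None):
    """Row sets (nuisance X, targets G) matching the engine's retention rule
    for the identity pairing, given firing-trial lengths."""
    k = int(tau) // BIN_MS
    nuis_rows, tgt_rows, keep = [], [], []
    for i, kin in enumerate(kins):
        D = _design_matrix(kin, pair)
        m = min(len(kin), lengths[i])
        lo, hi = max(0, -k), m - max(0, k)
        if hi <= lo:
            continue
        if mask_idx is not None:
            idx = mask_idx[i]
            idx = idx[(idx >= lo) & (idx < hi)]
        else:
            idx = np.arange(lo, hi)
        nuis_rows.append(D[idx, :4])
        tgt_rows.append(D[idx, 4:6])
        keep.append((i, idx + k))
    return np.concatenate(nuis_rows), np.concatenate(tgt_rows), keep


def residualize_firing(
    rates: list[RateSeries], kins: list[KinematicsSeries], pair: str, tau: float
) -> np.ndarray:
    """Firing residuals FR at one τ: OLS of F(t+τ) on intercept plus the
    four nuisance parameters at t, pooled over trials."""
    arrays = _rate_arrays(rates)
    X, _G, keep = _pooled_rows(kins, [len(a) for a in arrays], pair, tau)
    y = np.concatenate([arrays[i][idx] for i, idx in keep])
    Xi = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return y - Xi @ beta


def regress_residuals(
    fr: np.ndarray, kins: list[KinematicsSeries], pair: str, tau: float
) -> tuple[float, tuple[float, float]]:
    """OLS of the firing residuals on the two target parameters at t.

    Returns (R², (β₁, β₂)).  The sample set must be the one produced by
    :func:`residualize_firing` at the same τ.
    """
    lengths = [len(k) for k in kins]
    _X, G, _keep = _pooled_rows(kins, lengths, pair, tau)
    if len(G) != len(fr):
        raise ValueError("residuals do not match the pooled sample set")
    for col, name in zip(G.T, PAIRS[pair][1]):
        if np.var(col) <= 1e-12:
            raise CollinearityError(f"degenerate variance in target column {name!r}")
    Gi = np.column_stack([np.ones(len(fr)), G])
    beta, *_ = np.linalg.lstsq(Gi, fr, rcond=None)
    resid = fr - Gi @ beta
    sst = float(np.sum((fr - fr.mean()) ** 2))
    if sst <= 0:
        return 0.0, (0.0, 0.0)
    r2 = float(np.clip(1.0 - np.sum(resid**2) / sst, 0.0, 1.0))
    return r2, (float(beta[1]), float(beta[2]))


@dataclass
class EncodingProfile:
    """Per-τ results of the two-step regression for one parameter pair."""

    parameter_pair: str
    tau_ms: np.ndarray
    r2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    sensitivity: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    threshold: np.ndarray | None = None

    @property
    def has_null(self) -> bool:
        return self.threshold is not None

    def attach_null(self, null_mean, null_sd) -> "EncodingProfile":
        self.null_mean = np.asarray(null_mean)
        self.null_sd = np.asarray(null_sd)
        self.threshold = self.null_mean + 3.0 * self.null_sd
        return self


def _masks_to_indices(kins, inside_only):
    if not inside_only:
        return None
    idx = [np.flatnonzero(k.inside_target) for k in kins]
    total = sum(len(k) for k in kins)
    kept = sum(len(i) for i in idx)
    if kept == 0:
        raise ValueError("no samples inside the target")
    if kept < 0.1 * total:
        warnings.warn(f"inside-target restriction keeps only {kept}/{total} samples")
    return idx


def restrict_inside_target(rates, kins):
    """Mask the analysis to samples with the cursor inside the target.

    The mask is indexed at behavior time t; the τ-shifted firing sample
    follows its behavior sample.  Returns (rates, kins, mask indices).
    """
    return rates, kins, _masks_to_indices(kins, True)


def temporal_profile(
    rates: list[RateSeries],
    kins: list[KinematicsSeries],
    pair: str,
    mask_idx=None,
) -> EncodingProfile:
    """Residualize + regress + sensitivity at every τ of the grid."""
    arrays = _rate_arrays(rates)
    designs = [_design_matrix(k, pair) for k in kins]
    pairing = list(range(len(arrays)))
    r2, b1, b2 = _profile_engine(designs, arrays, pair, pairing, mask_idx)
    return EncodingProfile(
        parameter_pair=pair,
        tau_ms=TAU_MS.copy(),
        r2=r2,
        beta1=b1,
        beta2=b2,
        sensitivity=np.hypot(b1, b2),
    )


def shuffle_null(
    rates: list[RateSeries],
    kins: list[KinematicsSeries],
    pair: str,
    n_shuffles: int = 100,
    seed: int = 0,
    mask_idx=None,
):
    """Trial-shuffle null distribution of R²(τ).

    Each repeat permutes the assignment of whole firing-rate trials to
    behavior trials (derangement not enforced; mismatched lengths are
    truncated to the shorter trial) and recomputes the full profile.
    Returns (null_mean, null_sd, threshold) with
    threshold = mean + 3 SD, the upper side only since R² ≥ 0.
    """
    if len(rates) < 2:
        raise ValueError("trial shuffling requires at least 2 trials")
    arrays = _rate_arrays(rates)
    designs = [_design_matrix(k, pair) for k in kins]
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, len(TAU_MS)))
    for s in range(n_shuffles):
        pairing = rng.permutation(len(arrays))
        null[s], _, _ = _profile_engine(
            designs, arrays, pair, pairing, mask_idx, want_betas=False, check=False
        )
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    return null_mean, null_sd, null_mean + 3.0 * null_sd


def analyze_block(
    rates,
    kins,
    pair: str,
    n_shuffles: int = 100,
    seed: int = 0,
    inside_only: bool = False,
) -> EncodingProfile:
    """Temporal profile with its shuffle null attached; optionally
    restricted to samples with the cursor inside the target."""
    mask_idx = _masks_to_indices(kins, inside_only)
    profile = temporal_profile(rates, kins, pair, mask_idx)
    nm, nsd, _thr = shuffle_null(rates, kins, pair, n_shuffles, seed, mask_idx)
    return profile.attach_null(nm, nsd)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    tau_ms: float
    r2: float
    beta_pair: tuple[float, float]
    significant: bool = True


@dataclass(frozen=True)
class PeakSet:
    """Significant lead (τ < 0) and lag (τ > 0) R² peaks, either optional."""

    lead: Peak | None = None
    lag: Peak | None = None


def _local_max_indices(v: np.ndarray, tau: np.ndarray) -> list[int]:
    """Strict local maxima; endpoints eligible against their single
    neighbor; plateaus broken toward smaller |τ| (negative side on ties)."""
    out = []
    n = len(v)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            out.append(min(range(i, j + 1), key=lambda m: (abs(tau[m]), tau[m] > 0)))
        i = j + 1
    return out


def detect_peaks(profile: EncodingProfile) -> PeakSet:
    """Largest significant local R² maximum on each side of τ = 0.

    τ = 0 is assigned to neither side; a side with no significant local
    maximum has no peak.  Requires the shuffle-null threshold.
    """
    if not profile.has_null:
        raise ValueError("detect_peaks requires a profile with a shuffle null")
    best: dict[str, Peak | None] = {"lead": None, "lag": None}
    for i in _local_max_indices(profile.r2, profile.tau_ms):
        tau = float(profile.tau_ms[i])
        if tau == 0.0 or profile.r2[i] <= profile.threshold[i]:
            continue
        side = "lead" if tau < 0 else "lag"
        if best[side] is None or profile.r2[i] > best[side].r2:
            best[side] = Peak(
                tau_ms=tau,
                r2=float(profile.r2[i]),
                beta_pair=(float(profile.beta1[i]), float(profile.beta2[i])),
            )
    return PeakSet(lead=best["lead"], lag=best["lag"])


@dataclass(frozen=True)
class MatchedPair:
    dtau_ms: float
    dr2: float
    base: Peak
    manip: Peak


@dataclass(frozen=True)
class MatchedPeaks:
    lead: MatchedPair | None = None
    lag: MatchedPair | None = None


def _signs_agree(a: Peak, b: Peak) -> bool:
    return all(np.sign(x) == np.sign(y) for x, y in zip(a.beta_pair, b.beta_pair))


def match_peaks(baseline: PeakSet, manipulated: PeakSet) -> MatchedPeaks:
    """Pair lead/lag peaks across conditions.

    A peak is matched only if present in both conditions with both
    regression coefficients of the same sign; matched pairs report
    Δτ = τ_manip − τ_base and ΔR².
    """
    matched = {}
    for side in ("lead", "lag"):
        pb, pm = getattr(baseline, side), getattr(manipulated, side)
        if pb is not None and pm is not None and _signs_agree(pb, pm):
            matched[side] = MatchedPair(
                dtau_ms=pm.tau_ms - pb.tau_ms,
                dr2=pm.r2 - pb.r2,
                base=pb,
                manip=pm,
            )
        else:
            matched[side] = None
    return MatchedPeaks(lead=matched["lead"], lag=matched["lag"])


# ---------------------------------------------------------------------------
# firing maps
# ---------------------------------------------------------------------------


@dataclass
class FiringMap:
    """8×8 mean mean-subtracted firing rate over a parameter workspace.

    ``grid[i, j]`` is the mean rate for the i-th bin of the first pair
    member and j-th bin of the second; bins with occupancy below the
    minimum are NaN (missing, not zero).
    """

    parameter_pair: str
    tau_ms: float
    grid: np.ndarray
    occupancy: np.ndarray
    edges: np.ndarray


def build_firing_map(
    rates: list[RateSeries],
    kins: list[KinematicsSeries],
    pair: str,
    tau: float,
    min_occupancy: int = 5,
) -> FiringMap:
    """Mean firing rate at t+τ binned on the behavior workspace at t.

    Samples outside the printed workspace ranges are discarded; bin
    occupancy below ``min_occupancy`` renders the bin missing.
    """
    arrays = _rate_arrays(rates)
    half = MAP_RANGES[pair]
    edges = np.linspace(-half, half, MAP_BINS + 1)
    k = int(tau) // BIN_MS
    sums = np.zeros((MAP_BINS, MAP_BINS))
    counts = np.zeros((MAP_BINS, MAP_BINS))
    tgt_cols = PAIRS[pair][1]
    for kin, y in zip(kins, arrays):
        m = min(len(kin), len(y))
        lo, hi = max(0, -k), m - max(0, k)
        if hi <= lo:
            continue
        u = kin.column(tgt_cols[0])[lo:hi]
        v = kin.column(tgt_cols[1])[lo:hi]
        w = y[lo + k : hi + k]
        s, _, _ = np.histogram2d(u, v, bins=[edges, edges], weights=w)
        c, _, _ = np.histogram2d(u, v, bins=[edges, edges])
        sums += s
        counts += c
    if not counts.any():
        raise ValueError("all firing-map bins are empty")
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(counts >= min_occupancy, sums / np.maximum(counts, 1), np.nan)
    return FiringMap(
        parameter_pair=pair,
        tau_ms=float(tau),
        grid=grid,
        occupancy=counts.astype(int),
        edges=edges,
    )
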