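"""Independent oracles and tiny builders shared by the test modules."""
import numpy as np

from tracklag.encoding import PAIRS
from tracklag.preprocess import KinematicsSeries, RateSeries


def make_kin(n, rng, inside=None):
    cols = {c: rng.normal(0.0, 1.0, n) for c in ("X", "Y", "VX", "VY", "XE", "YE")}
    return KinematicsSeries(
        t_ms=np.arange(n) * 20.0 + 10.0,
        inside_target=np.ones(n, bool) if inside is None else inside,
        **cols,
    )


def make_rate(values):
    values = np.asarray(values, float)
    return RateSeries(
        np.arange(len(values)) * 20.0 + 10.0, values, stage="mean_subtracted"
    )


def brute_two_step(kins, rates, pair, tau):
    """Explicit (XᵀX)⁻¹Xᵀ normal-equation solves on pooled τ-shifted
    samples — independent of the package's Gram-based engine."""
    k = int(tau) // 20
    nuis_cols, tgt_cols = PAIRS[pair]
    Xs, Gs, ys = [], [], []
    for kin, r in zip(kins, rates):
        m = min(len(kin), len(r.rate))
        lo, hi = max(0, -k), m - max(0, k)
        Xs.append(np.column_stack([kin.column(c)[lo:hi] for c in nuis_cols]))
        Gs.append(np.column_stack([kin.column(c)[lo:hi] for c in tgt_cols]))
        ys.append(r.rate[lo + k : hi + k])
    X = np.vstack(Xs)
    G = np.vstack(Gs)
    y = np.concatenate(ys)
    Xi = np.column_stack([np.ones(len(y)), X])
    b1 = np.linalg.inv(Xi.T @ Xi) @ Xi.T @ y
    fr = y - Xi @ b1
    Gi = np.column_stack([np.ones(len(fr)), G])
    b2 = np.linalg.inv(Gi.T @ Gi) @ Gi.T @ fr
    resid = fr - Gi @ b2
    sst = np.sum((fr - fr.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
    return fr, r2, (b2[1], b2[2])
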