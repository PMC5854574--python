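"""Quick-look figures: R² temporal profiles and firing maps."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .encoding import EncodingProfile, FiringMap


def plot_profile(
    profiles: dict[str, EncodingProfile], ax=None, title: str = ""
):
    """Overlay R²(τ) per condition, with shuffle thresholds dashed."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    colors = {"baseline": "k", "manipulation": "tab:green"}
    for name, p in profiles.items():
        c = colors.get(name)
        ax.plot(p.tau_ms, p.r2, color=c, label=name)
        if p.has_null:
            ax.plot(p.tau_ms, p.threshold, color=c, ls="--", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel(r"$\tau$ (ms), negative = firing leads")
    ax.set_ylabel(r"$R^2$")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_firing_map(fmap: FiringMap, ax=None, target_radius: float | None = None):
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3))
    extent = [fmap.edges[0], fmap.edges[-1]] * 2
    im = ax.imshow(
        fmap.grid.T, origin="lower", extent=extent, cmap="RdBu_r", aspect="equal"
    )
    if target_radius is not None:
        ax.add_patch(
            plt.Circle((0, 0), target_radius, fill=False, color="k", lw=1.0)
        )
    ax.set_title(f"{fmap.parameter_pair}  τ = {fmap.tau_ms:+.0f} ms", fontsize=9)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_study(study, outdir: str | Path) -> Path:
    """One R² profile figure per analyzed cell and parameter pair."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ana in study.analyses:
        pairs = sorted({p for p, _ in ana.profiles})
        fig, axes = plt.subplots(
            1, len(pairs), figsize=(5 * len(pairs), 3.2), squeeze=False
        )
        for ax, pair in zip(axes[0], pairs):
            plot_profile(
                {b: ana.profiles[(pair, b)] for b in ("baseline", "manipulation")},
                ax=ax,
                title=f"cell {ana.cell_id} — {pair}",
            )
        fig.tight_layout()
        fig.savefig(outdir / f"profiles_cell{ana.cell_id:03d}.png", dpi=110)
        plt.close(fig)
    return outdir
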