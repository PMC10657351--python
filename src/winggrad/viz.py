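"""Profile and modularity plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_span_profiles", "plot_cr_null"]


def plot_span_profiles(profiles: dict, regions, template=None, out_path=None,
                       ylabel: str = "value"):
    """Overlay per-slice profiles (e.g. sigma2 and disparity) along the span.

    ``profiles`` maps a label to a 1-D array over slices; ``regions`` gives
    the per-slice AW/HW labels used to shade the armwing and mark the wrist.
    ``template`` optionally adds a mechanical-sensitivity expectation curve
    scaled to the first profile's range.
    """
    n = len(next(iter(profiles.values())))
    x = np.arange(1, n + 1)
    regions = list(regions)
    fig, ax = plt.subplots(figsize=(7, 4))
    styles = ["-", "--", ":", "-."]
    for (label, y), ls in zip(profiles.items(), styles):
        ax.plot(x, y, ls, label=label)
    n_aw = sum(r == "AW" for r in regions)
    ax.axvspan(0.5, n_aw + 0.5, color="0.9", zorder=0)
    ax.axvline(n_aw + 0.5, color="k", lw=0.8, ls="--")
    if template is not None:
        ref = next(iter(profiles.values()))
        t = np.asarray(template, float)
        span = np.nanmax(ref) - np.nanmin(ref)
        t_span = t.max() - t.min()
        scaled = np.nanmin(ref) + (t - t.min()) * (span / t_span if t_span else 0.0)
        ax.plot(x, scaled, color="gray", alpha=0.6, label="sensitivity template")
    ax.set_xlabel("slice (base → tip)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_cr_null(result, out_path=None):
    """Observed CR against its permutation null distribution."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if result.null_crs is not None:
        ax.hist(result.null_crs, bins=30, color="0.7")
    ax.axvline(result.cr, color="crimson", lw=2,
               label=f"CR = {result.cr:.3f} (p = {result.p_value:.3g})")
    ax.set_xlabel("covariance ratio")
    ax.set_ylabel("permutations")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
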