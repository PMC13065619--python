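"""Simple diagnostic figures: predicted-vs-observed scatter and deviation
profiles.  Kept deliberately minimal; all figures are per-animal."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .core import FitResult
from .signatures import Signature

__all__ = ["plot_predicted_vs_observed", "plot_profiles"]


def plot_predicted_vs_observed(
    fit: FitResult, observed: Signature, path: str | Path, title: str = ""
) -> None:
    """Scatter of best-fit predicted vs observed FA concentrations, with the
    fitted regression line.  Each point is one fatty acid."""
    labs = fit.predicted.labels
    x = fit.predicted.aligned(labs)
    y = observed.aligned(labs)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, color="tab:blue")
    if len(labs) >= 2 and float(x.max() - x.min()) > 0:
        b, a = _lstsq_line(x, y)
        xs = [x.min(), x.max()]
        ax.plot(xs, [a + b * v for v in xs], "k:", lw=1)
    ax.set_xlabel("predicted (µg/mg)")
    ax.set_ylabel("observed (µg/mg)")
    label = f"BMD={fit.bmd:.1f}"
    if fit.r_squared == fit.r_squared:  # not nan
        label += f", r²={fit.r_squared:.2f}"
    ax.set_title(f"{title} {label}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _lstsq_line(x, y):
    import numpy as np

    b, a = np.polyfit(x, y, 1)
    return b, a


def plot_profiles(fit: FitResult, path: str | Path, title: str = "") -> None:
    """Deviation-vs-proportion curve per source (solution-uniqueness check)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for source, prof in fit.profiles.items():
        ax.plot(100 * prof.grid, prof.min_deviation, label=source)
    ax.set_xlabel("fixed source contribution (%)")
    ax.set_ylabel("minimal deviation (µg/mg)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
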