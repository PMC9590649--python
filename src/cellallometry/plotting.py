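"""Four-panel regression figure: data, posterior-mean curves, HDI and ppd bands."""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .data import AllometryDataset
from .inference import CurveBand
from .models import ModelSpec

__all__ = ["plot_panels"]


def plot_panels(
    dataset: AllometryDataset,
    curves: Mapping[str, CurveBand],
    elpd: Optional[Mapping[str, tuple[float, float]]] = None,
    path: Optional[str] = None,
):
    """Render one panel per model: scatter of (n, k), posterior-mean curve,
    95% HDI band of f(n) and 95% band of the posterior predictive.

    ``elpd`` maps model name to (elpd, se) for the panel annotation.
    Axes are the log10-transformed variables on linear scales.
    """
    names = list(curves)
    ncols = 2
    nrows = (len(names) + 1) // 2
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(5.0 * ncols, 3.6 * nrows),
        sharex=True, sharey=True, squeeze=False,
    )
    for ax, name in zip(axes.ravel(), names):
        band = curves[name]
        ax.fill_between(
            band.grid, band.ppd_lower, band.ppd_upper,
            color="tab:orange", alpha=0.25, lw=0, label="95% HDI ppd",
        )
        ax.fill_between(
            band.grid, band.hdi_lower, band.hdi_upper,
            color="tab:blue", alpha=0.35, lw=0, label="95% HDI f(n)",
        )
        ax.plot(band.grid, band.mean, color="tab:blue", lw=1.5,
                label="posterior mean")
        ax.scatter(dataset.n, dataset.k, s=18, facecolors="none",
                   edgecolors="k", lw=0.8, zorder=3, label="data")
        title = ModelSpec.from_name(name).label()
        if elpd and name in elpd:
            e, se = elpd[name]
            title += f"\nelpd = {e:.2f} (se {se:.2f})"
        ax.set_title(title, fontsize=9)
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    for ax in axes[-1, :]:
        ax.set_xlabel(r"$n = \log_{10}$(number of cells)")
    for ax in axes[:, 0]:
        ax.set_ylabel(r"$k = \log_{10}$(number of cell types)")
    axes[0, 0].legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
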