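"""Pseudo-spectrum rendering.

A pseudo-spectrum plots a statistic (covariance) over the chemical-shift
axis, coloured by the corresponding correlation coefficient on a symmetric
blue-white-red map clipped at ±1, with the ppm axis reversed as is
conventional for NMR.  SVG output is made deterministic (fixed hash salt,
no embedded date) so rerenders diff cleanly.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

from .correlate import HetcaResult, StocsyResult

__all__ = ["plot_pseudo_spectrum"]

plt.rcParams["svg.hashsalt"] = "elina"


def plot_pseudo_spectrum(
    result: HetcaResult | StocsyResult,
    path: str | Path,
    title: str | None = None,
) -> None:
    """Render a HetCA or STOCSY result to an image file (SVG recommended)."""
    centres = result.bucket_centres
    cov = result.covariance
    corr = np.nan_to_num(result.correlation, nan=0.0)

    fig, ax = plt.subplots(figsize=(9, 3.2))
    pts = np.column_stack([centres, cov]).reshape(-1, 1, 2)
    segments = np.concatenate([pts[:-1], pts[1:]], axis=1)
    lc = LineCollection(
        segments,
        cmap="bwr",
        norm=plt.Normalize(-1.0, 1.0),
        linewidths=0.8,
    )
    lc.set_array(0.5 * (corr[:-1] + corr[1:]))
    ax.add_collection(lc)
    ax.set_xlim(centres[-1], centres[0])  # reversed ppm axis
    pad = 0.05 * (cov.max() - cov.min() or 1.0)
    ax.set_ylim(cov.min() - pad, cov.max() + pad)
    ax.set_xlabel(r"$\delta_H$ (ppm)")
    ax.set_ylabel("covariance")
    if title is None and isinstance(result, StocsyResult):
        title = f"STOCSY, driver {result.driver_ppm:g} ppm"
    elif title is None:
        title = "HetCA pseudo-spectrum"
    ax.set_title(title)
    fig.colorbar(lc, ax=ax, label="correlation")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
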