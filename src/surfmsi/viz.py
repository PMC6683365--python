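"""PNG rendering of ion maps, masks and association heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_ion_heatmap", "save_grid_tsv", "save_association_heatmap"]


def save_ion_heatmap(values: np.ndarray, path: str | Path, title: str = "",
                     vmin: float | None = None, vmax: float | None = None) -> None:
    """Render one 2D intensity grid; NaN (missing/off-tissue) in grey.

    Pass shared ``vmin``/``vmax`` to put several sections on one color
    scale.
    """
    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.85")
    im = ax.imshow(values, origin="upper", cmap=cmap, vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_grid_tsv(values: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, values, delimiter="\t", fmt="%.6g")


def save_association_heatmap(results, path: str | Path) -> None:
    """Spearman rho matrix: physiology summaries × (ion, MSI metric)."""
    import pandas as pd

    df = pd.DataFrame([(r.parameter, f"{r.ion}\n{r.msi_metric}", r.rho)
                       for r in results], columns=["param", "metric", "rho"])
    mat = df.pivot(index="param", columns="metric", values="rho")
    fig, ax = plt.subplots(figsize=(1.2 * len(mat.columns) + 2, 0.6 * len(mat) + 2))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(mat.columns)), mat.columns, fontsize=7)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=8)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, f"{mat.iat[i, j]:.2f}", ha="center", va="center",
                    fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Spearman rho")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
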