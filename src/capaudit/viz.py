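"""Minimal status-matrix heatmap helper."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np


def plot_status_matrix(
    matrix: Mapping[str, Mapping[str, object]],
    path: str | Path,
    title: str = "Fraction of samples with sufficient coverage",
) -> None:
    """Render a gene × cohort sufficiency-fraction heatmap to an image file.

    Cells marked ``not_considered`` (cohorts with a called mutation in the
    gene) are masked out, matching their exclusion from the audit.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = sorted(matrix)
    cohorts = sorted({c for row in matrix.values() for c in row})
    data = np.full((len(genes), len(cohorts)), np.nan)
    for i, g in enumerate(genes):
        for j, c in enumerate(cohorts):
            v = matrix[g].get(c)
            if isinstance(v, (int, float)):
                data[i, j] = v
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(cohorts) + 2), max(3, 0.3 * len(genes) + 2))
    )
    im = ax.imshow(data, aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(cohorts)), cohorts, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
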