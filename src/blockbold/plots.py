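"""Polar SNR/phase plots and connectivity heat maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import ROI_ORDER


def polar_snr_phase(summaries, path: str | Path, title: str = "") -> None:
    """2D polar scatter: radius = SNR, angle = fundamental phase.

    Solid markers for p < 0.01, open for p < 0.05, crosses otherwise.
    """
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    for s in summaries:
        th = np.deg2rad(s.phase_deg)
        if s.p < 0.01:
            ax.plot(th, s.snr, "o", color="C1")
        elif s.p < 0.05:
            ax.plot(th, s.snr, "o", mfc="none", color="C1")
        else:
            ax.plot(th, s.snr, "x", color="gray")
    ax.set_title(title)
    fig.savefig(str(path), dpi=100)
    plt.close(fig)


def connectivity_heatmap(matrix: np.ndarray, path: str | Path,
                         p_matrix: np.ndarray | None = None,
                         title: str = "") -> None:
    """Correlation heat map with significance outlines above the diagonal."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(ROI_ORDER)), ROI_ORDER, rotation=45, ha="right")
    ax.set_yticks(range(len(ROI_ORDER)), ROI_ORDER)
    if p_matrix is not None:
        k = matrix.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                if np.isnan(p_matrix[i, j]):
                    continue
                if p_matrix[i, j] < 0.01:
                    ec, lw = "black", 2.0
                elif p_matrix[i, j] < 0.05:
                    ec, lw = "black", 0.8
                else:
                    continue
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1,
                                           fill=False, edgecolor=ec, lw=lw))
    fig.colorbar(im, ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path), dpi=100)
    plt.close(fig)
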