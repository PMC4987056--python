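"""Vector-graphics output: scores, backscaled loadings, correlation heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .chemometrics import BackscaledLoading, PCAResult  # noqa: E402
from .corrstruct import CorrelationMatrix  # noqa: E402

__all__ = ["plot_scores", "plot_backscaled_loadings", "plot_correlation_heatmap"]


def plot_scores(result: PCAResult | np.ndarray, labels, path: str | Path,
                title: str = "scores") -> None:
    scores = result.scores if isinstance(result, PCAResult) else np.asarray(result)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in sorted(set(labels.tolist())):
        sel = labels == lab
        ax.scatter(scores[sel, 0], scores[sel, 1], s=14, label=str(lab))
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_backscaled_loadings(bl: BackscaledLoading, path: str | Path,
                             title: str = "backscaled loading weights") -> None:
    """Pseudo-spectrum: amplitude = weight x natural sd, colored by the
    correlation of each variable with the response."""
    x = np.arange(len(bl.columns))
    numeric = all(isinstance(c, (int, float, np.floating)) for c in bl.columns)
    if numeric:
        x = np.asarray(bl.columns, dtype=float)
    fig, ax = plt.subplots(figsize=(7, 3.2))
    sc = ax.scatter(x, bl.amplitude, c=bl.color, cmap="coolwarm",
                    vmin=-1, vmax=1, s=8)
    ax.vlines(x, 0, bl.amplitude, color="0.8", lw=0.5, zorder=0)
    fig.colorbar(sc, ax=ax, label="correlation with response")
    if numeric:
        ax.invert_xaxis()
        ax.set_xlabel("ppm")
    else:
        ax.set_xticks(x)
        ax.set_xticklabels([str(c) for c in bl.columns], rotation=90, fontsize=6)
    ax.set_ylabel("amplitude (covariance scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_correlation_heatmap(m: CorrelationMatrix, path: str | Path,
                             title: str = "clustered correlations") -> None:
    order = m.ordering if m.ordering is not None else list(m.r.columns)
    R = m.r.loc[order, order].to_numpy().copy()
    if m.mask is not None:
        R = np.where(m.mask.loc[order, order].to_numpy(), np.nan, R)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(R, cmap="coolwarm", vmin=-1, vmax=1, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ticks = np.arange(len(order))
    ax.set_xticks(ticks)
    ax.set_yticks(ticks)
    ax.set_xticklabels([str(c) for c in order], rotation=90, fontsize=5)
    ax.set_yticklabels([str(c) for c in order], fontsize=5)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
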