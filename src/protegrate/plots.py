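"""Diagnostic plots: KM curves, consensus CDFs, consensus heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_km(curves: dict, path: str, title: str = "Overall survival") -> None:
    """Step plot of per-group Kaplan-Meier survival functions."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sf in curves.items():
        ax.step(sf.index, sf.iloc[:, 0], where="post", label=str(label))
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_consensus_cdf(result, path: str) -> None:
    """Consensus CDF curves per k with the delta-area in the legend."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for k, (grid, cdf) in result.cdf.items():
        ax.plot(grid, cdf, label=f"k={k} (dA={result.delta_area[k]:.2f})")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_consensus_matrix(result, k: int, path: str) -> None:
    order = result.labels[k].sort_values().index
    C = result.consensus[k].loc[order, order]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(C.to_numpy(), vmin=0, vmax=1, cmap="Blues", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="consensus")
    ax.set_title(f"consensus matrix, k={k}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
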