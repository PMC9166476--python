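"""Report figures: per-sample heatmaps, class bar charts, t-SNE embedding.

All plotting is report-only; no analyzed quantity is derived from a
figure.  The four-panel heatmap shows, for one perturbed sample, the
original expression vector X, the perturbation P on a diverging scale
(positive = red = tumor-downregulated, negative = blue =
tumor-upregulated), the perturbed vector X+P, and the target-class mean
μ_T.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gem_io import ExpressionMatrix

__all__ = ["plot_sample_heatmap", "plot_class_bars", "plot_embedding"]


def plot_sample_heatmap(x: pd.Series, p: pd.Series, xp: pd.Series,
                        mu_t: pd.Series, path) -> None:
    """Four-panel (X, P, X+P, μ_T) column heatmap for one sample."""
    vectors = [x, p, xp, mu_t]
    n = len(x)
    if any(len(v) != n for v in vectors):
        raise ValueError("all four vectors must have equal length")
    fig, axes = plt.subplots(1, 4, figsize=(6, 8), sharey=True)
    titles = ["X", "P", "X+P", "mu_T"]
    expr_vals = np.concatenate([x.to_numpy(), xp.to_numpy(), mu_t.to_numpy()])
    vmin, vmax = np.nanmin(expr_vals), np.nanmax(expr_vals)
    p_max = max(float(np.nanmax(np.abs(p.to_numpy()))), 1e-12)
    for ax, vec, title in zip(axes, vectors, titles):
        col = vec.to_numpy(dtype=float).reshape(-1, 1)
        if title == "P":
            im = ax.imshow(col, aspect="auto", cmap="bwr",
                           vmin=-p_max, vmax=p_max)
        else:
            im = ax.imshow(col, aspect="auto", cmap="viridis",
                           vmin=vmin, vmax=vmax)
        ax.set_title(title)
        ax.set_xticks([])
        fig.colorbar(im, ax=ax, shrink=0.6)
    axes[0].set_ylabel("genes")
    fig.suptitle(str(x.name) if x.name is not None else "sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_class_bars(summary: pd.DataFrame, value_prefix: str, path,
                    title: str = "") -> None:
    """Grouped bar chart (one bar pair per class) with SE error bars.

    ``value_prefix`` picks the quantity, e.g. ``avg_up_count`` pairs with
    ``avg_down_count`` / ``se_*`` columns.
    """
    classes = summary["class"]
    idx = np.arange(len(classes))
    width = 0.38
    fig, ax = plt.subplots(figsize=(8, 4))

    def cols(direction: str) -> tuple[np.ndarray, np.ndarray]:
        for cand in (f"{value_prefix}_{direction}",
                     value_prefix.replace("DIR", direction)):
            if cand in summary:
                se = summary.get(cand.replace("avg", "se", 1),
                                 pd.Series(np.zeros(len(summary))))
                return summary[cand].to_numpy(), se.to_numpy()
        raise KeyError(f"no column for {value_prefix}/{direction}")

    up_vals, up_se = cols("up")
    down_vals, down_se = cols("down")
    ax.bar(idx - width / 2, down_vals, width, yerr=down_se,
           color="firebrick", label="tumor-downregulated (P > 0)")
    ax.bar(idx + width / 2, up_vals, width, yerr=up_se,
           color="steelblue", label="tumor-upregulated (P < 0)")
    ax.set_xticks(idx, classes, rotation=30, ha="right")
    ax.set_ylabel(value_prefix)
    ax.set_title(title or value_prefix)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(gem: ExpressionMatrix, labels: pd.Series,
                   perturbed: ExpressionMatrix | None, path,
                   seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE embedding of all samples (plus perturbed samples), seed-fixed.

    Returns the embedding coordinates (rows aligned to gem samples, then
    perturbed samples) so callers can compute centroid distances.
    """
    from sklearn.manifold import TSNE

    mats = [gem.values.T]
    names = list(labels.reindex(gem.sample_ids))
    if perturbed is not None:
        mats.append(perturbed.values.T)
        names += ["perturbed"] * perturbed.n_samples
    x = np.vstack(mats)
    if x.shape[0] < 3:
        raise ValueError("embedding needs at least 3 samples")
    perplexity = min(perplexity, (x.shape[0] - 1) / 3)
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(x)
    fig, ax = plt.subplots(figsize=(7, 6))
    for cls in dict.fromkeys(names):
        sel = np.array([n == cls for n in names])
        ax.scatter(emb[sel, 0], emb[sel, 1], s=12, label=cls, alpha=0.7)
    ax.legend(fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return emb
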