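"""Small plotting helpers for evaluation reports (optional)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_bray_curtis_by_purity(
    mixture_metrics: pd.DataFrame, path: str | Path
) -> Path:
    """Boxplots of per-mixture Bray-Curtis grouped by purity level and method.

    Expects the ``mixture_metrics`` frame produced by
    :func:`pseudomix.evaluate.report` (columns ``bray_curtis``, ``purity``,
    ``method``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = sorted(mixture_metrics["method"].unique())
    fig, axes = plt.subplots(
        1, len(methods), figsize=(4 * len(methods), 3.2), squeeze=False, sharey=True
    )
    for ax, method in zip(axes[0], methods):
        sub = mixture_metrics[mixture_metrics["method"] == method]
        levels = sorted(sub["purity"].dropna().unique())
        data = [sub.loc[sub["purity"] == p, "bray_curtis"] for p in levels]
        ax.boxplot(data, tick_labels=[f"{p:.0%}" for p in levels])
        ax.set_title(method)
        ax.set_xlabel("tumour purity")
        ax.set_ylabel("Bray-Curtis dissimilarity")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
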