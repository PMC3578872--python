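"""Basic cumulative-density and box plots for the analysis outputs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402


def cumulative_density(samples: dict[str, np.ndarray], xlabel: str,
                       path: str | Path, log_x: bool = False) -> None:
    """Empirical CDF curves for named samples (e.g. target vs non-target
    LSR, or up- vs down-group preference scores)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for label, values in samples.items():
        x = np.sort(np.asarray(values, float))
        ax.step(x, np.arange(1, x.size + 1) / x.size, where="post",
                label=f"{label} (n={x.size})")
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def change_by_site_bin(summaries: pd.DataFrame, site_counts: pd.Series,
                       column: str, path: str | Path,
                       ylabel: str | None = None) -> None:
    """Box plots of a per-gene change column binned by aUTR site count,
    with the zero-site bin leftmost."""
    bins = np.minimum(site_counts.reindex(summaries.index, fill_value=0), 5)
    labels = ["0", "1", "2", "3", "4", "5+"]
    groups = [summaries.loc[bins == i, column].to_numpy()
              for i in range(6)]
    keep = [i for i, gr in enumerate(groups) if gr.size]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.boxplot([groups[i] for i in keep], tick_labels=[labels[i] for i in keep],
               showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.7, ls="--")
    ax.set_xlabel("aUTR target sites of up-group families")
    ax.set_ylabel(ylabel or column)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
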