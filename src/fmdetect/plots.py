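"""Small plotting helpers for experiment outputs (Agg backend, file output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_model_comparison(results: pd.DataFrame, path: str | Path) -> Path:
    """Grouped bar chart of precision/recall/F1 per experiment cell."""
    metrics = [m for m in ("precision", "recall", "f1") if m in results.columns]
    labels = [
        f"in{int(row['model_input'])}/{row['classifier']}" if "classifier" in results.columns
        else str(i)
        for i, (_, row) in enumerate(results.iterrows())
    ]
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(results), 3.5))
    width = 0.8 / max(len(metrics), 1)
    for k, metric in enumerate(metrics):
        xs = [i + k * width for i in range(len(results))]
        ax.bar(xs, results[metric].fillna(0.0), width=width, label=metric)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(results))])
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylim(0, 1)
    ax.set_ylabel("score")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_performance_vs_count(table: pd.DataFrame, path: str | Path) -> Path:
    """Per-scan precision/recall against the number of UDFM events, sorted."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for metric, marker in (("precision", "o"), ("recall", "s")):
        if metric in table.columns:
            ax.plot(table["n_udfm"], table[metric], marker=marker, label=metric)
    ax.set_xlabel("UDFM events per scan")
    ax.set_ylabel("score")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
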