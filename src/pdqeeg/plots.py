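"""Report figures: LMG share bar chart and ROC curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import ModelReport


def plot_lmg_shares(report: ModelReport, path: str | Path) -> Path:
    path = Path(path)
    shares = dict(sorted(report.lmg_shares.items(), key=lambda kv: -kv[1]))
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(range(len(shares)), list(shares.values()), color="#4878a8")
    ax.set_xticks(range(len(shares)), list(shares), rotation=30, ha="right")
    ax.set_ylabel("explained variance share (%)")
    ax.set_title(f"LMG decomposition (total {sum(shares.values()):.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_roc(report: ModelReport, path: str | Path) -> Path:
    if report.roc is None:
        raise ValueError("report has no ROC summary")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc.fpr, report.roc.tpr, color="#a84848")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC = {report.roc.auc:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
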