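"""Best-effort summary figures for comparison reports.

Two convenience renderers mirror the usual comparison displays: bar
charts of the indicator medians, and box-style plots built from the
reported percentile ranges (whiskers at the 90th range, box at the 80th,
line at the median).  Tables are the primary output; these figures are a
convenience layer over them.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["bar_chart", "box_chart"]

_PERIOD_ORDER = ["short", "medium", "long"]


def _grid(table):
    indicators = list(dict.fromkeys(table["indicator"]))
    rules = list(dict.fromkeys(table["rule"]))
    ncols = 3
    nrows = int(np.ceil(len(indicators) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    return indicators, rules, fig, axes


def bar_chart(table, path: str | Path) -> None:
    """One panel per indicator: median value per rule in each period."""
    indicators, rules, fig, axes = _grid(table)
    width = 0.8 / len(rules)
    for k, ind in enumerate(indicators):
        ax = axes[k // 3][k % 3]
        sub = table[table["indicator"] == ind]
        for j, rule in enumerate(rules):
            med = [
                sub[(sub["rule"] == rule) & (sub["period"] == p)]["median"].squeeze()
                for p in _PERIOD_ORDER
            ]
            ax.bar(np.arange(3) + j * width, med, width=width, label=rule)
        ax.set_xticks(np.arange(3) + 0.4 - width / 2)
        ax.set_xticklabels(_PERIOD_ORDER)
        ax.set_title(ind)
    for k in range(len(indicators), axes.size):
        axes[k // 3][k % 3].axis("off")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def box_chart(table, path: str | Path) -> None:
    """Box plots from the reported percentiles (80th box, 90th whiskers)."""
    indicators, rules, fig, axes = _grid(table)
    for k, ind in enumerate(indicators):
        ax = axes[k // 3][k % 3]
        sub = table[table["indicator"] == ind]
        stats, positions = [], []
        for i, p in enumerate(_PERIOD_ORDER):
            for j, rule in enumerate(rules):
                row = sub[(sub["rule"] == rule) & (sub["period"] == p)]
                if row.empty or row["lo90"].isna().all():
                    continue
                r = row.iloc[0]
                stats.append(
                    {
                        "med": r["median"],
                        "q1": r["lo80"],
                        "q3": r["hi80"],
                        "whislo": r["lo90"],
                        "whishi": r["hi90"],
                        "label": rule,
                    }
                )
                positions.append(i * (len(rules) + 1) + j)
        if stats:
            ax.bxp(stats, positions=positions, showfliers=False)
        ax.set_xticks([i * (len(rules) + 1) + (len(rules) - 1) / 2 for i in range(3)])
        ax.set_xticklabels(_PERIOD_ORDER)
        ax.set_title(ind)
    for k in range(len(indicators), axes.size):
        axes[k // 3][k % 3].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
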