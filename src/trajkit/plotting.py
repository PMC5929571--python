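"""Presentation helpers (excluded from numeric testing)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_group_medians(medians: dict, path: str | Path) -> Path:
    """Median time-course panels (speed, P, D, Q_d) per selected group."""
    quantities = ["speed", "P", "D", "Q_d"]
    fig, axes = plt.subplots(len(quantities), 1, figsize=(7, 10), sharex=True)
    for ax, q in zip(axes, quantities):
        for grp, agg in medians.items():
            if q in agg:
                ax.plot(agg.index, agg[q], label=grp)
        ax.set_ylabel(q)
        ax.axhline(0.0, color="0.8", lw=0.8, zorder=0)
    axes[0].legend(loc="best", fontsize=8)
    axes[-1].set_xlabel("frame")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
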