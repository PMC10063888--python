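"""Optional figures (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agreement import AgreementSummary, PairedSeries, bland_altman


def bland_altman_plot(s: PairedSeries, path, summary: AgreementSummary | None = None,
                      title: str = "", units: str = ""):
    """Scatter of differences against pairwise means, with the mean
    difference and the limits of agreement drawn as horizontal lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = summary if summary is not None else bland_altman(s)
    mean_xy = (s.x + s.y) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean_xy, s.differences, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(ba.mean_diff, color="k", lw=1.2, label=f"md = {ba.mean_diff:.3g}")
    for loa in (ba.upper_loa, ba.lower_loa):
        ax.axhline(loa, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"mean of methods {('(' + units + ')') if units else ''}".strip())
    ax.set_ylabel(f"difference {('(' + units + ')') if units else ''}".strip())
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
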