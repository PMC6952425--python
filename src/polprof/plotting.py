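"""Minimal profile plotting."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metagene import MetageneProfile

__all__ = ["plot_metagene"]


def plot_metagene(profiles: dict[str, MetageneProfile], out: str | None = None, title: str = ""):
    """Overlay set-mean enrichment profiles, one line per condition/set."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, prof in profiles.items():
        ax.plot(prof.bin_labels, prof.mean, label=label)
        ax.fill_between(
            prof.bin_labels, prof.mean - prof.se, prof.mean + prof.se, alpha=0.2
        )
    ax.set_xlabel("position relative to anchor (bp)")
    ax.set_ylabel("fold enrichment over input")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
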