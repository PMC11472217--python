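"""Profile plots mirroring the standard laminar-fMRI figure layout."""

from __future__ import annotations

import numpy as np

from .profiles import DepthProfile

__all__ = ["plot_depth_profiles"]


def plot_depth_profiles(profiles: dict[str, DepthProfile], path=None):
    """Group mean +- SEM of each profile against cortical depth bin.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(profiles)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    for ax, (name, prof) in zip(axes[0], profiles.items()):
        x = np.arange(1, len(prof.bins) + 1)
        center = prof.group_center()
        n_ok = np.isfinite(prof.values).sum(axis=0)
        sem = np.where(
            n_ok > 1, np.sqrt(np.nanvar(prof.values, axis=0, ddof=1)) / np.sqrt(np.maximum(n_ok, 1)), np.nan
        )
        ax.errorbar(x, center, yerr=sem, marker="o", capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels(prof.bins, rotation=60, fontsize=7)
        ax.set_title(name, fontsize=9)
        ax.set_ylabel(prof.units, fontsize=8)
        ax.set_xlabel("depth bin (deep to superficial)", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
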