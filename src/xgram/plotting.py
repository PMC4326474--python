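"""Basic profile plots (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_class_profiles(class_profiles: dict, ax=None, relative_positions=True):
    """Mean transcriptogram per condition with an SE band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, cp in class_profiles.items():
        n = len(cp.mean)
        x = np.arange(n) / max(n - 1, 1) if relative_positions else np.arange(1, n + 1)
        ax.plot(x, cp.mean, label=cond, lw=1)
        ax.fill_between(x, cp.mean - cp.se, cp.mean + cp.se, alpha=0.3)
    ax.set_xlabel("relative gene position" if relative_positions else "gene position")
    ax.set_ylabel("transcriptogram (log2 expression)")
    ax.legend()
    return ax


def plot_comparison(results, ax=None, relative_positions=True):
    """Per-position -log10 P with the Bonferroni and 0.01 lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    p = results.frame["p"].to_numpy()
    n = len(p)
    x = np.arange(n) / max(n - 1, 1) if relative_positions else np.arange(1, n + 1)
    with np.errstate(divide="ignore"):
        ax.plot(x, -np.log10(p), lw=0.8, color="k")
    ax.axhline(-np.log10(0.01), color="0.3", ls="--", label="P = 0.01")
    ax.axhline(
        -np.log10(results.bonferroni_threshold),
        color="tab:blue",
        ls="--",
        label=f"Bonferroni {results.family_alpha}",
    )
    ax.set_xlabel("relative gene position" if relative_positions else "gene position")
    ax.set_ylabel("-log10 P")
    ax.legend()
    return ax
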