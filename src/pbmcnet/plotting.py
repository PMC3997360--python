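"""Plotting conveniences (not part of the analysis contract)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def radial_plot(percent: pd.Series, ax=None, reference_level: float = 100.0):
    """Radial (polar) percent-of-median profile for one subject.

    The reference population level (100 %) is drawn as a circle; the
    subject's per-gene percentages as a closed red trace.
    """
    genes = list(percent.index)
    theta = np.linspace(0, 2 * np.pi, len(genes), endpoint=False)
    vals = percent.to_numpy(dtype=float)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    closed_t = np.concatenate([theta, theta[:1]])
    ax.plot(closed_t, np.concatenate([vals, vals[:1]]), color="tab:red", lw=1.2)
    ax.plot(closed_t, np.full(len(closed_t), reference_level),
            color="tab:blue", lw=1.0)
    ax.set_xticks(theta)
    ax.set_xticklabels(genes, fontsize=5)
    ax.set_title(percent.name or "", fontsize=8)
    return ax


def ck_scatter(points: dict[str, tuple[int, float]], ax=None, label=None):
    """Scatter of clustering coefficient C(k) against degree k (log-log)."""
    if ax is None:
        _, ax = plt.subplots()
    ks = [k for k, _ in points.values()]
    cs = [c for _, c in points.values()]
    ax.scatter(ks, cs, s=18, label=label)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("degree k")
    ax.set_ylabel("clustering coefficient C(k)")
    if label:
        ax.legend()
    return ax
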