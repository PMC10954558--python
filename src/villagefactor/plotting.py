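"""Small plotting helpers (matplotlib is an optional dependency)."""

from __future__ import annotations

import numpy as np

__all__ = ["qq_plot", "score_vs_age_plot"]


def qq_plot(p_values, ax=None, label=None):
    """Quantile-quantile plot of -log10 p-values against the uniform null,
    the standard way to display per-factor association statistics."""
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(n) + 0.5) / n)
    observed = -np.log10(p)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(expected, observed, s=16, label=label)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    if label:
        ax.legend()
    return ax


def score_vs_age_plot(scores, ages, ax=None):
    """Scatter of (quantile-normalized) donor factor scores against age
    with an OLS trend line."""
    import matplotlib.pyplot as plt

    x = np.asarray(ages, dtype=float)
    y = np.asarray(scores, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(x, y, s=16, alpha=0.7)
    b, a = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, a + b * xs, c="crimson", lw=2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("factor score")
    return ax
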