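"""Convenience plotting: fitted-cdf overlay against the empirical cdf.

Requires matplotlib (the ``plot`` extra); imported lazily so the rest of
the package works without it.
"""

from __future__ import annotations

import numpy as np

from .core import ParamVector, Sample, gmoee_cdf


def cdf_overlay(sample: Sample, fitted: dict[str, "ParamVector | callable"],
                ax=None, npoints: int = 400):
    """Overlay fitted cdfs on the empirical cdf of a sample.

    ``fitted`` maps a label to a ParamVector (drawn as a GMO-EE cdf) or
    any callable ``x -> F(x)``.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = sample.sorted_values
    ax.step(xs, np.arange(1, sample.n + 1) / sample.n, where="post",
            color="k", lw=1.2, label="empirical")
    grid = np.linspace(0.0, xs[-1] * 1.05, npoints)
    for label, model in fitted.items():
        if isinstance(model, ParamVector):
            y = np.asarray(gmoee_cdf(grid, model))
        else:
            y = np.asarray(model(grid))
        ax.plot(grid, y, lw=1.0, label=label)
    ax.set_xlabel(sample.label or "x")
    ax.set_ylabel("F(x)")
    ax.legend()
    return ax
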