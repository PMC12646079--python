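"""Plot helpers for metric curves and permutation nulls (matplotlib)."""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .graphs import MetricCurve


def plot_metric_curves(curves: Iterable[MetricCurve], ax=None,
                       label_by: str = "timepoint"):
    """Overlay metric-vs-sparsity curves; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.sparsity_levels, c.values, alpha=0.6,
                label=getattr(c, label_by, None))
    first = next(iter(curves), None)
    ax.set_xlabel("sparsity (%)")
    if first is not None:
        ax.set_ylabel(first.metric)
    return ax


def plot_permutation_null(null_values: np.ndarray, observed: float, ax=None):
    """Histogram of a permutation null with the observed statistic marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(np.asarray(null_values), bins=30, color="0.7")
    ax.axvline(observed, color="crimson", label="observed")
    ax.set_xlabel("permutation statistic")
    ax.legend()
    return ax
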