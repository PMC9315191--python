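"""Optional plotting helpers (require the ``plot`` extra).

These are conveniences around the package's outputs; the Kaplan–Meier
panel in particular is a standard nonparametric estimator provided only
for eyeballing between-cluster variability, not part of the model.
"""

from __future__ import annotations

import numpy as np

from .data import ClusteredDataset
from .diagnostics import GradientCurve


def _pyplot():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib; install the 'plot' extra"
        ) from exc
    return plt


def plot_gradient(curve: GradientCurve, ax=None):
    """Gradient-function diagnostic with its reference level and bands."""
    plt = _pyplot()
    ax = ax or plt.gca()
    ax.plot(curve.grid, curve.delta, color="C0", label=r"$\Delta(G,u)$")
    if curve.band_lower is not None:
        ax.fill_between(
            curve.grid, curve.band_lower, curve.band_upper,
            alpha=0.25, color="C0", label="95% band",
        )
    ax.axhline(curve.threshold, color="k", ls="--", lw=1)
    ax.set_xlabel("random effect u")
    ax.set_ylabel("gradient function")
    ax.legend()
    return ax


def plot_cluster_survival(data: ClusteredDataset, ax=None, max_clusters=None):
    """Kaplan–Meier survival curves per cluster."""
    plt = _pyplot()
    try:
        from lifelines import KaplanMeierFitter
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the cluster survival plot requires lifelines; "
            "install the 'plot' extra"
        ) from exc
    ax = ax or plt.gca()
    labels = np.asarray(data.cluster_labels)
    for i in range(data.r if max_clusters is None else min(data.r, max_clusters)):
        rows = data.cluster == i
        km = KaplanMeierFitter()
        km.fit(data.time[rows], event_observed=data.status[rows])
        km.plot_survival_function(ax=ax, ci_show=False, legend=False, lw=1)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(f"Kaplan–Meier by cluster (r={data.r})")
    return ax
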