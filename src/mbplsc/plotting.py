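"""Basic diagnostic plots for fitted models and resampling results."""

from __future__ import annotations

import numpy as np


def plot_saliences(results, component: int, ax=None):
    """Bar plot of per-group GM saliences and shared WM saliences for one LV."""
    import matplotlib.pyplot as plt

    mb = results.multiblock
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    offset = 0
    width = 0.8 / max(len(mb.groups), 1)
    x = np.arange(mb.p)
    for i, g in enumerate(mb.groups):
        sal = results.gm_saliences(g).to_numpy()[:, component]
        ax.bar(x + i * width, sal, width=width, label=f"GM {g}")
    xw = np.arange(mb.q) + mb.p + 2
    ax.bar(xw, results.wm_saliences().to_numpy()[:, component], width=0.8,
           color="grey", label="WM (shared)")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("salience")
    ax.set_title(f"LV{component + 1} saliences")
    ax.legend(fontsize=8)
    return ax


def plot_convergence(trajectory, component: int, ax=None):
    """Mean |Δsalience| as a function of per-group sample size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mean = trajectory.mean_trajectory(component)
    ax.plot(mean.index, mean.to_numpy())
    ax.set_xlabel("n per group")
    ax.set_ylabel("mean |salience(n+1) - salience(n)|")
    ax.set_title(f"LV{component + 1} salience convergence")
    return ax


def plot_permutation_null(perm_result, ax=None):
    """Histogram of the permutation null inertia with the observed value."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(perm_result.null_inertia, bins=40, color="steelblue", alpha=0.8)
    ax.axvline(perm_result.observed_inertia, color="crimson",
               label=f"observed (p={perm_result.omnibus_p:.4g})")
    ax.set_xlabel("total inertia")
    ax.legend()
    return ax
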