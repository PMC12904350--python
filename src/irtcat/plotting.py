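"""Diagnostic plots for cohort simulation results.

Each function takes a :class:`~irtcat.simulate.CATSimulationResults` and an
optional matplotlib Axes; all return the Axes for further styling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_correlation_curve",
    "plot_se_by_length",
    "plot_se_reduction",
    "plot_theta_hist",
]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_correlation_curve(results, ax=None, static_r: float | None = None, **kwargs):
    """Correlation between length-k CAT thetas and full-length thetas.

    ``static_r`` draws a horizontal reference line for a fixed short form.
    """
    ax = _get_ax(ax)
    curve = results.correlation_curve()
    ax.plot(curve["k"], curve["r"], marker="o", **kwargs)
    if static_r is not None:
        ax.axhline(static_r, linestyle="--", color="grey", label="static short form")
        ax.legend()
    ax.set_xlabel("CAT length (items)")
    ax.set_ylabel("r with full-length theta")
    ax.set_ylim(None, 1.005)
    return ax


def plot_se_by_length(results, ax=None, **kwargs):
    """Distribution of interim SEs as a function of test length (boxplots)."""
    ax = _get_ax(ax)
    trace = results.interim_frame()
    steps = sorted(trace["step"].unique())
    data = [trace.loc[trace["step"] == s, "se"].to_numpy() for s in steps]
    ax.boxplot(data, positions=steps, **kwargs)
    ax.axhline(results.config.se_threshold, linestyle="--", color="grey")
    ax.set_xlabel("items administered")
    ax.set_ylabel("SE of theta")
    return ax


def plot_se_reduction(results, ax=None, delta: float = 0.01, **kwargs):
    """Share of continuing respondents whose SE dropped by more than delta."""
    ax = _get_ax(ax)
    tab = results.se_reduction(delta)
    ax.bar(tab["step"], tab["prop_reduction_gt_delta"], **kwargs)
    ax.set_xlabel("items already taken")
    ax.set_ylabel(f"proportion with SE reduction > {delta:g}")
    ax.set_ylim(0, 1)
    return ax


def plot_theta_hist(results, ax=None, bins=30, **kwargs):
    """Histogram of final CAT theta estimates."""
    ax = _get_ax(ax)
    th = results.thetas
    ax.hist(th, bins=bins, **kwargs)
    ax.set_xlabel("final theta")
    ax.set_ylabel("respondents")
    ax.set_title(f"mean {np.mean(th):.3f}, SD {np.std(th):.3f}")
    return ax
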