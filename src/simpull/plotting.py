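"""Small plotting helpers: trace fit overlays and distribution bars."""

from __future__ import annotations

import numpy as np

from .oligomer import OligomerDistribution
from .stepfit import StepFitResult
from .trace import Trace

__all__ = ["plot_trace_fit", "plot_distribution"]


def plot_trace_fit(trace: Trace, fit: StepFitResult, ax=None):
    """Overlay the fitted staircase on the raw trace."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    t = np.arange(len(trace)) * trace.frame_interval
    ax.plot(t, trace.intensities, lw=0.7, color="0.6", label="trace")
    ax.plot(t, fit.fitted(len(trace)), lw=1.8, color="C3",
            label=f"{fit.step_count} steps")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (counts)")
    ax.set_title(trace.spot_id)
    ax.legend(frameon=False)
    return ax


def plot_distribution(dist: OligomerDistribution, ax=None, cap: int = 6, **bar_kw):
    """Normalized step-count frequency bars (bins beyond ``cap`` pooled)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    s = dist.pooled(cap)
    ax.bar(range(len(s)), s.values, **bar_kw)
    ax.set_xticks(range(len(s)), s.index)
    ax.set_xlabel("photobleaching steps")
    ax.set_ylabel("normalized frequency")
    ax.set_title(f"{dist.condition} (N={dist.n_traces})")
    return ax
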