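"""Diagnostic plots: cursor trajectories and ramp/threshold panels."""
from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .engine import TargetGeometry, TrialRecord
from .core import ForceTrace
from .recruitment import ThresholdEstimate

__all__ = ["plot_trial", "plot_ramp"]


def plot_trial(trial: TrialRecord, geoms: Dict[str, TargetGeometry], ax=None):
    """Cursor trajectory of one trial in normalised-rate space."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for tid, g in geoms.items():
        circ = plt.Circle(g.center, g.radius, fill=False,
                          color="tab:blue" if tid == trial.target_id else "0.6")
        ax.add_patch(circ)
        ax.annotate(tid, g.center, textcoords="offset points", xytext=(4, 4))
    pos = trial.positions
    ax.plot(pos[:, 0], pos[:, 1], "-", color="0.3", lw=0.8)
    ax.scatter(pos[:, 0], pos[:, 1], c=np.arange(len(pos)), cmap="Greys", s=6)
    ax.set_xlabel("normalised rate MU1")
    ax.set_ylabel("normalised rate MU2")
    ax.set_title(f"{trial.target_id}: {trial.outcome}")
    ax.set_aspect("equal")
    ax.set_xlim(-0.2, 1.4)
    ax.set_ylim(-0.2, 1.4)
    return ax


def plot_ramp(force: ForceTrace, estimates: Sequence[ThresholdEstimate],
              ax=None):
    """Ramp force with per-unit recruitment (green) and de-recruitment
    (red) event markers."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(force.times, force.values, color="0.6", lw=1)
    for e in estimates:
        ax.plot(e.t_on, e.f_on, "g^", ms=4)
        if e.t_off is not None and e.f_off is not None:
            ax.plot(e.t_off, e.f_off, "rv", ms=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("force (%MVC)")
    return ax
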