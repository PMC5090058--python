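"""Score-profile plotting for scan trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .analysis import ChangeFlags, StepMetrics

__all__ = ["plot_score_profile"]


def plot_score_profile(
    series: dict[str, tuple[list[StepMetrics], list[ChangeFlags] | None]],
    ax: "plt.Axes | None" = None,
):
    """Best score vs. scan step for one or more ligands.

    ``series`` maps a ligand label to ``(metrics, flags)``; steps with a
    significant pose change are drawn filled, unchanged (plateau) steps
    hollow, echoing the standard presentation of scan profiles.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, (metrics, flags) in series.items():
        steps = [m.step_index for m in metrics]
        scores = [m.best_score for m in metrics]
        (line,) = ax.plot(steps, scores, "-", label=label)
        if flags is not None:
            sig = {f.step_index for f in flags if f.significant}
            filled = [(s, v) for s, v in zip(steps, scores) if s in sig]
            hollow = [(s, v) for s, v in zip(steps, scores) if s not in sig]
            if filled:
                ax.plot(*zip(*filled), "o", color=line.get_color())
            if hollow:
                ax.plot(*zip(*hollow), "o", markerfacecolor="white",
                        color=line.get_color())
    ax.set_xlabel("scan step")
    ax.set_ylabel("best docking score")
    ax.legend()
    return ax
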