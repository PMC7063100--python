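"""Learning-curve panels: Q(A), Q(B), and P(A) against trial number."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .simulator import Ensemble, Trajectory


def plot_learning_curves(
    run: Trajectory | Ensemble,
    path: Optional[str | Path] = None,
    title: Optional[str] = None,
):
    """Three stacked panels: value of random looking, value of gaze
    following, probability of random looking. For an ensemble the cross-seed
    mean is drawn with a +-1 sd band. Returns the matplotlib Figure; saves
    to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(run, Ensemble):
        qr, qf = run.mean_q_random, run.mean_q_follow
        pr = 1.0 - run.mean_p_follow
        bands = (run.sd_q_random, run.sd_q_follow, run.sd_p_follow)
    else:
        qr, qf, pr = run.q_random, run.q_follow, run.p_random
        bands = None

    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True)
    trials = range(len(qr))
    panels = [
        (qr, "Q(A) random looking"),
        (qf, "Q(B) gaze following"),
        (pr, "P(A) random looking"),
    ]
    for k, (ax, (y, label)) in enumerate(zip(axes, panels)):
        ax.plot(trials, y, lw=1.0)
        if bands is not None:
            ax.fill_between(
                trials, y - bands[k], y + bands[k], alpha=0.25, linewidth=0
            )
        ax.set_ylabel(label)
        ax.set_ylim(0, None)
    axes[-1].set_xlabel("trial")
    if title:
        axes[0].set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
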