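"""Optional trial-overlay plot: per-session curves with mean +- 2 sd bands.

Requires matplotlib (installed via the ``plot`` extra).
"""

from __future__ import annotations

import numpy as np

from .generator import StrideTrial

__all__ = ["plot_session_overlay"]


def plot_session_overlay(
    trials: list[StrideTrial],
    channel: str = "grf_right_vertical",
    sessions: tuple[str, ...] | None = None,
):
    """One panel per session: that session's trial curves (grey) over the
    global mean (solid) and +- 2 sd envelope (dotted) of all trials."""
    import matplotlib.pyplot as plt

    if sessions is None:
        sessions = tuple(dict.fromkeys(tr.session_id for tr in trials))
    curves = np.stack([tr.curves[channel] for tr in trials])
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0)
    x = np.linspace(0, 100, curves.shape[1])

    fig, axes = plt.subplots(
        2, (len(sessions) + 1) // 2, figsize=(3 * len(sessions) / 2 + 2, 6),
        sharex=True, sharey=True,
    )
    for ax, session in zip(np.ravel(axes), sessions):
        for tr in trials:
            if tr.session_id == session:
                ax.plot(x, tr.curves[channel], color="0.6", lw=0.6)
        ax.plot(x, mean, color="forestgreen", lw=1.5)
        ax.plot(x, mean + 2 * sd, color="forestgreen", lw=1.0, ls=":")
        ax.plot(x, mean - 2 * sd, color="forestgreen", lw=1.0, ls=":")
        ax.set_title(session)
        ax.set_xlabel("% stride")
    np.ravel(axes)[0].set_ylabel(channel)
    fig.tight_layout()
    return fig
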