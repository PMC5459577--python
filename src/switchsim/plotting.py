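"""Minimal per-scenario figures: state populations and on/off ratio."""

from __future__ import annotations

from pathlib import Path


def plot_scenario(result, path: str | Path, top_n: int = 8) -> None:
    """Population traces of the most-populated states plus the on/off ratio."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    traj = result.trajectory
    fig, (ax0, ax1) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    peak = traj.populations.max(axis=1)
    for i in np.argsort(peak)[::-1][:top_n]:
        ax0.plot(traj.times, traj.populations[i], label=traj.state_ids[i])
    ax0.set_ylabel("population")
    ax0.set_title(result.name)
    ax0.legend(fontsize=7, ncol=2)
    ratio = np.array(result.ratio, dtype=float)
    finite = np.isfinite(ratio)
    ax1.plot(traj.times[finite], ratio[finite])
    ax1.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax1.set_yscale("log")
    ax1.set_xlabel("time since position 75 (s)")
    ax1.set_ylabel("P(on) / P(off)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
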