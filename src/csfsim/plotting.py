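"""Matplotlib glue: quick-look figures for runs and compliance fits."""

from __future__ import annotations

from pathlib import Path

from .network import TimeSeriesResult
from .windkessel import ComplianceFit


def plot_timeseries(result: TimeSeriesResult, path: str | Path | None = None):
    """Three stacked panels: node pressures, conduit flows, outlet flows."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    for name in result.node_names:
        axes[0].plot(result.time, result.pressure(name), label=name)
    axes[0].set_ylabel("pressure (mmHg)")
    for name in result.conduit_names:
        axes[1].plot(result.time, result.conduit_flow(name), label=name)
    axes[1].set_ylabel("conduit flow (ml/s)")
    for name in result.outlet_names:
        axes[2].plot(result.time, result.outlet_flow(name), label=name)
    axes[2].set_ylabel("outlet flow (ml/s)")
    axes[2].set_xlabel("time (s)")
    for ax in axes:
        ax.legend(loc="upper right", fontsize="small")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_tuning_curve(fit: ComplianceFit, path: str | Path | None = None):
    """Amplitude-versus-compliance curve with the fitted crossing marked."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(fit.grid, fit.amplitudes, "k-", lw=1)
    ax.axhline(fit.target_amplitude, color="r", lw=1)
    ax.axvline(fit.c_tot, color="b", ls="--", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("total compliance (ml/mmHg)")
    ax.set_ylabel("pressure pulsation amplitude (mmHg)")
    ax.set_title(f"fitted C_tot = {fit.c_tot:.4f} ml/mmHg")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
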