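"""Optional diagnostic plots (never part of any computed result)."""

from __future__ import annotations

import numpy as np


def _axes(path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    return fig, ax, plt


def plot_vulnerability(series, fit, path) -> None:
    """Observed PLC points and the fitted logistic curve."""
    from .vulnerability import logistic_plc

    fig, ax, plt = _axes(path)
    for s in series:
        ax.plot(s.tensions, s.plc, "o", alpha=0.5, label=s.stem_id)
    psi = np.linspace(min(min(s.tensions) for s in series), 0.0, 200)
    if fit.converged:
        ax.plot(psi, logistic_plc(psi, fit.p50, fit.slope_a), "k-")
        ax.axvline(fit.p50, ls="--", c="grey")
    ax.set_xlabel("xylem pressure (MPa)")
    ax.set_ylabel("PLC (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pv_diagnostic(curve, ws, line, path) -> None:
    """(RWD, 1/psi) plane with the fitted osmotic line."""
    from .pressure_volume import relative_water_content

    fig, ax, plt = _axes(path)
    masses = np.asarray(curve.fresh_masses)
    psis = np.asarray(curve.psis)
    ok = psis < 0
    rwd = 1.0 - relative_water_content(masses[ok], curve.dry_mass, ws)
    ax.plot(rwd, 1.0 / psis[ok], "o")
    xs = np.linspace(0.0, rwd.max(), 50)
    ax.plot(xs, line.intercept + line.slope * xs, "k-")
    ax.set_xlabel("relative water deficit")
    ax.set_ylabel("1 / psi (MPa$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trajectory(traj, path) -> None:
    """Accumulated PLC band over the season."""
    fig, ax, plt = _axes(path)
    ax.fill_between(traj.days, traj.plc_min, traj.plc_max, color="0.8")
    ax.plot(traj.days, traj.plc_mean, "k-")
    ax.set_xlabel("day of year")
    ax.set_ylabel("accumulated PLC (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
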