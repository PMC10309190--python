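"""Publication-style plots for the standard outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .beads import BindingFit, one_site

__all__ = ["plot_cohort", "plot_retention", "plot_titration", "plot_mass_histogram"]


def plot_cohort(cohort_df, out_path, per_experiment=None):
    """Mean +/- SEM trace per condition, thin lines for each experiment."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cond, grp in cohort_df.groupby("condition"):
        line, = ax.plot(grp["t_s"] / 60, grp["mean"], lw=2, label=cond)
        if grp["sem"].notna().any():
            ax.fill_between(
                grp["t_s"] / 60,
                grp["mean"] - grp["sem"],
                grp["mean"] + grp["sem"],
                alpha=0.25,
                color=line.get_color(),
            )
    if per_experiment:
        for t, v in per_experiment:
            ax.plot(np.asarray(t) / 60, v, lw=0.6, color="gray", alpha=0.6)
    ax.set_xlabel("time after engulfment (min)")
    ax.set_ylabel("fold enrichment")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_retention(curve, out_path, per_event_intervals=None, t_max_s=None):
    """Thick proportion-positive line with thin per-event bars."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if per_event_intervals:
        for k, ivs in enumerate(per_event_intervals):
            for t0, t1 in ivs:
                ax.plot([t0 / 60, t1 / 60], [1.02 + 0.02 * k] * 2, color="gray", lw=1)
    ax.step(
        curve.bin_starts / 60,
        curve.proportions,
        where="post",
        lw=2.5,
        color="k",
    )
    ax.set_ylim(-0.02, None)
    ax.set_xlabel("time after engulfment (min)")
    ax.set_ylabel("proportion positive")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_titration(points_df, fit: BindingFit, out_path):
    """Per-concentration mean +/- SD with the fitted saturation curve."""
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    g = points_df.groupby("conc")["intensity"]
    ax.errorbar(g.mean().index, g.mean(), yerr=g.std(), fmt="o", ms=4, capsize=3)
    cgrid = np.linspace(0, points_df["conc"].max() * 1.05, 200)
    ax.plot(cgrid, one_site(cgrid, fit.kd, fit.bmax, fit.nonspecific), "r-", lw=1.5)
    label = f"apparent Kd = {fit.kd:.1f}"
    if fit.kd_error is not None:
        label += f" ± {fit.kd_error:.1f}"
    ax.set_title(label + " nM", fontsize=9)
    ax.set_xlabel("probe concentration (nM)")
    ax.set_ylabel("bead intensity (a.u.)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_mass_histogram(masses, components, out_path, bin_kd=4.0):
    """Event-mass histogram with the fitted Gaussian mixture overlaid."""
    from scipy.stats import norm

    masses = np.asarray(masses, float)
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    bins = np.arange(masses.min(), masses.max() + bin_kd, bin_kd)
    ax.hist(masses, bins=bins, color="0.7", density=True)
    grid = np.linspace(masses.min(), masses.max(), 400)
    total = np.zeros_like(grid)
    for c in components:
        pdf = c.fraction * norm.pdf(grid, c.mean, c.sd)
        total += pdf
        ax.plot(grid, pdf, lw=1, ls="--")
    ax.plot(grid, total, "r-", lw=1.5)
    ax.set_xlabel("apparent mass (kD)")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
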