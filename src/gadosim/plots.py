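"""Figure generation for study outputs.

All figures are rebuilt from the exported tables (never from in-memory
state alone) so that any archived study directory can be re-plotted.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_profile_envelope",
    "plot_gmr_forest",
    "plot_gfr_cl",
    "plot_urine_recovery",
]


def plot_profile_envelope(profiles: pd.DataFrame, title: str, path,
                          q_low: float = 0.05, q_high: float = 0.95) -> None:
    """Semi-log mean concentration-time profile with a percentile band."""
    wide = profiles.pivot(index="subject_id", columns="time_h", values="conc_mg_per_l")
    times = wide.columns.to_numpy(dtype=float)
    m = wide.to_numpy()
    mean = m.mean(axis=0)
    lo = np.quantile(m, q_low, axis=0)
    hi = np.quantile(m, q_high, axis=0)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(times, lo, hi, alpha=0.3, label=f"{q_low:.0%}-{q_high:.0%} band")
    ax.plot(times, mean, lw=1.5, label="mean")
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (mg/L)")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gmr_forest(comparison: pd.DataFrame, path,
                    bounds: tuple[float, float] = (0.8, 1.2)) -> None:
    """Forest plot of GMR +/- 95% CI per (parameter, cohort)."""
    df = comparison.dropna(subset=["p_adj"]).copy()
    params = list(df["parameter"].unique())
    fig, axes = plt.subplots(
        1, len(params), figsize=(3.2 * len(params), 0.45 * df["cohort"].nunique() + 2),
        sharey=True,
    )
    if len(params) == 1:
        axes = [axes]
    for ax, param in zip(axes, params):
        sub = df[df["parameter"] == param]
        y = np.arange(len(sub))
        ax.errorbar(
            sub["gmr"], y,
            xerr=[sub["gmr"] - sub["ci_low"], sub["ci_high"] - sub["gmr"]],
            fmt="o", capsize=3,
        )
        for b in bounds:
            ax.axvline(b, ls="--", color="grey", lw=0.8)
        ax.axvline(1.0, color="k", lw=0.8)
        ax.set_yticks(y, sub["cohort"])
        ax.set_title(param)
        ax.set_xlabel("GMR vs control")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gfr_cl(subjects: pd.DataFrame, path) -> None:
    """GFR vs observed clearance across all subjects, with fitted line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cohort, sub in subjects.groupby("cohort"):
        ax.scatter(sub["gfr"], sub["cl_obs"], s=10, alpha=0.6, label=cohort)
    x = subjects["gfr"].to_numpy()
    y = subjects["cl_obs"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    xs = np.linspace(x.min(), x.max(), 50)
    r = np.corrcoef(x, y)[0, 1]
    ax.plot(xs, slope * xs + intercept, "k-", lw=1,
            label=f"fit (r = {r:.3f})")
    ax.set_xlabel("GFR (mL/min)")
    ax.set_ylabel("systemic CL (L/h)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_urine_recovery(profiles_by_cohort: dict[str, pd.DataFrame], path) -> None:
    """Mean cumulative urinary recovery (mg) over time per cohort."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cohort, profiles in profiles_by_cohort.items():
        mean = profiles.groupby("time_h")["urine_cum_mg"].mean()
        ax.plot(mean.index, mean.to_numpy(), label=cohort, lw=1.2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("cumulative amount in urine (mg)")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
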