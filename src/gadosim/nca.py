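"""Non-compartmental analysis of a single concentration-time profile.

NCA is deliberately model-blind: it consumes only the observed
(times, concentrations, cumulative urine, dose, body weight) and reports
the standard exposure metrics.  Conventions: linear trapezoidal AUC;
terminal slope (lambda_z) from a log-linear least-squares fit over the
final 24 h of the profile; AUC(0-inf) = AUC(0-last) + C_last / lambda_z;
CL = dose / AUC(0-inf).  The reported "AUC" of the study tables is
AUC(0-inf); AUC(0-last) is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .engine import ConcentrationProfile, fraction_excreted
from .errors import FitError, GridError

__all__ = [
    "NCASummary",
    "auc_trapezoid",
    "lambda_z_fit",
    "biexp_fit",
    "nca_summary",
]

#: Width of the default terminal-slope window (h), measured back from the
#: end of the profile; safely past the ~0.5-h distribution phase.
LAMBDA_Z_WINDOW_H = 24.0


@dataclass(frozen=True)
class NCASummary:
    """Per-subject NCA metrics in the units of the study tables."""

    cmax: float  # mg/L
    tmax: float  # h
    auc_last: float  # mg*h/L, 0 to last sample
    auc_inf: float  # mg*h/L, extrapolated to infinity
    lambda_z: float  # 1/h
    t_half_elim_obs: float  # h, ln2/lambda_z
    t_half_dist_obs: float  # h, fast phase of the bi-exponential fit
    cl_obs: float  # L/h, dose / auc_inf
    cl_per_kg: float  # mL/h/kg
    fe_72: float  # fraction of dose in urine by 72 h
    c_at_1h: float  # mg/L


def auc_trapezoid(times, conc, upto: float) -> float:
    """Linear-trapezoid AUC of (times, conc) truncated at `upto` hours.

    `upto` must lie within the sampled range; the last partial interval
    is handled by linear interpolation.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if upto < t[0] or upto > t[-1]:
        raise GridError(f"upto={upto} outside sampled range [{t[0]}, {t[-1]}]")
    if upto == t[0]:
        return 0.0
    mask = t <= upto
    tt = t[mask]
    cc = c[mask]
    if tt[-1] < upto:
        c_up = float(np.interp(upto, t, c))
        tt = np.append(tt, upto)
        cc = np.append(cc, c_up)
    return float(np.trapezoid(cc, tt))


def lambda_z_fit(times, conc, window: tuple[float, float] | None = None):
    """Terminal log-linear rate constant and half-life.

    Ordinary least squares of ln(C) on t over `window` (default: the last
    24 h of the profile).  Requires >= 3 strictly positive concentrations
    in the window.

    Returns
    -------
    (lambda_z, t_half) : 1/h, h
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if window is None:
        window = (t[-1] - LAMBDA_Z_WINDOW_H, t[-1])
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise FitError(
            f"terminal fit needs >= 3 points in window [{lo}, {hi}], "
            f"got {int(mask.sum())}"
        )
    cw = c[mask]
    if np.any(cw <= 0):
        raise FitError("terminal fit window contains non-positive concentrations")
    slope, _ = np.polyfit(t[mask], np.log(cw), 1)
    lam = -slope
    if lam <= 0:
        raise FitError(f"terminal slope is non-negative (lambda_z={lam:.3g})")
    return float(lam), float(np.log(2.0) / lam)


def _strip_initial_guess(t, c):
    """Curve-stripping initial values for the bi-exponential fit."""
    lam_z, _ = lambda_z_fit(t, c)
    # back-extrapolate the terminal line to t=0
    mask = t >= t[-1] - LAMBDA_Z_WINDOW_H
    slope, intercept = np.polyfit(t[mask], np.log(c[mask]), 1)
    b0 = np.exp(intercept)
    resid = c - b0 * np.exp(slope * t)
    early = (resid > 0) & (t < t[-1] - LAMBDA_Z_WINDOW_H)
    if early.sum() < 3:
        raise FitError("profile has no resolvable distribution phase")
    sl, ic = np.polyfit(t[early], np.log(resid[early]), 1)
    if sl >= 0:
        raise FitError("stripped distribution phase has non-negative slope")
    return np.exp(ic), -sl, b0, lam_z


def biexp_fit(times, conc):
    """Fit C(t) = A e^{-alpha t} + B e^{-beta t}; return both half-lives.

    Nonlinear least squares on the log scale, initialised by curve
    stripping.  Raises :class:`FitError` if the profile is effectively
    mono-exponential (phases not separable) or the optimiser fails.

    Returns
    -------
    (t_half_dist_obs, t_half_elim_obs) : h, with alpha > beta
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if len(t) < 6:
        raise FitError("bi-exponential fit needs >= 6 points spanning both phases")
    if np.any(c <= 0):
        raise FitError("bi-exponential fit requires positive concentrations")
    a0, al0, b0, be0 = _strip_initial_guess(t, c)

    def log_model(tt, la, lal, lb, lbe):
        # log-sum-exp form with clipped rates: overflow-safe while the
        # optimiser explores extreme log-rate values
        ra = np.exp(np.clip(lal, -30.0, 30.0))
        rb = np.exp(np.clip(lbe, -30.0, 30.0))
        return np.logaddexp(la - ra * tt, lb - rb * tt)

    p0 = np.log([a0, al0, b0, be0])
    try:
        popt, _ = curve_fit(log_model, t, np.log(c), p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - optimiser failure path
        raise FitError(f"bi-exponential fit did not converge: {exc}") from exc
    amp_a, alpha, amp_b, beta = np.exp(popt)
    if alpha < beta:
        alpha, beta = beta, alpha
        amp_a, amp_b = amp_b, amp_a
    total = amp_a + amp_b
    if alpha / beta < 1.05 or amp_a / total < 1e-4 or amp_b / total < 1e-4:
        raise FitError(
            "degenerate bi-exponential fit: phases are not separable "
            f"(alpha={alpha:.4g}, beta={beta:.4g}, A={amp_a:.4g}, B={amp_b:.4g})"
        )
    ln2 = np.log(2.0)
    return float(ln2 / alpha), float(ln2 / beta)


def nca_summary(profile: ConcentrationProfile, weight: float) -> NCASummary:
    """Full NCA of one profile; `weight` (kg) normalises clearance."""
    t = profile.times
    c = profile.conc_plasma
    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_last = auc_trapezoid(t, c, upto=float(t[-1]))
    lam, t_half_elim = lambda_z_fit(t, c)
    auc_inf = auc_last + float(c[-1]) / lam
    cl_obs = profile.dose / auc_inf
    t_half_dist, _ = biexp_fit(t, c)
    fe = fraction_excreted(profile, min(72.0, float(t[-1])))
    c1 = float(np.interp(1.0, t, c)) if t[-1] >= 1.0 else float("nan")
    return NCASummary(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lam,
        t_half_elim_obs=t_half_elim,
        t_half_dist_obs=t_half_dist,
        cl_obs=cl_obs,
        cl_per_kg=cl_obs / weight * 1000.0,
        fe_72=fe,
        c_at_1h=c1,
    )
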