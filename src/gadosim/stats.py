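"""Between-cohort comparison statistics.

All comparisons are against the healthy-volunteer control cohort on the
log scale: one-way ANOVA with Dunnett many-to-one adjusted p-values,
geometric-mean ratios (GMR) with two-sample t confidence intervals, and
a fixed 0.8-1.2 equivalence band on the GMR.  Arithmetic-mean
fold-changes are reported alongside (the study's "AUC fold increase"
figures are ratios of arithmetic means).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError

__all__ = [
    "EQUIVALENCE_BOUNDS",
    "gmr_ci",
    "dunnett_anova",
    "fold_change",
    "significance_stars",
    "compare_cohorts",
]

#: Fixed GMR equivalence band ("GMR +/- 0.2").
EQUIVALENCE_BOUNDS = (0.8, 1.2)

#: Parameters compared between cohorts by default.
COMPARE_PARAMS = ["cmax", "auc_inf", "cl_obs", "fe_72"]


def _validate_positive(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidParameterError(f"{name} needs >= 2 values")
    if np.any(arr <= 0):
        raise InvalidParameterError(f"{name} must be strictly positive for log-scale analysis")
    return arr


def gmr_ci(test_values, control_values, level: float = 0.95):
    """Geometric-mean ratio and its two-sample t confidence interval.

    GMR = exp(mean(ln test) - mean(ln control)); the CI is the pooled-
    variance two-sample t interval on the log difference, back-
    transformed.

    Returns
    -------
    (gmr, ci_low, ci_high)
    """
    x = np.log(_validate_positive(test_values, "test_values"))
    y = np.log(_validate_positive(control_values, "control_values"))
    if not 0 < level < 1:
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    nx, ny = len(x), len(y)
    diff = x.mean() - y.mean()
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    tcrit = sps.t.ppf(0.5 + level / 2.0, df=nx + ny - 2)
    return (
        float(np.exp(diff)),
        float(np.exp(diff - tcrit * se)),
        float(np.exp(diff + tcrit * se)),
    )


def dunnett_anova(
    groups: dict[str, np.ndarray],
    control: str,
    random_state: int | None = 0,
) -> dict[str, float]:
    """Dunnett many-to-one adjusted p-values on log-transformed values.

    Each non-control group is compared with the control under the
    multivariate-t reference distribution of Dunnett's procedure.  Values
    are log-transformed first (PK metrics are analysed on the log scale).

    Returns
    -------
    dict mapping each non-control label to its adjusted p-value.
    """
    if control not in groups:
        raise InvalidParameterError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise InvalidParameterError("need at least two groups")
    logs = {}
    for label, values in groups.items():
        logs[label] = np.log(_validate_positive(values, label))
    labels = [lb for lb in groups if lb != control]
    res = sps.dunnett(
        *[logs[lb] for lb in labels],
        control=logs[control],
        random_state=random_state,
    )
    return {lb: float(p) for lb, p in zip(labels, res.pvalue)}


def anova_log_p(groups: dict[str, np.ndarray]) -> float:
    """Overall one-way ANOVA p-value on log-transformed values."""
    samples = [np.log(_validate_positive(v, lb)) for lb, v in groups.items()]
    return float(sps.f_oneway(*samples).pvalue)


def fold_change(test_values, control_values) -> float:
    """Ratio of arithmetic means, test over control."""
    test = np.asarray(test_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    cm = control.mean()
    if cm <= 0:
        raise InvalidParameterError("control mean must be > 0")
    return float(test.mean() / cm)


def significance_stars(p: float) -> str:
    """The study tables' star convention: */**/*** at 0.05/0.01/0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_cohorts(
    values: dict[str, pd.DataFrame],
    control: str = "healthy",
    params: list[str] | None = None,
    random_state: int | None = 0,
) -> pd.DataFrame:
    """Full between-cohort comparison table.

    Parameters
    ----------
    values : dict label -> per-subject DataFrame containing the PK columns.
    control : control cohort label.
    params : PK columns to compare (default Cmax, AUCinf, CL, fe72).

    Returns
    -------
    DataFrame with one row per (parameter, cohort): n, geometric mean,
    GMR vs control with 95% CI, Dunnett-adjusted p, significance stars,
    the 0.8-1.2 equivalence flag and the arithmetic-mean fold change.
    The control row carries GMR 1 by definition and no p-value.
    """
    if control not in values:
        raise InvalidParameterError(f"control cohort {control!r} missing")
    params = params or COMPARE_PARAMS
    lo, hi = EQUIVALENCE_BOUNDS
    rows = []
    for param in params:
        groups = {lb: df[param].to_numpy() for lb, df in values.items()}
        pvals = dunnett_anova(groups, control=control, random_state=random_state)
        ctrl = groups[control]
        for label, vals in groups.items():
            if label == control:
                gmr, ci_l, ci_h = 1.0, np.nan, np.nan
                p = np.nan
                stars = ""
            else:
                gmr, ci_l, ci_h = gmr_ci(vals, ctrl)
                p = pvals[label]
                stars = significance_stars(p)
            rows.append(
                {
                    "parameter": param,
                    "cohort": label,
                    "n": len(vals),
                    "geo_mean": float(np.exp(np.mean(np.log(vals)))),
                    "gmr": gmr,
                    "ci_low": ci_l,
                    "ci_high": ci_h,
                    "p_adj": p,
                    "stars": stars,
                    "equivalent": bool(lo <= gmr <= hi),
                    "fold_change": fold_change(vals, ctrl),
                }
            )
    return pd.DataFrame(rows)
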