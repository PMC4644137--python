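"""Contrast-agent parameters and the two-compartment structural model.

Gadofosveset is a gadolinium-based blood-pool contrast agent that binds
reversibly to serum albumin and is cleared exclusively by the kidneys.
With hepatic extraction set to zero, the minimal-PBPK topology (blood pool
plus a single adjusted compartment representing the extravascular-
extracellular space) reduces exactly to a linear two-compartment model
with elimination from the central compartment.  This module holds the
compound inputs, converts the albumin dissociation constant into a plasma
fraction unbound, and maps between micro rate constants ``(v1, v2, q, cl)``
and the macro bi-exponential constants ``(alpha, beta, A, B)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from .errors import InfeasibleCalibrationError, InvalidParameterError

__all__ = [
    "ALBUMIN_MW",
    "DEFAULT_ALBUMIN_G_L",
    "GFR_YOUNG_MALE_ML_MIN",
    "CompoundParams",
    "SubjectPK",
    "albumin_um",
    "fraction_unbound",
    "theoretical_filtration_clearance",
    "micro_to_macro",
    "solve_subject_pk",
    "calibrate_q",
]

#: Molecular weight of human serum albumin (g/mol) for g/L -> uM conversion.
ALBUMIN_MW = 66_500.0

#: Conventional plasma albumin concentration of a healthy adult (g/L).
DEFAULT_ALBUMIN_G_L = 45.0

#: Textbook glomerular filtration rate of a healthy young adult male
#: (mL/min); used only for the theoretical filtration clearance fu*GFR.
GFR_YOUNG_MALE_ML_MIN = 130.0


def albumin_um(albumin_g_l: float) -> float:
    """Convert a plasma albumin concentration from g/L to micromolar."""
    if albumin_g_l < 0:
        raise InvalidParameterError(f"albumin must be >= 0, got {albumin_g_l}")
    return albumin_g_l / ALBUMIN_MW * 1e6


def fraction_unbound(kd_um: float, albumin_conc_um: float) -> float:
    """Plasma fraction unbound from single-site, non-saturating binding.

    With ligand far below the albumin concentration, the bound fraction is
    [Alb]/(Kd + [Alb]) and so fu = Kd / (Kd + [Alb]).  For gadofosveset
    (Kd = 85 uM) at 45 g/L albumin this gives fu ~= 0.11.

    Parameters
    ----------
    kd_um : float
        Dissociation constant of the agent-albumin complex (uM), > 0.
    albumin_conc_um : float
        Plasma albumin concentration (uM), >= 0.
    """
    if kd_um <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd_um}")
    if albumin_conc_um < 0:
        raise InvalidParameterError(
            f"albumin concentration must be >= 0, got {albumin_conc_um}"
        )
    return kd_um / (kd_um + albumin_conc_um)


def theoretical_filtration_clearance(
    fu: float, gfr_ml_min: float = GFR_YOUNG_MALE_ML_MIN
) -> float:
    """Theoretical renal filtration clearance fu x GFR, in L/h.

    Only unbound drug is filtered at the glomerulus, so the upper bound on
    passive renal clearance is fu*GFR.  For gadofosveset this theoretical
    value (~0.86 L/h at fu 0.11) is well above the observed ~0.5 L/h,
    which is why clearance is treated as an empirical input scaled by GFR
    rather than predicted from binding.
    """
    if not 0 < fu <= 1:
        raise InvalidParameterError(f"fu must be in (0, 1], got {fu}")
    return fu * gfr_ml_min * 60.0 / 1000.0


@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical and pharmacokinetic inputs of the contrast agent.

    Defaults reproduce the gadofosveset reference values: 30 mg/kg IV
    dose, Vss 0.148 L/kg, distribution half-life 0.48 h, elimination
    half-life 16.3 h, albumin Kd 85 uM, and a typical renal clearance of
    0.5 L/h for the healthy young male reference subject.  ``v1_per_kg``
    is the central (blood-pool) volume per kg, a calibration constant
    fixed so that C(0) = dose/v1 matches the observed peak concentration.
    pKa/logP/PSA are carried as metadata only.
    """

    molecular_weight: float = 975.87  # g/mol
    dose_per_kg: float = 30.0  # mg/kg
    cl_ref: float = 0.5  # L/h, typical renal CL of the reference subject
    vss_per_kg: float = 0.148  # L/kg
    v1_per_kg: float = 0.0545  # L/kg, central volume calibration constant
    t_half_dist: float = 0.48  # h
    t_half_elim: float = 16.3  # h
    kd_albumin: float = 85.0  # uM
    fu_override: Optional[float] = None
    # metadata, used by no operation
    pka_acid: float = 0.78
    pka_base: float = 9.67
    logp: float = -1.2
    psa: float = 268.96

    def __post_init__(self) -> None:
        positive = {
            "molecular_weight": self.molecular_weight,
            "dose_per_kg": self.dose_per_kg,
            "cl_ref": self.cl_ref,
            "vss_per_kg": self.vss_per_kg,
            "v1_per_kg": self.v1_per_kg,
            "t_half_dist": self.t_half_dist,
            "t_half_elim": self.t_half_elim,
            "kd_albumin": self.kd_albumin,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value}")
        if self.t_half_dist >= self.t_half_elim:
            raise InvalidParameterError(
                "distribution half-life must be shorter than elimination "
                f"half-life ({self.t_half_dist} >= {self.t_half_elim})"
            )
        if self.v1_per_kg >= self.vss_per_kg:
            raise InvalidParameterError(
                "central volume per kg must be smaller than Vss per kg "
                f"({self.v1_per_kg} >= {self.vss_per_kg})"
            )
        if self.fu_override is not None and not 0 < self.fu_override <= 1:
            raise InvalidParameterError(
                f"fu_override must be in (0, 1], got {self.fu_override}"
            )

    def fu(self, albumin_g_l: float = DEFAULT_ALBUMIN_G_L) -> float:
        """Fraction unbound at a given plasma albumin level (g/L)."""
        if self.fu_override is not None:
            return self.fu_override
        return fraction_unbound(self.kd_albumin, albumin_um(albumin_g_l))

    def with_(self, **kwargs) -> "CompoundParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def micro_to_macro(
    v1: float, v2: float, q: float, cl: float
) -> tuple[float, float, float, float]:
    """Closed-form macro constants of the two-compartment IV-bolus model.

    With k10 = cl/v1, k12 = q/v1, k21 = q/v2, the plasma concentration is

        C(t) = dose * (coeff_a * exp(-alpha t) + coeff_b * exp(-beta t))

    where alpha > beta are the roots of
    x^2 - (k10 + k12 + k21) x + k10 k21 = 0 and

        coeff_a = (alpha - k21) / (v1 (alpha - beta))
        coeff_b = (k21 - beta) / (v1 (alpha - beta))

    so that coeff_a + coeff_b = 1/v1 (units: 1/L, i.e. mg/L per mg dose).

    Returns
    -------
    (alpha, beta, coeff_a, coeff_b)
    """
    for name, value in {"v1": v1, "v2": v2, "q": q, "cl": cl}.items():
        if not value > 0:
            raise InvalidParameterError(f"{name} must be > 0, got {value}")
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = s * s - 4.0 * p
    # discriminant = (k10+k12-k21)^2 + 4 k12 k21 > 0 always
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = p / alpha  # numerically stable companion root
    denom = v1 * (alpha - beta)
    coeff_a = (alpha - k21) / denom
    coeff_b = (k21 - beta) / denom
    return alpha, beta, coeff_a, coeff_b


def solve_subject_pk(
    cl: float,
    vss: float,
    t_half_dist: float,
    t_half_elim: float,
    fu: float = 1.0,
) -> "SubjectPK":
    """Invert macro parameters (CL, Vss, both half-lives) to micro constants.

    The system v1 + v2 = vss, alpha*beta = (cl/v1)(q/v2),
    alpha + beta = cl/v1 + q/v1 + q/v2 has the closed-form solution

        v1 = cl / (alpha + beta - alpha*beta*vss/cl)
        v2 = vss - v1
        q  = alpha*beta*v1*v2 / cl

    which exists and is positive iff the denominator is positive and
    v1 < vss.  Raises :class:`InfeasibleCalibrationError` otherwise,
    naming the violated constraint.
    """
    for name, value in {
        "cl": cl,
        "vss": vss,
        "t_half_dist": t_half_dist,
        "t_half_elim": t_half_elim,
    }.items():
        if not value > 0:
            raise InvalidParameterError(f"{name} must be > 0, got {value}")
    if t_half_dist >= t_half_elim:
        raise InvalidParameterError(
            "distribution half-life must be shorter than elimination half-life"
        )
    alpha = math.log(2.0) / t_half_dist
    beta = math.log(2.0) / t_half_elim
    denom = alpha + beta - alpha * beta * vss / cl
    if denom <= 0:
        raise InfeasibleCalibrationError(
            "no positive central volume: requires "
            "alpha + beta > alpha*beta*vss/cl, i.e. the half-lives are "
            "incompatible with the given CL and Vss"
        )
    v1 = cl / denom
    if v1 >= vss:
        raise InfeasibleCalibrationError(
            "central volume >= Vss: requires cl/v1 > beta "
            "(elimination faster than the terminal phase alone allows)"
        )
    v2 = vss - v1
    q = alpha * beta * v1 * v2 / cl
    return SubjectPK.from_micro(v1=v1, v2=v2, q_inter=q, cl_renal=cl, fu=fu)


def calibrate_q(v1: float, v2: float, cl: float, alpha_target: float) -> float:
    """Inter-compartmental clearance making `alpha_target` the fast root.

    Solves alpha^2 - alpha (cl/v1 + q/v1 + q/v2) + (cl/v1)(q/v2) = 0 for q
    at fixed volumes and elimination clearance.  Used to pin the
    distribution half-life of the reference subject at its observed value;
    the elimination half-life is then emergent.
    """
    num = alpha_target * alpha_target - alpha_target * cl / v1
    den = alpha_target * (1.0 / v1 + 1.0 / v2) - cl / (v1 * v2)
    if den <= 0 or num <= 0:
        raise InfeasibleCalibrationError(
            "no positive q yields the requested distribution rate "
            f"alpha={alpha_target} for v1={v1}, v2={v2}, cl={cl}"
        )
    return num / den


@dataclass(frozen=True)
class SubjectPK:
    """Structural PK parameters of one subject, micro and macro.

    v1/v2 are the central (blood pool) and peripheral (extravascular-
    extracellular, "Vsac") volumes in L, q_inter the distribution
    clearance between them (L/h), cl_renal the renal elimination
    clearance from the central compartment (L/h), fu the plasma fraction
    unbound.  alpha/beta are the derived bi-exponential rate constants.
    """

    v1: float
    v2: float
    q_inter: float
    cl_renal: float
    fu: float
    alpha: float
    beta: float

    @classmethod
    def from_micro(
        cls,
        v1: float,
        v2: float,
        q_inter: float,
        cl_renal: float,
        fu: float = 1.0,
    ) -> "SubjectPK":
        """Build a subject from micro constants, deriving alpha and beta."""
        if not 0 < fu <= 1:
            raise InvalidParameterError(f"fu must be in (0, 1], got {fu}")
        alpha, beta, _, _ = micro_to_macro(v1, v2, q_inter, cl_renal)
        return cls(
            v1=v1,
            v2=v2,
            q_inter=q_inter,
            cl_renal=cl_renal,
            fu=fu,
            alpha=alpha,
            beta=beta,
        )

    @property
    def vss(self) -> float:
        return self.v1 + self.v2

    @property
    def t_half_dist(self) -> float:
        """Distribution-phase half-life ln2/alpha (h)."""
        return math.log(2.0) / self.alpha

    @property
    def t_half_elim(self) -> float:
        """Elimination-phase half-life ln2/beta (h)."""
        return math.log(2.0) / self.beta

    def macro_coefficients(self) -> tuple[float, float, float, float]:
        """(alpha, beta, coeff_a, coeff_b) of this subject's model."""
        return micro_to_macro(self.v1, self.v2, self.q_inter, self.cl_renal)
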