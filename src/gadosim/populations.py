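"""Virtual population cohorts and the physiology -> PK mapping.

This is the study's synthetic-data generator.  Each cohort is a
distributional recipe over body weight, sex, age, glomerular filtration
rate (GFR) and plasma albumin; a sampled individual is mapped to
subject-level structural PK parameters by

* allometric (proportional-to-weight) scaling of the volumes and of the
  inter-compartmental clearance from a 74-kg reference subject,
* linear GFR scaling of renal clearance, cl = cl_ref * GFR / 96, anchored
  at the typical healthy-young-male value of 0.5 L/h,
* albumin-dependent fraction unbound (reported, but by design not used to
  rescale clearance: the observed renal clearance sits far below fu*GFR
  and follows a single linear GFR relation across all cohorts),
* a cohort-level whole-body volume-expansion multiplier (>= 1) modelling
  ascites/edema in liver cirrhosis, which lowers the peak concentration
  at a fixed mg/kg dose,
* a lognormal inter-individual variability term on the central volume
  (default CV 15%, matching the observed spread of peak concentrations).

The published study gives no distributional parameters, only cohort-level
summary tables; the numbers in :func:`builtin_cohorts` are calibrated so
that the generated cohorts reproduce those tables (mean dose, CL, AUC)
under the default trial design.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy import stats

from .compound import CompoundParams, SubjectPK, albumin_um, calibrate_q, fraction_unbound
from .errors import InvalidParameterError

__all__ = [
    "REF_WEIGHT_KG",
    "GFR_REF_ML_MIN",
    "VirtualIndividual",
    "CohortSpec",
    "COHORT_ORDER",
    "builtin_cohorts",
    "subject_rng",
    "sample_individual",
    "subject_pk_from_physiology",
    "reference_subject",
]

#: Body weight of the reference healthy young male (kg).
REF_WEIGHT_KG = 74.0

#: GFR at which renal clearance equals the reference 0.5 L/h (mL/min).
GFR_REF_ML_MIN = 96.0


@dataclass(frozen=True)
class VirtualIndividual:
    """One sampled subject: demographics, renal function, albumin.

    ``v1_scale`` is the subject's lognormal central-volume deviation
    (population mean 1) on top of the weight-proportional volume.
    """

    id: str
    sex: str  # "F" or "M"
    age: float  # years
    weight: float  # kg
    gfr: float  # mL/min, absolute
    albumin: float  # g/L
    cohort: str
    v1_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise InvalidParameterError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for name in ("weight", "gfr", "albumin", "v1_scale"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Distributional recipe for one virtual cohort.

    Weights are normal per sex (pooled mean +/- ``sex_weight_offset``,
    common SD), truncated at 3 SD; GFR and albumin are truncated normals
    with explicit or 3-SD bounds; age is uniform on ``age_range`` and
    drives nothing downstream.  ``volume_multiplier`` expands both model
    volumes (>= 1, disease-state fluid expansion); ``v1_cv`` is the
    lognormal CV of the central-volume inter-individual variability.
    """

    label: str
    weight_mean: float  # kg, pooled over sexes
    weight_sd: float = 12.0
    sex_weight_offset: float = 6.0  # M: +offset, F: -offset
    age_range: tuple[float, float] = (20.0, 50.0)
    gfr_mean: float = 108.0  # mL/min
    gfr_sd: float = 13.0
    gfr_bounds: Optional[tuple[float, float]] = None  # default: mean +/- 3 sd
    albumin_mean: float = 45.0  # g/L
    albumin_sd: float = 3.0
    volume_multiplier: float = 1.0
    v1_cv: float = 0.15
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("weight_sd", "gfr_sd", "albumin_sd", "v1_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.volume_multiplier < 1.0:
            raise InvalidParameterError("volume_multiplier must be >= 1")
        if self.gfr_bounds is not None and not self.gfr_bounds[0] < self.gfr_bounds[1]:
            raise InvalidParameterError("gfr_bounds must be ordered (lo < hi)")
        if not self.age_range[0] < self.age_range[1]:
            raise InvalidParameterError("age_range must be ordered (lo < hi)")

    # ---- frozen scipy distributions (used for sampling and for analytic
    # ---- means in validation); cached because freezing is costly --------
    def weight_dist(self, sex: str):
        mean = self.weight_mean + (
            self.sex_weight_offset if sex == "M" else -self.sex_weight_offset
        )
        return _truncnorm(mean, self.weight_sd, max(1.0, mean - 3 * self.weight_sd),
                          mean + 3 * self.weight_sd)

    def gfr_dist(self):
        if self.gfr_bounds is not None:
            lo, hi = self.gfr_bounds
        else:
            lo = max(1.0, self.gfr_mean - 3 * self.gfr_sd)
            hi = self.gfr_mean + 3 * self.gfr_sd
        return _truncnorm(self.gfr_mean, self.gfr_sd, lo, hi)

    def albumin_dist(self):
        return _truncnorm(
            self.albumin_mean, self.albumin_sd,
            max(1.0, self.albumin_mean - 3 * self.albumin_sd),
            self.albumin_mean + 3 * self.albumin_sd,
        )

    def replace(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


@lru_cache(maxsize=512)
def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


#: Reporting order of the built-in cohorts (healthy first, as control).
COHORT_ORDER = [
    "healthy",
    "renal_mod",
    "renal_sev",
    "obese",
    "oncology",
    "cirrhosis_a",
    "cirrhosis_b",
    "cirrhosis_c",
]


def builtin_cohorts() -> dict[str, CohortSpec]:
    """The eight built-in cohort recipes, calibrated to the study tables.

    Weight means are mean administered dose / 30 mg/kg; GFR means are
    back-calculated from the cohort mean clearances via the linear GFR
    scaling (with the moderate-renal-impairment cohort constrained to its
    defining 30-60 mL/min band); albumin follows standard disease
    physiology and affects only the reported fraction unbound; the
    cirrhosis volume multipliers implement increasing fluid expansion
    with Child-Pugh severity.
    """
    specs = [
        CohortSpec(
            label="healthy",
            weight_mean=73.8,
            age_range=(20.0, 50.0),
            gfr_mean=108.0,
            gfr_sd=12.96,
            notes="healthy volunteers (control)",
        ),
        CohortSpec(
            label="renal_mod",
            weight_mean=70.2,
            age_range=(40.0, 70.0),
            gfr_mean=56.0,
            gfr_sd=4.0,
            gfr_bounds=(30.0, 60.0),
            notes="moderate renal impairment, GFR 30-60 mL/min",
        ),
        CohortSpec(
            label="renal_sev",
            weight_mean=70.2,
            age_range=(40.0, 70.0),
            gfr_mean=46.0,
            gfr_sd=5.52,
            notes=(
                "severe renal impairment; effective GFR calibrated to the "
                "published clearance, which exceeds the nominal <30 label"
            ),
        ),
        CohortSpec(
            label="obese",
            weight_mean=99.9,
            age_range=(20.0, 50.0),
            gfr_mean=145.0,
            gfr_sd=17.4,
            notes="obese, dose scales with body weight",
        ),
        CohortSpec(
            label="oncology",
            weight_mean=74.3,
            age_range=(45.0, 75.0),
            gfr_mean=96.0,
            gfr_sd=11.5,
            albumin_mean=39.0,
            notes="oncology population, mild hypoalbuminemia",
        ),
        CohortSpec(
            label="cirrhosis_a",
            weight_mean=76.1,
            age_range=(40.0, 70.0),
            gfr_mean=77.0,
            gfr_sd=9.2,
            albumin_mean=38.0,
            volume_multiplier=1.25,
            notes="liver cirrhosis Child-Pugh A (hepatorenal GFR reduction)",
        ),
        CohortSpec(
            label="cirrhosis_b",
            weight_mean=76.1,
            age_range=(40.0, 70.0),
            gfr_mean=79.0,
            gfr_sd=9.5,
            albumin_mean=31.0,
            volume_multiplier=1.55,
            notes="liver cirrhosis Child-Pugh B",
        ),
        CohortSpec(
            label="cirrhosis_c",
            weight_mean=76.1,
            age_range=(40.0, 70.0),
            gfr_mean=88.0,
            gfr_sd=10.6,
            albumin_mean=25.0,
            volume_multiplier=1.95,
            notes="liver cirrhosis Child-Pugh C (marked ascites/edema)",
        ),
    ]
    return {s.label: s for s in specs}


def subject_rng(
    global_seed: int, cohort: str, trial: int, subject: int
) -> np.random.Generator:
    """Counter-based per-subject random stream.

    The stream depends only on (global_seed, cohort label, trial index,
    subject index), never on draw order, so any subject is reproducible
    in isolation.
    """
    label_key = zlib.crc32(cohort.encode("utf-8"))
    seq = np.random.SeedSequence([int(global_seed), label_key, int(trial), int(subject)])
    return np.random.default_rng(seq)


def sample_individual(
    spec: CohortSpec,
    sex: str,
    rng: np.random.Generator,
    id: str = "",
) -> VirtualIndividual:
    """Draw one virtual individual from a cohort recipe.

    Fields are drawn in a fixed order (weight, GFR, albumin, age,
    central-volume scale) so that a given generator state yields a unique
    individual.
    """
    if sex not in ("F", "M"):
        raise InvalidParameterError(f"sex must be 'F' or 'M', got {sex!r}")
    weight = float(spec.weight_dist(sex).rvs(random_state=rng))
    gfr = float(spec.gfr_dist().rvs(random_state=rng))
    albumin = float(spec.albumin_dist().rvs(random_state=rng))
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi))
    if spec.v1_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.v1_cv**2))
        v1_scale = float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))
    else:
        v1_scale = 1.0
    return VirtualIndividual(
        id=id,
        sex=sex,
        age=age,
        weight=weight,
        gfr=gfr,
        albumin=albumin,
        cohort=spec.label,
        v1_scale=v1_scale,
    )


def subject_pk_from_physiology(
    ind: VirtualIndividual,
    compound: CompoundParams,
    spec: CohortSpec | None = None,
) -> SubjectPK:
    """Map a virtual individual's physiology to structural PK parameters.

    * v1 = v1_per_kg * weight * volume_multiplier * v1_scale
    * v2 = (vss_per_kg - v1_per_kg) * weight * volume_multiplier
    * q  scales linearly with weight from the reference subject, whose q
      is calibrated so the reference distribution half-life matches the
      compound's observed value
    * cl_renal = cl_ref * GFR / 96 (linear GFR scaling)
    * fu from albumin binding (reported; does not rescale clearance)
    """
    mult = spec.volume_multiplier if spec is not None else 1.0
    v1 = compound.v1_per_kg * ind.weight * mult * ind.v1_scale
    v2 = (compound.vss_per_kg - compound.v1_per_kg) * ind.weight * mult
    q = _reference_q(compound) * ind.weight / REF_WEIGHT_KG
    cl = compound.cl_ref * ind.gfr / GFR_REF_ML_MIN
    fu = compound.fu(albumin_g_l=ind.albumin)
    return SubjectPK.from_micro(v1=v1, v2=v2, q_inter=q, cl_renal=cl, fu=fu)


def _reference_q(compound: CompoundParams) -> float:
    """Reference-subject inter-compartmental clearance (L/h).

    Calibrated once so that the 74-kg, GFR-96 reference subject's fast
    root equals ln2 / t_half_dist; other subjects scale q with weight.
    """
    v1 = compound.v1_per_kg * REF_WEIGHT_KG
    v2 = (compound.vss_per_kg - compound.v1_per_kg) * REF_WEIGHT_KG
    alpha = math.log(2.0) / compound.t_half_dist
    return calibrate_q(v1, v2, compound.cl_ref, alpha)


def reference_subject(compound: CompoundParams | None = None) -> SubjectPK:
    """The 74-kg, GFR-96 healthy young male at nominal calibration."""
    compound = compound or CompoundParams()
    ind = VirtualIndividual(
        id="reference",
        sex="M",
        age=25.0,
        weight=REF_WEIGHT_KG,
        gfr=GFR_REF_ML_MIN,
        albumin=45.0,
        cohort="healthy",
        v1_scale=1.0,
    )
    return subject_pk_from_physiology(ind, compound, spec=None)
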