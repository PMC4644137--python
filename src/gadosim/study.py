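"""End-to-end study pipeline: all cohorts, NCA, comparisons, artifacts.

``run_full_study`` executes the canonical replication — eight cohorts of
10 trials x 10 subjects under the default design — and writes a study
directory containing, per cohort, the profile and NCA tables, plus the
pooled summary table (mean +/- SD of dose, Cmax, AUC, CL, fe), the
healthy-cohort validation summary, the between-cohort comparison table,
figures, and a manifest recording the seed and configuration hash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compound import (
    CompoundParams,
    theoretical_filtration_clearance,
)
from .config import StudyConfig, config_hash, save_config
from .engine import simulate_iv_bolus
from .io import write_nca_csv, write_profiles_csv
from .nca import nca_summary
from .populations import REF_WEIGHT_KG, reference_subject
from .stats import compare_cohorts
from .trial import StudyResult, run_study

__all__ = [
    "reference_subject_summary",
    "summary_table",
    "validation_summary",
    "run_full_study",
]

logger = logging.getLogger("gadosim")

SUMMARY_COLUMNS = ["dose_mg", "cmax", "auc_inf", "cl_obs", "fe_72"]


def reference_subject_summary(compound: CompoundParams | None = None) -> dict:
    """Deterministic single-subject computations for validation.

    Simulates the 74-kg reference healthy male at nominal calibration
    (30 mg/kg bolus) and runs the full NCA on the resulting profile.
    """
    compound = compound or CompoundParams()
    pk = reference_subject(compound)
    dose = compound.dose_per_kg * REF_WEIGHT_KG
    profile = simulate_iv_bolus(pk, dose, subject_ref="reference")
    nca = nca_summary(profile, weight=REF_WEIGHT_KG)
    return {
        "weight_kg": REF_WEIGHT_KG,
        "dose_mg": dose,
        "c0_mg_per_l": float(profile.conc_plasma[0]),
        "c_at_1h_mg_per_l": nca.c_at_1h,
        "cmax_mg_per_l": nca.cmax,
        "auc_inf_mg_h_per_l": nca.auc_inf,
        "cl_obs_l_per_h": nca.cl_obs,
        "cl_per_kg_ml_h_kg": nca.cl_per_kg,
        "fe_72": nca.fe_72,
        "t_half_dist_obs_h": nca.t_half_dist_obs,
        "t_half_elim_obs_h": nca.t_half_elim_obs,
        "fu": compound.fu(),
        "fu_times_gfr_l_per_h": theoretical_filtration_clearance(round(compound.fu(), 2)),
    }


def summary_table(results: dict[str, StudyResult]) -> pd.DataFrame:
    """Pooled mean +/- SD of the headline PK parameters per cohort."""
    rows = []
    for label, res in results.items():
        row = {"cohort": label, "n": len(res.subjects)}
        for col in SUMMARY_COLUMNS:
            row[f"{col}_mean"] = res.pooled_mean[col]
            row[f"{col}_sd"] = res.pooled_sd[col]
        rows.append(row)
    return pd.DataFrame(rows)


def validation_summary(results: dict[str, StudyResult],
                       compound: CompoundParams | None = None) -> dict:
    """Healthy-cohort validation values and renal AUC fold increases."""
    compound = compound or CompoundParams()
    out = {"reference_subject": reference_subject_summary(compound)}
    if "healthy" in results:
        h = results["healthy"].pooled_mean
        out["healthy_pooled"] = {
            "cmax_mg_per_l": float(h["cmax"]),
            "auc_inf_mg_h_per_l": float(h["auc_inf"]),
            "cl_obs_l_per_h": float(h["cl_obs"]),
            "cl_per_kg_ml_h_kg": float(h["cl_per_kg"]),
            "fe_72": float(h["fe_72"]),
            "c_at_1h_mg_per_l": float(h["c_at_1h"]),
        }
        for label, key in (("renal_mod", "auc_fold_moderate_renal"),
                           ("renal_sev", "auc_fold_severe_renal")):
            if label in results:
                out[key] = float(
                    results[label].pooled_mean["auc_inf"] / h["auc_inf"]
                )
    return out


def run_full_study(config: StudyConfig | None = None, out_dir=None) -> Path:
    """Run the full multi-cohort study and write all artifacts.

    Returns the study directory.  Byte-identical outputs for identical
    (configuration, seed).
    """
    config = config or StudyConfig()
    out = Path(out_dir) if out_dir is not None else Path(config.output.directory)
    out.mkdir(parents=True, exist_ok=True)

    results: dict[str, StudyResult] = {}
    for label in config.cohort_order:
        spec = config.cohorts[label]
        logger.info("cohort %s: %d trials x %d subjects, seed %d",
                    label, config.design.n_trials,
                    config.design.n_subjects_per_trial, config.design.global_seed)
        res = run_study(config.design, spec, config.compound)
        results[label] = res
        write_profiles_csv(res.profiles, out / f"profiles_{label}.csv")
        write_nca_csv(res.subjects, out / f"nca_{label}.csv")

    summary = summary_table(results)
    summary.to_csv(out / "summary_table.csv", index=False, float_format="%.12g")

    control = "healthy" if "healthy" in results else config.cohort_order[0]
    comparison = compare_cohorts(
        {lb: r.subjects for lb, r in results.items()}, control=control,
        random_state=config.design.global_seed % (2**31),
    )
    comparison.to_csv(out / "comparison.csv", index=False, float_format="%.12g")

    validation = validation_summary(results, config.compound)
    (out / "validation.json").write_text(json.dumps(validation, indent=2))

    pooled = {
        lb: {"mean": r.pooled_mean.to_dict(), "sd": r.pooled_sd.to_dict()}
        for lb, r in results.items()
    }
    (out / "summary.json").write_text(json.dumps(pooled, indent=2))

    manifest = {
        "gadosim_version": __version__,
        "global_seed": config.design.global_seed,
        "config_hash": config_hash(config),
        "cohorts": config.cohort_order,
        "design": asdict(config.design),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_config(config, out / "config_resolved.yaml")

    if config.output.plots:
        _write_plots(out, results, comparison, config)
    return out


def _write_plots(out: Path, results, comparison, config: StudyConfig) -> None:
    from . import plots  # deferred: pulls in matplotlib

    for label, res in results.items():
        plots.plot_profile_envelope(
            res.profiles, title=label, path=out / f"profiles_{label}.png",
            q_low=config.output.envelope_low, q_high=config.output.envelope_high,
        )
    plots.plot_gmr_forest(comparison, out / "gmr_forest.png")
    all_subjects = pd.concat(
        [r.subjects.assign(cohort=lb) for lb, r in results.items()],
        ignore_index=True,
    )
    plots.plot_gfr_cl(all_subjects, out / "gfr_vs_cl.png")
    plots.plot_urine_recovery(
        {lb: r.profiles for lb, r in results.items()}, out / "urine_recovery.png"
    )
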