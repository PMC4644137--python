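"""Virtual cohorts: sampling distributions, physiology -> PK mapping."""

import numpy as np
import pytest

import gadosim as g
from gadosim.populations import GFR_REF_ML_MIN, REF_WEIGHT_KG


@pytest.fixture(scope="module")
def cohorts():
    return g.builtin_cohorts()


def _sample_many(spec, n, seed=123):
    rng = np.random.default_rng(seed)
    sexes = ["F", "M"] * (n // 2)
    return [g.sample_individual(spec, sex, rng) for sex in sexes]


@pytest.fixture(scope="module")
def big_samples(cohorts):
    """10,000 sex-balanced draws per cohort, shared across the module."""
    out = {}
    for label, spec in cohorts.items():
        inds = _sample_many(spec, 10_000)
        out[label] = {
            "weight": np.array([i.weight for i in inds]),
            "gfr": np.array([i.gfr for i in inds]),
            "albumin": np.array([i.albumin for i in inds]),
            "v1_scale": np.array([i.v1_scale for i in inds]),
        }
    return out


class TestBuiltinCohorts:
    def test_all_eight_present(self, cohorts):
        assert set(cohorts) == {
            "healthy", "renal_mod", "renal_sev", "obese", "oncology",
            "cirrhosis_a", "cirrhosis_b", "cirrhosis_c",
        }

    def test_healthy_calibration(self, cohorts):
        h = cohorts["healthy"]
        assert h.gfr_mean == pytest.approx(108.0)
        assert h.albumin_mean == 45.0

    def test_renal_mod_band(self, cohorts):
        m = cohorts["renal_mod"]
        assert m.gfr_bounds == (30.0, 60.0)
        assert 30.0 < m.gfr_mean < 60.0

    def test_cirrhosis_volume_expansion_increases_with_severity(self, cohorts):
        mults = [cohorts[f"cirrhosis_{x}"].volume_multiplier for x in "abc"]
        assert mults[0] < mults[1] < mults[2]
        assert all(m >= 1 for m in mults)

    def test_unknown_label_lookup_fails(self, cohorts):
        with pytest.raises(KeyError):
            cohorts["pediatric"]


class TestSampleIndividual:
    def test_same_seed_state_reproduces_individual(self, cohorts):
        a = g.sample_individual(cohorts["healthy"], "F",
                                g.subject_rng(1, "healthy", 2, 3))
        b = g.sample_individual(cohorts["healthy"], "F",
                                g.subject_rng(1, "healthy", 2, 3))
        assert a == b

    def test_streams_independent_of_order(self):
        # counter-based scheme: stream (seed, cohort, trial, subject) is fixed
        r1 = g.subject_rng(42, "obese", 1, 1).random(3)
        g.subject_rng(42, "obese", 9, 9).random(3)  # interleaved draw
        r2 = g.subject_rng(42, "obese", 1, 1).random(3)
        assert np.array_equal(r1, r2)

    @pytest.mark.parametrize("label, expected_weight", [
        ("healthy", 73.8),   # mean dose 2212.90 mg / 30 mg/kg
        ("obese", 99.9),     # mean dose 2997.52 mg / 30 mg/kg
    ])
    def test_pooled_weight_means(self, big_samples, label, expected_weight):
        w = big_samples[label]["weight"]
        se = w.std(ddof=1) / np.sqrt(len(w))
        assert abs(w.mean() - expected_weight) < 2 * se + 0.05

    def test_resampled_means_match_analytic_means(self, cohorts, big_samples):
        # 10,000 draws per cohort reproduce the recipe's analytic
        # truncated-normal means within ~2 standard errors
        for label, spec in cohorts.items():
            gfr = big_samples[label]["gfr"]
            alb = big_samples[label]["albumin"]
            gfr_se = gfr.std(ddof=1) / 100.0
            assert abs(gfr.mean() - spec.gfr_dist().mean()) < 2.5 * gfr_se
            assert abs(alb.mean() - spec.albumin_dist().mean()) < 2.5 * (
                alb.std(ddof=1) / 100.0
            )

    def test_renal_mod_respects_truncation(self, big_samples):
        gfr = big_samples["renal_mod"]["gfr"]
        assert gfr.min() >= 30.0 and gfr.max() <= 60.0

    def test_age_within_range(self, cohorts):
        inds = _sample_many(cohorts["oncology"], 200)
        lo, hi = cohorts["oncology"].age_range
        assert all(lo <= i.age <= hi for i in inds)

    def test_v1_scale_mean_one(self, big_samples):
        s = big_samples["healthy"]["v1_scale"]
        assert s.mean() == pytest.approx(1.0, abs=0.01)
        assert s.std(ddof=1) == pytest.approx(0.15, abs=0.02)


class TestPhysiologyToPK:
    def test_reference_male_clearance(self, compound):
        ind = g.VirtualIndividual(id="r", sex="M", age=25, weight=74.0,
                                  gfr=96.0, albumin=45.0, cohort="healthy")
        pk = g.subject_pk_from_physiology(ind, compound)
        assert pk.cl_renal == pytest.approx(0.5, rel=1e-12)

    def test_linear_gfr_scaling(self, compound):
        ind = g.VirtualIndividual(id="x", sex="M", age=50, weight=74.0,
                                  gfr=48.0, albumin=45.0, cohort="renal_mod")
        pk = g.subject_pk_from_physiology(ind, compound)
        assert pk.cl_renal == pytest.approx(0.25, rel=1e-12)

    def test_cl_gfr_correlation_is_exact(self, compound, cohorts):
        inds = _sample_many(cohorts["healthy"], 1000)
        gfr = np.array([i.gfr for i in inds])
        cl = np.array([
            g.subject_pk_from_physiology(i, compound, cohorts["healthy"]).cl_renal
            for i in inds
        ])
        assert np.corrcoef(gfr, cl)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_single_global_slope_across_cohorts(self, compound, cohorts):
        slopes = []
        for label in ("healthy", "renal_sev", "cirrhosis_c"):
            ind = _sample_many(cohorts[label], 10)[0]
            pk = g.subject_pk_from_physiology(ind, compound, cohorts[label])
            slopes.append(pk.cl_renal / ind.gfr)
        assert np.ptp(slopes) < 1e-12

    def test_volume_multiplier_expands_both_compartments(self, compound, cohorts):
        ind = g.VirtualIndividual(id="c", sex="M", age=55, weight=76.1,
                                  gfr=88.0, albumin=25.0, cohort="cirrhosis_c")
        base = g.subject_pk_from_physiology(ind, compound, cohorts["healthy"])
        cirr = g.subject_pk_from_physiology(ind, compound, cohorts["cirrhosis_c"])
        m = cohorts["cirrhosis_c"].volume_multiplier
        assert cirr.v1 == pytest.approx(base.v1 * m, rel=1e-12)
        assert cirr.v2 == pytest.approx(base.v2 * m, rel=1e-12)

    def test_fu_from_cohort_albumin(self, compound, cohorts):
        ind = g.VirtualIndividual(id="c", sex="F", age=55, weight=70.0,
                                  gfr=88.0, albumin=25.0, cohort="cirrhosis_c")
        pk = g.subject_pk_from_physiology(ind, compound, cohorts["cirrhosis_c"])
        assert pk.fu == pytest.approx(
            g.fraction_unbound(85.0, g.albumin_um(25.0)), rel=1e-12
        )

    def test_dose_column_recovered(self, big_samples):
        # mean cohort dose = 30 mg/kg x mean weight, within 2% of the
        # published dose column at n = 10,000
        published = {
            "healthy": 2212.90, "renal_mod": 2104.51, "renal_sev": 2104.51,
            "obese": 2997.52, "oncology": 2228.18, "cirrhosis_a": 2283.12,
            "cirrhosis_b": 2283.12, "cirrhosis_c": 2283.12,
        }
        for label, dose in published.items():
            mean_dose = 30.0 * big_samples[label]["weight"].mean()
            assert abs(mean_dose - dose) / dose < 0.02


class TestReferenceSubject:
    def test_reference_constants(self, ref_subject):
        assert ref_subject.v1 == pytest.approx(0.0545 * REF_WEIGHT_KG, rel=1e-12)
        assert ref_subject.vss == pytest.approx(0.148 * REF_WEIGHT_KG, rel=1e-12)
        assert ref_subject.cl_renal == 0.5
        assert GFR_REF_ML_MIN == 96.0
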