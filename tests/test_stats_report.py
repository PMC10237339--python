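"""Group statistics: percent change, ANOVA + Bonferroni, nonparametrics, F test."""

import numpy as np
import pandas as pd
import pytest

from nmjkit.stats_report import (
    build_report,
    nonparametric_compare,
    percent_change,
    two_way_anova_bonferroni,
    variance_f_test,
)


def _table(rng, ages, genos, n, mean_fn, sd_fn=lambda a, g: 1.0):
    rows = []
    for a in ages:
        for g in genos:
            vals = rng.normal(mean_fn(a, g), sd_fn(a, g), n)
            rows += [{"age_weeks": a, "genotype": g, "measure": "m", "value": v}
                     for v in vals]
    return pd.DataFrame(rows)


class TestPercentChange:
    def test_published_arithmetic(self):
        """The symptomatic mEPP means 1.19 vs 0.94 give a 21.0% reduction."""
        assert round(percent_change(1.19, 0.94), 1) == 21.0

    def test_no_change(self):
        assert percent_change(3.7, 3.7) == 0.0

    def test_increase_is_negative(self):
        assert percent_change(2.0, 3.0) == pytest.approx(-50.0)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestTwoWayAnova:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        df = _table(rng, [2, 4], ["WT", "SOD1"], 40, lambda a, g: 1.0)
        results = two_way_anova_bonferroni(df, "m")
        geno = [r for r in results if r.test == "two_way_anova"
                and "C(genotype)" in r.note and "age" not in r.note.replace("C(genotype)", "")]
        assert geno[0].p_value > 0.05

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(1)
        df = _table(rng, [2, 4, 8], ["WT", "SOD1"], 20, lambda a, g: 1.0)
        for r in two_way_anova_bonferroni(df, "m"):
            if r.test == "t_posttest":
                assert r.adjusted_p == pytest.approx(min(1.0, r.p_value * 3))
                assert r.adjusted_p >= r.p_value

    def test_shift_at_one_age_detected(self):
        """A 0.25 mV genotype shift at one age, n=60/group, sd=0.35:
        the post-test at that age is significant with high power."""
        hits = 0
        for rep in range(25):
            rng = np.random.default_rng(100 + rep)
            df = _table(rng, [8, 16], ["SOD1", "WT"], 60,
                        lambda a, g: 1.0 + (0.25 if (a == 16 and g == "WT") else 0.0),
                        lambda a, g: 0.35)
            res = two_way_anova_bonferroni(df, "m")
            post16 = [r for r in res if r.test == "t_posttest" and r.age_weeks == 16]
            hits += post16[0].adjusted_p < 0.05
        assert hits / 25 > 0.9

    def test_empty_cell_errors(self):
        rng = np.random.default_rng(2)
        df = _table(rng, [2, 4], ["WT", "SOD1"], 10, lambda a, g: 1.0)
        df = df[~((df.age_weeks == 4) & (df.genotype == "SOD1"))]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova_bonferroni(df, "m")


class TestNonparametric:
    def test_identical_samples_null(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 30)
        rows = [{"age_weeks": 8, "genotype": g, "measure": "m", "value": v}
                for g in ("WT", "SOD1") for v in base]
        res = nonparametric_compare(pd.DataFrame(rows), "m")
        mw = [r for r in res if r.test == "mann_whitney_u"][0]
        assert mw.p_value > 0.9

    def test_location_shift_pattern(self):
        """Pure location shift: Mann-Whitney fires, Ansari-Bradley does not."""
        sig_mw = sig_ab = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            rows = []
            for g, mu in (("WT", 0.0), ("SOD1", 1.2)):
                rows += [{"age_weeks": 8, "genotype": g, "measure": "m", "value": v}
                         for v in rng.normal(mu, 1, 40)]
            res = nonparametric_compare(pd.DataFrame(rows), "m")
            sig_mw += [r for r in res if r.test == "mann_whitney_u"][0].p_value < 0.05
            sig_ab += [r for r in res if r.test == "ansari_bradley"][0].p_value < 0.05
        assert sig_mw >= 18
        assert sig_ab <= 5

    def test_scale_shift_pattern(self):
        """Pure dispersion difference: converse of the location case."""
        sig_mw = sig_ab = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            rows = []
            for g, sd in (("WT", 1.0), ("SOD1", 3.0)):
                rows += [{"age_weeks": 8, "genotype": g, "measure": "m", "value": v}
                         for v in rng.normal(0, sd, 40)]
            res = nonparametric_compare(pd.DataFrame(rows), "m")
            sig_mw += [r for r in res if r.test == "mann_whitney_u"][0].p_value < 0.05
            sig_ab += [r for r in res if r.test == "ansari_bradley"][0].p_value < 0.05
        assert sig_ab >= 18
        assert sig_mw <= 5

    def test_small_groups_flagged(self):
        rows = [{"age_weeks": 8, "genotype": g, "measure": "m", "value": v}
                for g, vals in (("WT", [1, 2]), ("SOD1", [1, 2, 3, 4]))
                for v in vals]
        res = nonparametric_compare(pd.DataFrame(rows), "m")
        assert all(np.isnan(r.p_value) and "underpowered" in r.note for r in res)


class TestVarianceFTest:
    def test_variance_inflation_detected(self):
        """3x SD inflation, n=40/group: significant at alpha=0.005 with power > 0.8."""
        hits = 0
        for rep in range(25):
            rng = np.random.default_rng(400 + rep)
            df = _table(rng, [12], ["SOD1", "WT"], 40, lambda a, g: 0.0,
                        lambda a, g: 3.0 if g == "SOD1" else 1.0)
            res = variance_f_test(df, "m")
            hits += res[0].p_value < 0.005
        assert hits / 25 > 0.8

    def test_single_observation_group_flagged(self):
        rows = [{"age_weeks": 8, "genotype": "WT", "measure": "m", "value": 1.0},
                {"age_weeks": 8, "genotype": "SOD1", "measure": "m", "value": 2.0},
                {"age_weeks": 8, "genotype": "SOD1", "measure": "m", "value": 3.0},
                {"age_weeks": 8, "genotype": "SOD1", "measure": "m", "value": 4.0}]
        res = variance_f_test(pd.DataFrame(rows), "m")
        assert np.isnan(res[0].p_value) and "underpowered" in res[0].note

    def test_zero_variance_errors(self):
        rows = [{"age_weeks": 8, "genotype": g, "measure": "m", "value": v}
                for g, vals in (("WT", [1.0] * 5), ("SOD1", [1, 2, 3, 4, 5]))
                for v in vals]
        with pytest.raises(ValueError, match="zero variance"):
            variance_f_test(pd.DataFrame(rows), "m")


class TestTypeICalibration:
    """Observed type-I error of each test sits at the nominal level under the null."""

    @pytest.mark.parametrize("test_fn, test_name", [
        (nonparametric_compare, "mann_whitney_u"),
        (nonparametric_compare, "ansari_bradley"),
        (variance_f_test, "f_test"),
    ])
    def test_alpha_calibration(self, test_fn, test_name):
        reps, n, alpha = 600, 30, 0.05
        rng = np.random.default_rng(hash(test_name) % 2**31)
        rejections = 0
        for _ in range(reps):
            rows = [{"age_weeks": 8, "genotype": g, "measure": "m", "value": v}
                    for g in ("WT", "SOD1") for v in rng.normal(0, 1, n)]
            res = test_fn(pd.DataFrame(rows), "m")
            p = [r for r in res if r.test == test_name][0].p_value
            rejections += p < alpha
        rate = rejections / reps
        tol = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) < tol + 0.01  # discrete-statistic slack


class TestBuildReport:
    def test_report_bundle(self, tmp_path):
        rng = np.random.default_rng(5)
        ephys = pd.DataFrame({
            "age_weeks": np.repeat([2, 20], 20),
            "genotype": np.tile(np.repeat(["WT", "SOD1"], 10), 2),
            "mepp_mean_corrected": rng.normal(1.2, 0.2, 40),
            "qc": rng.normal(30, 5, 40),
        })
        morpho = pd.DataFrame({
            "age_weeks": np.repeat([12, 20], 20),
            "genotype": np.tile(np.repeat(["WT", "SOD1"], 10), 2),
            "d_achr_area": rng.normal(300, 40, 40),
            "fractal_dimension": rng.normal(1.0, 0.02, 40),
            "floccular_category": rng.choice(["none", "lt50", "gt50"], 40),
            "has_extrajunctional": rng.choice([True, False], 40),
        })
        tables = build_report(ephys, morpho, tmp_path)
        assert (tmp_path / "ephys_summary.csv").exists()
        assert (tmp_path / "incidence.csv").exists()
        inc = tables["incidence"]
        assert inc.n_nmjs.sum() == 40  # incidence rows conserve the NMJ count
        assert len(tables["ephys_summary"]) == 2 * 2 * 2

    def test_empty_inputs_produce_empty_bundle(self, tmp_path):
        tables = build_report(None, None, tmp_path)
        assert tables == {}
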