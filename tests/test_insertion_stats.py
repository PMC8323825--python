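"""Statistical layer: rate bookkeeping against printed counts, fit and
ANOVA behaviour on constructed tables, and Monte-Carlo calibration of the
correlation estimator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beamforce.insertion_stats import (
    buckling_rate_table,
    build_report,
    diameter_linearity_fit,
    dimpling_force_ratio,
    read_study,
    rupture_dimpling_correlation,
    three_factor_anova,
    trial_counts_from_study,
    write_study,
)
from beamforce.synthetic_data import StudyDesign, simulate_study

# penetrated/total per condition as recorded in the study's rate table
STUDY_COUNTS = [
    # (material, tip, diameter, membrane, penetrated, total, printed rate %)
    ("tungsten", "sharp", 25, "pia_only", 10, 11, 9.1),
    ("tungsten", "sharp", 50, "pia_only", 11, 11, 0.0),
    ("tungsten", "sharp", 100, "pia_only", 10, 10, 0.0),
    ("tungsten", "blunt", 12, "pia_only", 8, 9, 11.1),
    ("tungsten", "blunt", 25, "pia_only", 11, 11, 0.0),
    ("tungsten", "blunt", 50, "pia_only", 10, 10, 0.0),
    ("tungsten", "blunt", 100, "pia_only", 11, 11, 0.0),
    ("stainless_steel", "blunt", 12, "pia_only", 10, 11, 9.1),
    ("stainless_steel", "blunt", 25, "pia_only", 10, 10, 0.0),
    ("stainless_steel", "blunt", 50, "pia_only", 11, 11, 0.0),
    ("stainless_steel", "blunt", 100, "pia_only", 10, 10, 0.0),
    ("tungsten", "sharp", 25, "dura_pia", 10, 14, 28.6),
    ("tungsten", "sharp", 50, "dura_pia", 14, 14, 0.0),
    ("tungsten", "sharp", 100, "dura_pia", 14, 14, 0.0),
    ("tungsten", "blunt", 25, "dura_pia", 8, 14, 42.9),
    ("tungsten", "blunt", 50, "dura_pia", 13, 14, 7.1),
    ("tungsten", "blunt", 100, "dura_pia", 12, 12, 0.0),
    ("stainless_steel", "blunt", 25, "dura_pia", 6, 14, 57.1),
    ("stainless_steel", "blunt", 50, "dura_pia", 13, 14, 7.1),
    ("stainless_steel", "blunt", 100, "dura_pia", 13, 13, 0.0),
]


def study_counts_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [row[:6] for row in STUDY_COUNTS],
        columns=["material", "tip", "diameter_um", "membrane", "penetrated", "total"],
    )


def synthetic_table(n_per_cell=6, noise=0.0, seed=0, rho_break=None) -> pd.DataFrame:
    """Deterministic-by-construction trial table, linear in diameter."""
    rng = np.random.default_rng(seed)
    rows = []
    for material in ("tungsten", "stainless_steel"):
        for tip in ("blunt", "sharp"):
            for d in (12, 25, 50, 100):
                for _ in range(n_per_cell):
                    force = (0.2 + 0.03 * d) * (0.6 if tip == "sharp" else 1.0)
                    force += rng.normal(0, noise)
                    rows.append(
                        dict(material=material, tip=tip, diameter_um=d,
                             membrane="pia_only", outcome="penetrated",
                             rupture_force_mn=force, dimpling_mm=force / 3.0,
                             animal=0, order=0)
                    )
    return pd.DataFrame(rows)


class TestBucklingRateTable:
    def test_printed_rates_row_wise(self):
        table = buckling_rate_table(study_counts_frame())
        rows = table[~table["pooled"]]
        for (*_, printed), (_, got) in zip(STUDY_COUNTS, rows.iterrows()):
            assert round(got["buckling_rate_pct"], 1) == printed

    def test_pooled_rates(self):
        table = buckling_rate_table(study_counts_frame())
        pooled = table[table["pooled"]].set_index("membrane")["buckling_rate_pct"]
        assert round(pooled["pia_only"], 1) == 2.6
        assert round(pooled["dura_pia"], 1) == 16.3

    def test_all_penetrated_is_zero(self):
        table = buckling_rate_table(pd.DataFrame({"penetrated": [10], "total": [10]}))
        assert table["buckling_rate_pct"].iloc[0] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            buckling_rate_table(pd.DataFrame({"penetrated": [0], "total": [0]}))

    def test_counts_from_simulated_study(self, registry):
        study = simulate_study(StudyDesign(), seed=3, registry=registry)
        counts = trial_counts_from_study(study)
        assert counts["total"].sum() == 238
        assert (counts["penetrated"] <= counts["total"]).all()


class TestDiameterLinearityFit:
    def test_exact_linearity_gives_unit_r2(self):
        table = synthetic_table(noise=0.0)
        fit = diameter_linearity_fit(table, "rupture_force_mn", "pia_only",
                                     material="tungsten", tip="blunt")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.03)
        assert fit.intercept == pytest.approx(0.2)

    def test_means_fit_equals_raw_fit_when_balanced_noiseless(self):
        table = synthetic_table(noise=0.0)
        on_means = diameter_linearity_fit(table, membrane="pia_only", on_means=True,
                                          material="tungsten", tip="blunt")
        raw = diameter_linearity_fit(table, membrane="pia_only", on_means=False,
                                     material="tungsten", tip="blunt")
        assert on_means.slope == pytest.approx(raw.slope)
        assert on_means.intercept == pytest.approx(raw.intercept)

    def test_linear_model_beats_quadratic_on_linear_data(self):
        wins = 0
        for seed in range(40):
            table = synthetic_table(noise=0.2, seed=seed)
            fit = diameter_linearity_fit(table, membrane="pia_only",
                                         material="tungsten", tip="blunt")
            wins += fit.r_squared > fit.quadratic_r_squared
        assert wins >= 38  # >= 95%

    def test_single_diameter_level_rejected(self):
        table = synthetic_table().query("diameter_um == 25")
        with pytest.raises(ValueError):
            diameter_linearity_fit(table, membrane="pia_only")


class TestThreeFactorAnova:
    def test_identical_observations_give_zero_f(self):
        table = synthetic_table()
        table["rupture_force_mn"] = 2.0
        res = three_factor_anova(table, "rupture_force_mn", "pia_only")
        assert (res.table["F"] == 0.0).all()
        assert (res.table["p"] == 1.0).all()

    def test_p_invariant_under_level_relabeling(self):
        table = synthetic_table(noise=0.2, seed=1)
        res1 = three_factor_anova(table, "rupture_force_mn", "pia_only")
        relabeled = table.replace(
            {"material": {"tungsten": "zz_metal"}, "tip": {"blunt": "aa_flat"}}
        )
        res2 = three_factor_anova(relabeled, "rupture_force_mn", "pia_only")
        for factor in ("material", "tip", "diameter_um"):
            assert res1.p(factor) == pytest.approx(res2.p(factor))

    def test_f_invariant_under_affine_response_transform(self):
        table = synthetic_table(noise=0.2, seed=2)
        res1 = three_factor_anova(table, "rupture_force_mn", "pia_only")
        table2 = table.assign(rupture_force_mn=3.5 * table["rupture_force_mn"] - 1.0)
        res2 = three_factor_anova(table2, "rupture_force_mn", "pia_only")
        for factor in ("material", "tip", "diameter_um"):
            assert res1.f(factor) == pytest.approx(res2.f(factor))

    def test_strong_diameter_effect_detected(self, registry):
        study = simulate_study(StudyDesign(), seed=4, registry=registry)
        res = three_factor_anova(study, "rupture_force_mn", "pia_only")
        assert res.p("diameter_um") < 1e-6

    def test_single_level_factor_named_in_error(self):
        table = synthetic_table().query("tip == 'blunt'")
        with pytest.raises(ValueError, match="tip"):
            three_factor_anova(table, "rupture_force_mn", "pia_only")


class TestCorrelation:
    def frame(self, x, y):
        n = len(x)
        return pd.DataFrame(
            dict(material="tungsten", tip="blunt", diameter_um=25, membrane="pia_only",
                 outcome="penetrated", rupture_force_mn=x, dimpling_mm=y,
                 animal=0, order=range(n))
        )

    def test_perfect_correlation(self):
        x = np.linspace(1, 5, 20)
        res = rupture_dimpling_correlation(self.frame(x, x), "pia_only", strata=("all",))
        assert res[0].r == pytest.approx(1.0)
        assert res[0].strength == "strong"

    def test_tiny_stratum_reports_undefined_p(self):
        x = np.array([1.0, 2.0])
        res = rupture_dimpling_correlation(self.frame(x, x * 2), "pia_only", strata=("all",))
        assert res[0].n == 2 and np.isnan(res[0].p)

    def test_constant_vector_undefined_r(self):
        x = np.ones(10)
        res = rupture_dimpling_correlation(self.frame(x, np.arange(10.0)), "pia_only",
                                           strata=("all",))
        assert np.isnan(res[0].r)

    def test_estimator_unbiased_on_bivariate_normal(self, rng):
        """Mean estimated r within 0.05 of the true rho at n = 30."""
        for rho in (0.0, 0.3, 0.7):
            cov = [[1.0, rho], [rho, 1.0]]
            estimates = []
            for _ in range(500):
                xy = rng.multivariate_normal([0, 0], cov, size=30)
                res = rupture_dimpling_correlation(
                    self.frame(xy[:, 0], xy[:, 1]), "pia_only", strata=("all",)
                )
                estimates.append(res[0].r)
            assert abs(np.mean(estimates) - rho) < 0.05

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        n_draws = 500
        for _ in range(n_draws):
            x, y = rng.normal(size=30), rng.normal(size=30)
            res = rupture_dimpling_correlation(self.frame(x, y), "pia_only", strata=("all",))
            rejections += res[0].p < 0.05
        assert abs(rejections / n_draws - 0.05) < 0.03

    def test_matches_reference_pearson(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = rupture_dimpling_correlation(self.frame(x, y), "pia_only", strata=("all",))[0]
        ref_r, ref_p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(float(ref_r))
        assert res.p == pytest.approx(float(ref_p))


class TestDimplingForceRatio:
    def test_arithmetic(self):
        table = self_frame = pd.DataFrame(
            dict(material=["tungsten"], tip=["blunt"], diameter_um=[25],
                 membrane=["pia_only"], outcome=["penetrated"],
                 rupture_force_mn=[2.0], dimpling_mm=[0.5], animal=[0], order=[0])
        )
        with_ratio, summary = dimpling_force_ratio(table)
        assert with_ratio["ratio_mm_per_mn"].iloc[0] == pytest.approx(0.25)
        assert summary["mean"].iloc[0] == pytest.approx(0.25)

    def test_invariant_under_joint_rescaling(self):
        table = synthetic_table(noise=0.1, seed=3)
        r1, _ = dimpling_force_ratio(table)
        scaled = table.assign(
            rupture_force_mn=7.0 * table["rupture_force_mn"],
            dimpling_mm=7.0 * table["dimpling_mm"],
        )
        r2, _ = dimpling_force_ratio(scaled)
        assert np.allclose(r1["ratio_mm_per_mn"], r2["ratio_mm_per_mn"])

    def test_noiseless_ratio_is_inverse_membrane_stiffness(self, registry):
        design = StudyDesign(residual_sd=0.0, animal_sd=0.0, dimpling_noise_sd_mm=0.0)
        study = simulate_study(design, seed=0, registry=registry)
        with_ratio, _ = dimpling_force_ratio(study[study.membrane == "pia_only"])
        assert np.allclose(with_ratio["ratio_mm_per_mn"], 1.0 / 3.0)

    def test_zero_force_excluded(self):
        table = synthetic_table(noise=0.0).head(5).copy()
        table.loc[table.index[0], "rupture_force_mn"] = 0.0
        with_ratio, summary = dimpling_force_ratio(table)
        assert len(with_ratio) == 4
        assert summary.attrs["excluded_zero_force"] == 1


class TestReport:
    def test_empty_study_gives_valid_empty_report(self):
        report = build_report(pd.DataFrame())
        assert report["n_trials"] == 0
        assert report["fits"] == [] and report["anovas"] == []

    def test_bookkeeping_matches_input(self, registry, tmp_path):
        study = simulate_study(StudyDesign(), seed=6, registry=registry)
        report = build_report(study, outdir=tmp_path)
        buckling = report["buckling"]
        assert buckling.loc[~buckling["pooled"], "total"].sum() == len(study)
        # both membranes analyzed, three responses each
        assert len(report["anovas"]) == 6
        assert (tmp_path / "buckling_rates.csv").exists()
        assert (tmp_path / "anova.csv").exists()

    def test_study_io_round_trip(self, registry, tmp_path):
        study = simulate_study(StudyDesign(), seed=7, registry=registry)
        path = tmp_path / "study.csv"
        write_study(path, study)
        back = read_study(path)
        assert len(back) == len(study)
        assert set(back.columns) == set(study.columns)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_study(path)
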