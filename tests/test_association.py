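import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycoclust.association import (
    build_design,
    fit_cluster_models,
    genotype_comparison,
    per_glycan_association,
    significant_clusters,
)
from glycoclust.data_io import AcaMatrix, ValidationError
from glycoclust.profiles import ClusterScoreMatrix
from glycoclust.synthetic import SynthSpec, generate_cohorts, generate_panel
from tests.conftest import toy_clinical, truth_score_matrix


def scores_from_frame(frame):
    return ClusterScoreMatrix(scores=frame, loadings={}, explained_variance={}, orientation={})


class TestClusterModels:
    def test_planted_progressor_coefficient_recovered(self):
        rng = np.random.default_rng(0)
        clin = toy_clinical(rng, n=120)
        design = build_design(clin)
        y = 2.0 * design["progressor"] + rng.normal(0, 0.01, size=len(design))
        frame = pd.DataFrame({"cluster_1": y}, index=design.index)
        res = fit_cluster_models(scores_from_frame(frame), clin)
        row = res[(res.term == "progressor")].iloc[0]
        assert row.estimate == pytest.approx(2.0, abs=0.02)
        assert row.p_value < 1e-10
        others = res[~res.term.isin(["progressor", "intercept"])]
        assert (others.p_value > 0.01).all()
        assert significant_clusters(res) == [1]

    def test_estimates_match_normal_equations_oracle(self):
        """OLS estimates equal the from-scratch (X'X)^-1 X'y solve."""
        rng = np.random.default_rng(1)
        clin = toy_clinical(rng, n=90)
        design = build_design(clin)
        y = rng.normal(size=len(design))
        frame = pd.DataFrame({"cluster_1": y}, index=design.index)
        res = fit_cluster_models(scores_from_frame(frame), clin)
        X = design.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        terms = ["intercept" if t == "const" else t for t in design.columns]
        for t, b in zip(terms, beta):
            assert res[res.term == t].iloc[0].estimate == pytest.approx(b, abs=1e-8)

    def test_type_one_error_calibrated_under_permutation(self):
        """Permuting the response makes each term's p-value uniform: rejection
        rate at 0.05 stays inside the binomial 95% band over 1000 replicates."""
        rng = np.random.default_rng(2)
        clin = toy_clinical(rng, n=100)
        design = build_design(clin)
        n = len(design)
        rejections = {t: 0 for t in ("progressor", "non_progressor", "draw_age")}
        n_rep = 1000
        y0 = rng.normal(size=n)
        for _ in range(n_rep):
            y = rng.permutation(y0)
            frame = pd.DataFrame({"cluster_1": y}, index=design.index)
            res = fit_cluster_models(scores_from_frame(frame), clin)
            for t in rejections:
                rejections[t] += res[res.term == t].iloc[0].p_value < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        for t, count in rejections.items():
            assert lo <= count <= hi, (t, count)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        clin = toy_clinical(rng, n=60)
        design = build_design(clin)
        y = rng.normal(size=len(design))
        frame = pd.DataFrame({"cluster_1": y}, index=design.index)
        res1 = fit_cluster_models(scores_from_frame(frame), clin)
        perm = rng.permutation(len(design))
        frame2 = frame.iloc[perm]
        res2 = fit_cluster_models(scores_from_frame(frame2), clin)
        pd.testing.assert_frame_equal(res1, res2)

    def test_collinear_design_named(self):
        rng = np.random.default_rng(4)
        clin = toy_clinical(rng, n=50)
        clin.table["hla_risk"] = "H"  # hla_H column becomes the constant
        design_y = rng.normal(size=(clin.table["hla_risk"] != "unknown").sum())
        frame = pd.DataFrame({"cluster_1": design_y}, index=build_design(clin).index)
        with pytest.raises(ValidationError, match="hla_H"):
            fit_cluster_models(scores_from_frame(frame), clin)

    def test_hla_unknown_excluded_listwise(self):
        rng = np.random.default_rng(5)
        clin = toy_clinical(rng, n=60)
        clin.table.iloc[:10, clin.table.columns.get_loc("hla_risk")] = "unknown"
        design = build_design(clin)
        assert len(design) == 50


class TestPerGlycan:
    def test_glycan_equal_to_draw_age_flags_age_only(self):
        rng = np.random.default_rng(6)
        clin = toy_clinical(rng, n=100)
        design = build_design(clin)
        values = pd.DataFrame(
            {
                "G001": design["draw_age"] + rng.normal(0, 0.01, len(design)),
                "G002": rng.lognormal(5, 1, len(design)),
            },
            index=design.index,
        )
        m = AcaMatrix(cohort="B", values=values)
        res = per_glycan_association(m, clin)
        g1 = res[res.glycan == "G001"]
        assert (~g1.significant).all()  # disease contrasts n.s. for the age glycan

    def test_radar_boundary_value(self):
        assert -np.log10(0.05) == pytest.approx(1.3010, abs=1e-4)

    def test_agrees_with_per_response_ols(self):
        rng = np.random.default_rng(7)
        clin = toy_clinical(rng, n=80)
        design = build_design(clin)
        values = pd.DataFrame(
            rng.lognormal(5, 1, size=(len(design), 5)),
            index=design.index,
            columns=[f"G{j + 1:03d}" for j in range(5)],
        )
        m = AcaMatrix(cohort="B", values=values)
        res = per_glycan_association(m, clin)
        import statsmodels.api as sm

        for g in values.columns:
            fit = sm.OLS(values[g].to_numpy(), design.to_numpy()).fit()
            j = list(design.columns).index("progressor")
            row = res[(res.glycan == g) & (res.contrast == "progressor")].iloc[0]
            assert row.p_value == pytest.approx(fit.pvalues[j], abs=1e-10)
            assert row.estimate == pytest.approx(fit.params[j], abs=1e-10)

    def test_power_on_planted_effect_glycans(self):
        """A planted block shift of 1.0 log-odds per unit score is detected in
        the progressor contrast in at least 80% of 200 replicates."""
        detected = 0
        n_rep = 200
        for rep in range(n_rep):
            spec = SynthSpec(
                seed=10_000 + rep,
                n_glycans=20,
                n_clusters_planted=2,
                cohort_sizes=(2, 112),
                effect_clusters=((1, 1.0),),
                bimodal_feature=(19, 0.05, 2.5),
                genotype_feature=(19, 0.0),
            )
            panel = generate_panel(spec)
            _, b, clin, _, truth = generate_cohorts(spec, panel)
            effect_glycans = [g for g, blk in truth.partition.items() if blk == 1][:1]
            sub = AcaMatrix(cohort="B", values=np.log(b.values[effect_glycans + ["G011"]]))
            res = per_glycan_association(sub, clin)
            row = res[
                (res.glycan == effect_glycans[0]) & (res.contrast == "progressor")
            ].iloc[0]
            detected += row.significant
        assert detected >= 0.8 * n_rep


class TestGenotype:
    def test_identical_groups_null(self):
        levels = pd.Series(np.ones(60), index=[f"s{i}" for i in range(60)])
        geno = pd.Series(
            ["G/G"] * 20 + ["G/A"] * 20 + ["A/A"] * 20, index=levels.index
        )
        res = genotype_comparison(levels, geno)
        assert res.tukey_p.eq(1.0).all()
        assert (res.mean_diff == 0).all()

    def test_planted_shift_detected_in_right_contrasts(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(120)]
        geno = pd.Series(["G/G"] * 40 + ["G/A"] * 40 + ["A/A"] * 40, index=idx)
        base = rng.normal(0, 1, 120)
        base[80:] += 5.0  # A/A shifted by 5 sigma
        res = genotype_comparison(pd.Series(base, index=idx), geno).set_index(
            ["group_1", "group_2"]
        )
        assert res.loc[("A/A", "G/A")].bh_p < 0.01
        assert res.loc[("A/A", "G/G")].bh_p < 0.01
        assert res.loc[("G/A", "G/G")].bh_p > 0.05

    def test_tukey_p_matches_studentized_range(self):
        """Tukey-adjusted p for a balanced 3-group toy set equals the
        studentized-range survival function evaluated from scratch."""
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(30)]
        geno = pd.Series(["G/G"] * 10 + ["G/A"] * 10 + ["A/A"] * 10, index=idx)
        vals = pd.Series(rng.normal(0, 1, 30) + np.repeat([0.0, 0.4, 1.0], 10), index=idx)
        res = genotype_comparison(vals, geno).set_index(["group_1", "group_2"])
        groups = {g: vals[(geno == g).values].to_numpy() for g in ("G/G", "G/A", "A/A")}
        n_per, k = 10, 3
        df = 30 - k
        mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
        for (a, b), row in res.iterrows():
            q = abs(groups[a].mean() - groups[b].mean()) / np.sqrt(mse / n_per)
            p_ref = stats.studentized_range.sf(q, k, df)
            assert row.tukey_p == pytest.approx(p_ref, abs=1e-6)

    def test_bh_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(10)
        idx = [f"s{i}" for i in range(90)]
        geno = pd.Series(["G/G"] * 30 + ["G/A"] * 30 + ["A/A"] * 30, index=idx)
        vals = pd.Series(rng.normal(0, 1, 90) + np.repeat([0, 0.3, 0.8], 30), index=idx)
        res = genotype_comparison(vals, geno)
        assert (res.bh_p >= res.tukey_p - 1e-12).all()
        by_raw = res.sort_values("tukey_p")["bh_p"].to_numpy()
        assert (np.diff(by_raw) >= -1e-12).all()

    def test_single_group_errors(self):
        levels = pd.Series(np.ones(5), index=[f"s{i}" for i in range(5)])
        geno = pd.Series(["G/G"] * 5, index=levels.index)
        with pytest.raises(ValidationError):
            genotype_comparison(levels, geno)
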