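import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfpulse import (
    CohortSpec,
    correlation_matrix,
    generate_cohort,
    partial_correlation,
    residualization_fit,
    run_association_report,
)
from csfpulse.assoc import (
    correlate,
    partial_correlation_arrays,
    residualization_arrays,
)


def random_table(rng, n=16, cols=("x", "y", "z")):
    return pd.DataFrame({c: rng.normal(size=n) for c in cols})


class TestCorrelate:
    def test_monotone_transform_gives_spearman_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        r, p, n = correlate(x, 2 * x + 1, method="spearman")
        assert r == 1.0
        assert p == 0.0
        assert n == 6

    @pytest.mark.parametrize("method", ["spearman", "pearson"])
    def test_agrees_with_scipy_reference(self, rng, method):
        for _ in range(50):
            x = rng.normal(size=16)
            y = rng.normal(size=16) + 0.3 * x
            r, p, _ = correlate(x, y, method=method)
            if method == "spearman":
                ref = stats.spearmanr(x, y)
            else:
                ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_correlation_small_at_large_n(self, rng):
        hits = 0
        for _ in range(100):
            x, y = rng.normal(size=5000), rng.normal(size=5000)
            r, _, _ = correlate(x, y)
            hits += abs(r) < 0.05
        assert hits >= 95

    def test_exact_permutation_p_perfect_rank(self):
        x = np.arange(7, dtype=float)
        r, p, _ = correlate(x, x**3, method="spearman", p_mode="exact")
        assert r == pytest.approx(1.0, abs=1e-12)
        # only the identity and the reversal reach |rho| = 1
        assert p == pytest.approx(2 / 5040)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            correlate(np.arange(3), np.arange(3))


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        table = random_table(rng, 20, cols=list("abcd"))
        m = correlation_matrix(table)
        assert np.allclose(m.rho.values, m.rho.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.rho.values), 1.0)
        assert np.allclose(np.diag(m.p.values), 0.0)

    def test_invariant_under_monotone_transform(self, rng):
        table = random_table(rng, 30)
        m1 = correlation_matrix(table, method="spearman")
        table2 = table.copy()
        table2["x"] = np.exp(table2["x"])  # strictly monotone
        m2 = correlation_matrix(table2, method="spearman")
        pd.testing.assert_frame_equal(m1.rho, m2.rho)

    def test_sparse_cell_reported_missing_not_zero(self, rng):
        table = random_table(rng, 10)
        table.loc[3:, "y"] = np.nan  # only 3 complete (x, y) pairs
        m = correlation_matrix(table)
        assert np.isnan(m.rho.loc["x", "y"])
        assert np.isnan(m.p.loc["x", "y"])
        assert m.n.loc["x", "y"] == 3
        assert np.isfinite(m.rho.loc["x", "z"])

    def test_significance_mask_and_bh(self, rng):
        t = generate_cohort(CohortSpec(n_subjects=16, seed=4))
        m = correlation_matrix(t, columns=["age_years", "peak", "csf_ab42_40_ratio"])
        sig = m.significant(0.05)
        assert not sig.values.diagonal().any()
        bh = m.bh_adjusted_p()
        off = ~np.eye(len(bh), dtype=bool)
        assert np.all(bh.values[off] >= m.p.values[off] - 1e-15)


class TestPartialCorrelation:
    def test_irrelevant_control_approaches_marginal(self, rng):
        n = 4000
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        r_marg, _, _ = correlate(x, y, method="pearson")
        r_part, _, _ = partial_correlation_arrays(x, y, z, method="pearson")
        assert r_part == pytest.approx(r_marg, abs=0.02)

    def test_collinear_control_undefined(self):
        z = np.arange(10.0)
        table = pd.DataFrame({"x": z, "y": z**2, "z": z})
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(table, "x", "y", "z", method="pearson")

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_agrees_with_pingouin_reference(self, rng, method):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(25):
            table = random_table(rng, 16)
            res = partial_correlation(table, "x", "y", "z", method=method)
            ref = pingouin.partial_corr(
                table, x="x", y="y", covar="z", method=method
            )
            p_col = "p-val" if "p-val" in ref.columns else "p_val"
            assert res.rho_partial == pytest.approx(ref["r"].iloc[0], abs=1e-10)
            assert res.p_value == pytest.approx(ref[p_col].iloc[0], abs=1e-8)
            assert res.df == 13

    def test_triplewise_deletion_reports_n(self, rng):
        table = random_table(rng, 20)
        table.loc[0:4, "z"] = np.nan
        res = partial_correlation(table, "x", "y", "z")
        assert res.n_used == 15
        assert res.df == 12


class TestResidualization:
    def test_exact_recovery_in_noiseless_linear_model(self, rng):
        n = 20
        age = rng.uniform(10, 27, n)
        metric = 5.0 - 0.3 * age + rng.normal(size=n)
        resid = metric - np.polyval(np.polyfit(age, metric, 1), age)
        biomarker = 0.7 + 2.5 * resid  # exactly linear in the residual
        est, se, t, p, df = residualization_arrays(metric, biomarker, age)
        assert est == pytest.approx(2.5, abs=1e-9)
        assert p < 1e-12

    def test_metric_fully_explained_by_age_rejected(self):
        age = np.arange(10.0, 26.0)
        table = pd.DataFrame(
            {"age_years": age, "m": 2 * age + 1, "b": np.random.default_rng(0).normal(size=16)}
        )
        with pytest.raises(ValueError, match="zero variance"):
            residualization_fit(table, "m", "b")

    def test_t_statistic_equals_pearson_partial_t(self, rng):
        # the twin-column identity: the age-adjusted slope's t equals the
        # Pearson partial-correlation t on the same triple
        for _ in range(50):
            table = random_table(rng, 16)
            est, se, t, p, df = residualization_arrays(
                table["x"].values, table["y"].values, table["z"].values
            )
            r, p_pc, df_pc = partial_correlation_arrays(
                table["x"].values, table["y"].values, table["z"].values,
                method="pearson",
            )
            t_pc = r * np.sqrt(df_pc / (1 - r**2))
            assert t == pytest.approx(t_pc, abs=1e-8)
            assert p == pytest.approx(p_pc, abs=1e-10)
            assert df == df_pc

    def test_null_effect_gives_flat_estimates(self):
        ests = []
        for seed in range(60):
            t = generate_cohort(
                CohortSpec(n_subjects=16, beta_flow_ratio=0.0, seed=seed)
            )
            res = residualization_fit(t, "peak", "csf_ab42_40_ratio")
            ests.append(res.estimate)
        assert abs(np.mean(ests)) < 3 * np.std(ests) / np.sqrt(len(ests)) + 1e-4


class TestAssociationReport:
    def test_empty_biomarker_set_allowed(self):
        t = generate_cohort(CohortSpec(seed=1))
        cols = ["subject_id", "age_years", "peak", "amplitude"]
        report = run_association_report(
            t[cols], metrics=["peak", "amplitude"], adjusted_biomarker=None
        )
        assert set(report.matrix.rho.columns) == {"age_years", "peak", "amplitude"}
        assert len(report.adjusted) == 2

    def test_row_permutation_invariance(self, rng):
        t = generate_cohort(CohortSpec(seed=2))
        shuffled = t.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r1 = run_association_report(t)
        r2 = run_association_report(shuffled)
        pd.testing.assert_frame_equal(r1.matrix.rho, r2.matrix.rho)
        pd.testing.assert_frame_equal(r1.adjusted, r2.adjusted)
        for key in r1.scatter:
            pd.testing.assert_frame_equal(r1.scatter[key], r2.scatter[key])

    def test_report_files_written(self, tmp_path):
        t = generate_cohort(CohortSpec(seed=3))
        report = run_association_report(t)
        report.write(tmp_path / "report")
        for name in (
            "correlation_rho.csv",
            "correlation_p.csv",
            "age_adjusted_table.csv",
            "report.json",
        ):
            assert (tmp_path / "report" / name).exists()

    def test_failed_cells_annotated_missing(self):
        t = generate_cohort(CohortSpec(seed=4))
        t.loc[3:, "csf_ab42_40_ratio"] = np.nan  # too few complete triples
        report = run_association_report(t)
        assert report.adjusted["partial_r"].isna().all()
        assert report.notes  # each failure is annotated
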