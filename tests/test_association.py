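"""Adjusted regression family: OLS statistics, effect sizes, Bonferroni control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractwmh import (
    CouplingConfig,
    ModelSpec,
    adjusted_r2,
    bonferroni_threshold,
    cohens_f,
    fit_adjusted_model,
    run_family,
    sample_covariates,
    simulate_association_table,
    standardized_beta,
)
from tractwmh.association import DEFAULT_COVARIATES
from tractwmh.errors import EstimationError, InputError


def _spec(**kw):
    return ModelSpec(outcome="suvr_IPL", predictor="log_wmh_SLF",
                     tract="SLF", region="IPL", **kw)


class TestScalarHelpers:
    @pytest.mark.parametrize("b1,sdx,sdy,expected", [(0.5, 2, 1, 1.0), (0.0, 3, 2, 0.0)])
    def test_standardized_beta_arithmetic(self, b1, sdx, sdy, expected):
        assert standardized_beta(b1, sdx, sdy) == pytest.approx(expected)

    def test_standardized_beta_zero_sd_rejected(self):
        with pytest.raises(EstimationError):
            standardized_beta(0.5, 0.0, 1.0)

    @pytest.mark.parametrize(
        "r2,n,p,expected",
        [(0.25, 60, 5, 1 - 0.75 * 59 / 54), (1.0, 30, 5, 1.0), (0.0, 20, 5, -5 / 14)],
    )
    def test_adjusted_r2_formula(self, r2, n, p, expected):
        assert adjusted_r2(r2, n, p) == pytest.approx(expected)

    def test_adjusted_r2_hand_value(self):
        assert adjusted_r2(0.25, 60, 5) == pytest.approx(0.1806, abs=5e-5)

    @given(r2=st.floats(0.0, 0.999), n=st.integers(10, 500))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_adjustment_never_exceeds_r2(self, r2, n):
        assert adjusted_r2(r2, n, 5) <= r2 + 1e-12

    @pytest.mark.parametrize("adj,expected", [(0.20, 0.5), (0.0, 0.0), (0.09, 0.3145)])
    def test_cohens_f_values(self, adj, expected):
        assert cohens_f(adj) == pytest.approx(expected, abs=5e-5)

    def test_cohens_f_clamps_negative_input(self):
        assert cohens_f(-0.12) == 0.0

    def test_cohens_f_rejects_r2_of_one(self):
        with pytest.raises(InputError):
            cohens_f(1.0)

    @given(a=st.floats(0, 0.95), b=st.floats(0.001, 0.04))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_cohens_f_strictly_increasing(self, a, b):
        assert cohens_f(a + b) > cohens_f(a)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 2, 0.005)])
    def test_bonferroni_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


class TestFitAdjustedModel:
    def test_noiseless_cohort_recovers_slope_exactly(self):
        coupling = CouplingConfig(b0=1.5, b1=0.3, noise_sd=0.0)
        tab = simulate_association_table(80, coupling, seed=21)
        res = fit_adjusted_model(tab, _spec())
        assert res.b1 == pytest.approx(0.3, abs=1e-7)
        assert res.b0 == pytest.approx(1.5, abs=1e-6)
        assert res.p_value < 1e-12
        assert res.significant

    def test_matches_normal_equations_oracle(self):
        """Coefficients, R^2, t-based p and CI recomputed from scratch."""
        from scipy import stats

        coupling = CouplingConfig(b0=1.5, b1=0.25, noise_sd=0.3)
        tab = simulate_association_table(70, coupling, seed=13)
        res = fit_adjusted_model(tab, _spec())

        cols = ["log_wmh_SLF", *DEFAULT_COVARIATES]
        X = np.column_stack([np.ones(len(tab))] + [tab[c].to_numpy(float) for c in cols])
        y = tab["suvr_IPL"].to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        s2 = resid @ resid / dof
        cov_beta = s2 * np.linalg.inv(X.T @ X)
        se1 = np.sqrt(cov_beta[1, 1])
        t1 = beta[1] / se1
        p1 = 2 * stats.t.sf(abs(t1), dof)
        tcrit = stats.t.ppf(0.975, dof)
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - (resid @ resid) / ss_tot

        assert res.b1 == pytest.approx(beta[1], abs=1e-8)
        assert res.b0 == pytest.approx(beta[0], abs=1e-8)
        assert res.p_value == pytest.approx(p1, abs=1e-10)
        assert res.ci_low == pytest.approx(beta[1] - tcrit * se1, abs=1e-8)
        assert res.ci_high == pytest.approx(beta[1] + tcrit * se1, abs=1e-8)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.adj_r2 == pytest.approx(adjusted_r2(r2, len(y), 5), abs=1e-10)

    def test_simple_regression_std_beta_equals_pearson_r(self, rng):
        x = rng.normal(0, 1, 200)
        y = 0.4 * x + rng.normal(0, 1, 200)
        df = pd.DataFrame({"y": y, "x": x})
        spec = ModelSpec(outcome="y", predictor="x", covariates=(), family_size=1)
        res = fit_adjusted_model(df, spec)
        assert res.std_beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_std_beta_invariant_to_affine_rescaling(self):
        coupling = CouplingConfig(b0=1.5, b1=0.25, noise_sd=0.3)
        tab = simulate_association_table(70, coupling, seed=31)
        base = fit_adjusted_model(tab, _spec()).std_beta
        scaled = tab.copy()
        scaled["log_wmh_SLF"] = 7.0 * scaled["log_wmh_SLF"] - 3.0
        scaled["suvr_IPL"] = 0.2 * scaled["suvr_IPL"] + 11.0
        assert fit_adjusted_model(scaled, _spec()).std_beta == pytest.approx(base, abs=1e-10)

    def test_constant_outcome_raises(self):
        tab = simulate_association_table(40, CouplingConfig(noise_sd=0.1), seed=2)
        tab["suvr_IPL"] = 1.5
        with pytest.raises(EstimationError):
            fit_adjusted_model(tab, _spec())

    def test_insufficient_n_raises(self):
        tab = simulate_association_table(6, CouplingConfig(noise_sd=0.1), seed=2)
        with pytest.raises(EstimationError):
            fit_adjusted_model(tab, _spec())


class TestRunFamily:
    @staticmethod
    def _tables(n=200, seed=0, b1_per_tract=None, noise_sd=0.15):
        coupling = CouplingConfig(b1=0.0, noise_sd=noise_sd)
        tab = simulate_association_table(n, coupling, seed=seed, b1_per_tract=b1_per_tract)
        suvr_rows, tract_rows = [], []
        from tractwmh import REGION_FOR_TRACT

        for tract, region in REGION_FOR_TRACT.items():
            suvr_rows.append(
                pd.DataFrame({"subject_id": tab["subject_id"], "region_name": region,
                              "suvr": tab[f"suvr_{region}"]})
            )
            tract_rows.append(
                pd.DataFrame({"subject_id": tab["subject_id"], "tract_name": tract,
                              "log_volume": tab[f"log_wmh_{tract}"]})
            )
        cov = tab[["subject_id", "age", "sex", "apoe_e4_count", "icv"]]
        return pd.concat(suvr_rows), pd.concat(tract_rows), cov

    def test_only_coupled_pair_flagged_significant(self):
        suvr, tracts, cov = self._tables(n=200, seed=3, b1_per_tract={"SLF": 0.3})
        results = run_family(suvr, tracts, cov)
        assert len(results) == 4
        by_tract = results.set_index("tract")
        assert bool(by_tract.loc["SLF", "significant"])
        for other in ("IFOF", "CING", "CING_Hippo"):
            assert not by_tract.loc[other, "significant"]

    def test_empty_tract_table_reports_all_pairs_inestimable(self):
        suvr, _, cov = self._tables(n=50, seed=4)
        empty = pd.DataFrame(columns=["subject_id", "tract_name", "log_volume"])
        with pytest.warns(UserWarning, match="not estimable"):
            results = run_family(suvr, empty, cov)
        assert len(results) == 4
        assert results["p_value"].isna().all()
        assert not results["significant"].any()

    def test_result_columns_are_table_shaped(self):
        suvr, tracts, cov = self._tables(n=60, seed=5)
        results = run_family(suvr, tracts, cov)
        assert list(results.columns) == [
            "region", "tract", "std_beta", "p_value", "adj_r2",
            "ci_low", "ci_high", "cohens_f", "n_used", "significant",
        ]
        assert (results["ci_low"] <= results["ci_high"]).all()
        assert (results["n_used"] == 60).all()


class TestStochasticCalibration:
    def test_familywise_false_positive_rate_controlled(self):
        """All slopes null: Bonferroni keeps the family-wise error near alpha
        times m/m, i.e. below .05, across replicate cohorts."""
        reps, fw_hits = 120, 0
        for r in range(reps):
            suvr, tracts, cov = TestRunFamily._tables(n=60, seed=10_000 + r)
            results = run_family(suvr, tracts, cov)
            fw_hits += int(results["significant"].any())
        # 4 independent tests at .0125 -> FWER <= .049; binomial 3-sigma margin
        assert fw_hits / reps < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
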