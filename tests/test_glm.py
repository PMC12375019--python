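"""Viability-scan GLM: IRLS fits, FDR, outlier extraction, scan behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybridscan.glm import (
    ScanResult,
    fdr_adjust,
    fit_glm_irls,
    het_scan,
    outlier_loci,
)
from conftest import make_matrix, make_meta


def newton_raphson_glm(y, X, family, n_iter=200):
    """Independent oracle: direct Newton-Raphson on the log-likelihood."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        if family == "binomial":
            mu = 1 / (1 + np.exp(-eta))
            w = mu * (1 - mu)
        else:
            mu = np.exp(eta)
            w = mu
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess + 1e-12 * np.eye(len(beta)), grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


class TestGlmClosedForms:
    def test_binomial_intercept_only(self):
        fit = fit_glm_irls(np.array([1, 1, 0, 0.0]), np.ones((4, 1)))
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)

    def test_binomial_two_by_two_log_odds_ratio(self):
        # successes 1/4 at x=0 and 3/4 at x=1: beta1 = log(9)
        y = np.array([1, 0, 0, 0, 1, 1, 1, 0.0])
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = fit_glm_irls(y, X)
        assert fit.params[1] == pytest.approx(np.log(9.0), abs=1e-8)

    def test_poisson_intercept_is_log_mean(self):
        fit = fit_glm_irls(np.array([1, 2, 3.0]), np.ones((3, 1)), family="poisson")
        assert fit.params[0] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_empty_response_rejected(self):
        with pytest.raises(ValueError):
            fit_glm_irls(np.array([]), np.zeros((0, 1)))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            fit_glm_irls(np.array([1.0]), np.ones((1, 1)), family="gamma")


class TestGlmAgainstOracles:
    @pytest.mark.parametrize("family", ["binomial", "poisson"])
    def test_matches_newton_raphson_on_random_data(self, family):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = rng.integers(30, 80)
            p = rng.integers(1, 4)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            beta_true = rng.normal(scale=0.5, size=p)
            eta = X @ beta_true
            if family == "binomial":
                y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
                if y.min() == y.max():
                    continue
            else:
                y = rng.poisson(np.exp(eta)).astype(float)
                if y.sum() == 0:
                    continue
            fit = fit_glm_irls(y, X, family=family)
            if not fit.converged:
                continue
            oracle = newton_raphson_glm(y, X, family)
            np.testing.assert_allclose(fit.params, oracle, atol=1e-6)

    def test_matches_statsmodels_wald_inference(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(200), rng.normal(size=200), rng.integers(0, 2, 200)])
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 - 0.8 * X[:, 1])))).astype(float)
        fit = fit_glm_irls(y, X)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params, res.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, res.bse, atol=1e-6)
        np.testing.assert_allclose(fit.pvalues, res.pvalues, atol=1e-6)


class TestGlmDegenerateCases:
    def test_perfect_separation_flagged(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        fit = fit_glm_irls(y, X)
        assert not fit.converged
        assert np.isnan(fit.pvalues).all()

    def test_aliased_column_dropped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        X = np.column_stack([np.ones(60), x, 2 * x])  # third column aliased
        y = (rng.random(60) < 0.5).astype(float)
        fit = fit_glm_irls(y, X)
        assert fit.aliased.sum() == 1
        assert np.isnan(fit.params[fit.aliased]).all()


class TestFdrAdjust:
    def test_bh_step_up_worked_example(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_strata_are_independent(self):
        p = np.array([0.025, 0.5, 0.025, 0.5])
        strata = np.array([0, 0, 1, 1])
        q = fdr_adjust(p, strata)
        np.testing.assert_allclose(q, [0.05, 0.5, 0.05, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))

    def test_nan_passthrough(self):
        q = fdr_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_q_dominates_p_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(2, 50))
        q = fdr_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_hand_bh_oracle(self):
        rng = np.random.default_rng(11)
        p = rng.random(17)
        # independent step-up implementation
        m = len(p)
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(fdr_adjust(p), expected)


class TestHetScan:
    def _cohort(self, seed=0, n=120, n_loci=8):
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 3, size=(n, n_loci)).astype(float)
        m = make_matrix(states)
        meta = make_meta(
            m,
            age=rng.integers(0, 3, n),
            sex=np.where(rng.random(n) < 0.5, "F", "M"),
        )
        return m, meta

    def test_scan_returns_row_per_locus(self):
        m, meta = self._cohort()
        scan = het_scan(m, meta)
        assert len(scan.table) == m.n_loci
        assert set(f"q_{t}" for t in scan.terms) <= set(scan.table.columns)

    def test_monomorphic_locus_skipped(self):
        m, meta = self._cohort()
        m.states[:, 0] = 1.0
        scan = het_scan(m, meta)
        row = scan.table.iloc[0]
        assert row["skipped"] and row["skip_reason"] == "monomorphic"

    def test_too_few_cases_skipped(self):
        m, meta = self._cohort()
        m.states[10:, 0] = np.nan
        scan = het_scan(m, meta)
        assert scan.table.iloc[0]["skip_reason"] == "too_few_cases"

    def test_invariant_to_individual_order(self):
        m, meta = self._cohort(seed=4)
        perm = np.random.default_rng(0).permutation(m.n_individuals)
        m2 = m.subset_individuals(perm)
        scan1 = het_scan(m, meta)
        scan2 = het_scan(m2, meta)
        np.testing.assert_allclose(
            scan1.table["p_age"].to_numpy(), scan2.table["p_age"].to_numpy(), atol=1e-9
        )

    def test_unknown_sex_dropped(self):
        m, meta = self._cohort(seed=5)
        meta.table.iloc[:30, meta.table.columns.get_loc("sex")] = "unknown"
        scan = het_scan(m, meta)
        assert (scan.table["n_used"] <= m.n_individuals - 30).all()

    def test_z_loci_form_their_own_stratum(self):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 3, size=(150, 10)).astype(float)
        chroms = ["chr1"] * 5 + ["chrZ"] * 5
        m = make_matrix(states, chroms=chroms)
        meta = make_meta(m, age=rng.integers(0, 3, 150), sex=["M"] * 150)
        scan = het_scan(m, meta)
        auto = scan.table[~scan.table["is_z"]]
        z = scan.table[scan.table["is_z"]]
        # q within the autosome stratum must not depend on Z p-values
        expected = fdr_adjust(auto["p_age"].to_numpy())
        np.testing.assert_allclose(auto["q_age"].to_numpy(), expected)
        assert len(z) == 5


class TestOutlierLoci:
    def _scan(self, q):
        table = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, len(q) + 1),
                "q_age": q,
                "p_age": q,
            }
        )
        return ScanResult(table, terms=["age"])

    def test_empty_when_none_below_alpha(self):
        assert outlier_loci(self._scan([0.2, 0.9]), "age").empty

    def test_boundary_is_strict(self):
        out = outlier_loci(self._scan([0.05, 0.01]), "age")
        assert out["pos"].tolist() == [2]

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            outlier_loci(self._scan([0.1]), "sex")
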