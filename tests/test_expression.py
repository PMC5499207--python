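import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rnadx.expression import (
    ExpressionOutlierModel,
    compute_zscore,
    fit_gene_nb,
)
from rnadx.io import ValidationError
from rnadx.preprocessing import build_design
from rnadx.simulate import SimulationConfig, simulate_expression_counts


def _toy_design(n, patient_idx=0):
    ann = pd.DataFrame(
        {
            "batch": ["b0"] * n,
            "sex": ["x0"] * n,
            "biopsy_site": ["t0"] * n,
            "group_id": [f"P{j}" for j in range(n)],
        },
        index=[f"S{j}" for j in range(n)],
    )
    return build_design(ann, f"P{patient_idx}")


class TestFitGeneNB:
    def test_null_effect_is_small_and_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        n = 100
        design = _toy_design(n)
        s = np.ones(n)
        betas, ps = [], []
        for _ in range(60):
            mu, alpha = 200.0, 0.05
            y = rng.poisson(rng.gamma(1 / alpha, alpha * mu, n))
            fit = fit_gene_nb(y, design, s)
            betas.append(fit.beta1)
            ps.append(fit.p)
        assert abs(np.mean(betas)) < 0.2
        # Wald p under the null should not pile up near zero
        assert np.mean(np.array(ps) < 0.1) < 0.3
        assert np.mean(ps) == pytest.approx(0.5, abs=0.15)

    def test_matches_poisson_glm_oracle_on_poisson_data(self):
        rng = np.random.default_rng(1)
        n = 80
        design = _toy_design(n)
        s = np.exp(rng.normal(0, 0.1, n))
        y = rng.poisson(50 * s)
        y[0] = 220  # make the contrast non-trivial
        fit = fit_gene_nb(y, design, s)
        oracle = sm.GLM(
            y, design.to_numpy(), family=sm.families.Poisson(),
            offset=np.log(s),
        ).fit()
        # dispersion collapses to the floor, so the NB fit is Poisson
        assert fit.alpha < 1e-6
        assert fit.beta1 * np.log(2) == pytest.approx(oracle.params[1], rel=1e-4)
        assert fit.p == pytest.approx(oracle.pvalues[1], rel=1e-3, abs=1e-12)

    def test_matches_statsmodels_nb_glm_at_fixed_dispersion(self):
        rng = np.random.default_rng(2)
        n = 60
        design = _toy_design(n)
        s = np.ones(n)
        alpha = 0.1
        y = rng.poisson(rng.gamma(1 / alpha, alpha * 120.0, n))
        fit = fit_gene_nb(y, design, s)
        oracle = sm.GLM(
            y,
            design.to_numpy(),
            family=sm.families.NegativeBinomial(alpha=fit.alpha),
        ).fit()
        assert fit.beta1 * np.log(2) == pytest.approx(oracle.params[1], abs=1e-5)
        assert fit.se_beta1 * np.log(2) == pytest.approx(oracle.bse[1], rel=1e-3)

    def test_true_fold_change_within_wald_interval(self):
        rng = np.random.default_rng(3)
        n = 60
        design = _toy_design(n)
        s = np.ones(n)
        true_l2fc = -4.0
        covered = 0
        reps = 40
        for _ in range(reps):
            mu = np.full(n, 400.0)
            mu[0] *= 2.0 ** true_l2fc
            alpha = 0.05
            y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
            fit = fit_gene_nb(y, design, s)
            lo = fit.beta1 - 1.96 * fit.se_beta1
            hi = fit.beta1 + 1.96 * fit.se_beta1
            covered += lo <= true_l2fc <= hi
        assert covered / reps >= 0.9

    def test_all_zero_gene_not_testable(self):
        design = _toy_design(10)
        fit = fit_gene_nb(np.zeros(10), design, np.ones(10))
        assert not fit.testable


class TestComputeZscore:
    def test_zero_fold_change_gives_zero(self):
        assert compute_zscore(0.0, [1.0, 2.0, 4.0]) == 0.0

    def test_homogeneity_in_sd(self):
        row = np.array([10.0, 20.0, 40.0, 80.0])
        z1 = compute_zscore(2.0, row)
        wide = 2.0 ** (2.0 * np.log2(row + 1)) - 1  # doubles the sd of log2(x+1)
        z2 = compute_zscore(2.0, wide)
        assert z2 == pytest.approx(z1 / 2.0)

    def test_toy_row_matches_direct_formula(self):
        row = np.array([3.0, 7.0, 15.0, 31.0])
        sd = np.std(np.log2(row + 1), ddof=1)
        assert compute_zscore(1.5, row) == pytest.approx(1.5 / sd)

    def test_zero_variance_flagged(self):
        assert np.isnan(compute_zscore(1.0, [5.0, 5.0, 5.0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            compute_zscore(1.0, [5.0, 6.0])


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_genes=150, n_samples=30, seed=13)
    sim = simulate_expression_counts(cfg)
    res = ExpressionOutlierModel(sim.counts, sim.annotation).fit()
    return sim, res


class TestCallOutliers:

    def test_outlier_flag_matches_thresholds(self, cohort):
        _, res = cohort
        calls = res.call_outliers()
        flagged = calls[calls.is_outlier]
        assert (flagged.padj < 0.05).all()
        assert (flagged.zscore.abs() > 3).all()

    def test_zscore_and_log2fc_share_sign(self, cohort):
        _, res = cohort
        tab = res.table.dropna(subset=["zscore"])
        nonzero = tab[tab.log2fc != 0]
        assert (np.sign(nonzero.zscore) == np.sign(nonzero.log2fc)).all()

    def test_forced_under_expression_reported_negative(self, cohort):
        sim, _ = cohort
        counts = sim.counts.copy()
        gene = counts.median(axis=1).idxmax()
        counts.loc[gene, "S003"] = 0
        res = ExpressionOutlierModel(counts, sim.annotation).fit(patient="S003")
        calls = res.call_outliers()
        hit = calls[(calls.gene == gene) & (calls["sample"] == "S003")].iloc[0]
        assert hit.is_outlier
        assert hit.zscore < 0 and hit.log2fc < 0

    def test_permuting_sample_order_changes_only_ordering(self, cohort):
        sim, _ = cohort
        rng = np.random.default_rng(0)
        perm = rng.permutation(sim.counts.columns)
        res_perm = ExpressionOutlierModel(
            sim.counts[perm], sim.annotation.loc[perm]
        ).fit()
        res = ExpressionOutlierModel(sim.counts, sim.annotation).fit()
        a = res.table.set_index(["gene", "sample"]).sort_index()
        b = res_perm.table.set_index(["gene", "sample"]).sort_index()
        num = ["log2fc", "zscore", "pvalue", "padj"]
        # summation order differs, so allow floating-point-level wiggle
        for col in num:
            np.testing.assert_allclose(
                a[col].to_numpy(), b[col].to_numpy(), rtol=1e-3, atol=1e-8
            )

    def test_refuses_tiny_cohorts(self):
        cfg = SimulationConfig(n_genes=30, n_samples=2, seed=1)
        sim = simulate_expression_counts(cfg)
        with pytest.raises(ValidationError):
            ExpressionOutlierModel(sim.counts, sim.annotation)
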