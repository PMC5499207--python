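import numpy as np
import pandas as pd
import pytest

from rnadx.simulate import (
    ConfigurationError,
    MixtureTruth,
    SimulationConfig,
    simulate_allele_counts,
    simulate_expression_counts,
    simulate_junction_table,
    simulate_mixture_observations,
    write_cohort,
)


class TestConfig:
    def test_rates_must_be_fractions(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(outlier_rate_expression=1.5)

    def test_pi_rows_must_sum_to_one(self):
        bad = MixtureTruth(pi=((0.5, 0.4, 0.2), (1, 0, 0), (1, 0, 0)))
        with pytest.raises(ConfigurationError):
            SimulationConfig(mixture_truth=bad)

    def test_dimensions_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=0)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_genes: 33\nn_samples: 5\nseed: 3\n")
        cfg = SimulationConfig.from_yaml(path)
        assert (cfg.n_genes, cfg.n_samples, cfg.seed) == (33, 5, 3)


class TestDeterminism:
    def test_same_seed_gives_identical_outputs(self, small_config):
        a = simulate_expression_counts(small_config)
        b = simulate_expression_counts(small_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert a.truth.expression_outliers == b.truth.expression_outliers

        ja = simulate_junction_table(small_config)
        jb = simulate_junction_table(small_config)
        pd.testing.assert_frame_equal(ja.junctions, jb.junctions)

        va = simulate_allele_counts(small_config)
        vb = simulate_allele_counts(small_config)
        pd.testing.assert_frame_equal(va.variants, vb.variants)

    def test_written_cohort_is_byte_reproducible(self, small_config, tmp_path):
        p1 = write_cohort(small_config, tmp_path / "a")
        p2 = write_cohort(small_config, tmp_path / "b")
        for key in ("counts", "junctions", "variants", "gtf", "truth"):
            assert open(p1[key], "rb").read() == open(p2[key], "rb").read()


class TestZeroRates:
    def test_zero_rates_give_empty_truth(self):
        cfg = SimulationConfig(
            n_genes=50,
            n_samples=8,
            n_junction_clusters=10,
            n_variants=50,
            outlier_rate_expression=0.0,
            splice_outlier_rate=0.0,
            mae_rate=0.0,
            seed=2,
        )
        assert simulate_expression_counts(cfg).truth.expression_outliers == set()
        assert simulate_junction_table(cfg).truth.splice_outliers == set()
        assert simulate_allele_counts(cfg).truth.mae_variants == set()


class TestExpressionGenerator:
    def test_counts_are_nonnegative_integers(self, expr_sim):
        k = expr_sim.counts.to_numpy()
        assert (k >= 0).all()
        assert np.issubdtype(k.dtype, np.integer)

    def test_truth_refers_to_existing_genes_and_samples(self, expr_sim):
        genes = set(expr_sim.counts.index)
        samples = set(expr_sim.counts.columns)
        for g, s in expr_sim.truth.expression_outliers:
            assert g in genes and s in samples

    def test_moment_recovery_against_generative_truth(self):
        cfg = SimulationConfig(
            n_genes=5000, n_samples=100, outlier_rate_expression=0.0, seed=17
        )
        sim = simulate_expression_counts(cfg)
        norm = sim.counts.to_numpy() / sim.size_factors.to_numpy()[None, :]
        mu_hat = norm.mean(axis=1)
        mu_true = sim.truth.gene_means.to_numpy()
        rel_err = np.abs(mu_hat - mu_true) / mu_true
        # covariate effects (log-sd 0.1) put a floor under the agreement
        assert np.median(rel_err) < 0.1

        # method-of-moments dispersion on well-expressed genes
        well = mu_true > 100
        v = norm.var(axis=1, ddof=1)
        alpha_hat = (v - mu_hat) / mu_hat**2
        alpha_true = sim.truth.gene_dispersions.to_numpy()
        rel = alpha_hat[well] / alpha_true[well]
        assert 0.8 < np.median(rel) < 1.3


class TestJunctionGenerator:
    def test_counts_nonnegative_and_annotation_matches(self, junc_sim):
        samples = [c for c in junc_sim.junctions.columns
                   if c not in ("chrom", "donor", "acceptor", "strand")]
        assert (junc_sim.junctions[samples].to_numpy() >= 0).all()

    def test_background_only_config_concentrates_psi_near_zero(self):
        flat = MixtureTruth(pi=((1, 0, 0),) * 3)
        cfg = SimulationConfig(
            n_junction_clusters=300, n_samples=10, splice_outlier_rate=0.0,
            mixture_truth=flat, seed=3,
        )
        obs = simulate_mixture_observations(cfg, n_obs=20000)
        psi = obs["n"] / obs["N"]
        expected = flat.alpha[0] / (flat.alpha[0] + flat.beta[0])
        assert psi.mean() == pytest.approx(expected, rel=0.1)

    def test_injected_clusters_recorded_with_event_class(self, junc_sim):
        assert len(junc_sim.truth.splice_outliers) > 0
        for cluster, sample, event in junc_sim.truth.splice_outliers:
            assert event == "new exon"
            assert sample in junc_sim.annotation.index


class TestAlleleGenerator:
    def test_af_labels_present_and_valid(self, allele_sim):
        af = allele_sim.variants["population_af"]
        assert ((af >= 0) & (af <= 1)).all()

    def test_balanced_variants_average_half(self):
        cfg = SimulationConfig(n_variants=2500, n_samples=4, mae_rate=0.0, seed=4)
        sim = simulate_allele_counts(cfg)
        ref = sim.variants[[c for c in sim.variants if c.endswith("_ref")]].to_numpy()
        alt = sim.variants[[c for c in sim.variants if c.endswith("_alt")]].to_numpy()
        total = ref + alt
        frac = alt[total > 0] / total[total > 0]
        assert frac.mean() == pytest.approx(0.5, abs=0.01)

    def test_injected_variants_are_alt_skewed(self, allele_sim):
        long_ids = {
            (v, s) for v, s in allele_sim.truth.mae_variants
        }
        assert long_ids
        wide = allele_sim.variants
        vid = (
            wide["chrom"].astype(str) + ":" + wide["pos"].astype(str)
            + ":" + wide["ref"] + ">" + wide["alt"]
        )
        lookup = {v: i for i, v in enumerate(vid)}
        fracs = []
        for v, s in long_ids:
            row = wide.iloc[lookup[v]]
            total = row[f"{s}_ref"] + row[f"{s}_alt"]
            if total >= 10:
                fracs.append(row[f"{s}_alt"] / total)
        assert np.mean(fracs) > 0.85
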