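"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators emulate the cohort data the pipeline consumes, each
with ground-truth labels so every downstream stage is testable at desk
scale:

* gene-level read counts: negative-binomial with log-normal baseline
  means, gamma-distributed dispersions, per-sample size factors and
  small multiplicative batch/sex/site effects; expression outliers are
  injected by scaling one sample's mean by 2**(z * sd) where sd is the
  gene's spread of log2 normalised expression (so the injected
  |Z-score| targets ``outlier_z``), alternating up/down by index.
* split-read junction tables: clusters of one canonical intron plus a
  cryptic exon pair; per junction a splice class (background / weak /
  strong) is drawn from group-specific mixing proportions given its
  annotation group s, psi from the class beta, and counts binomially
  given the cluster coverage. Aberrant splicing is injected by turning
  a weak cryptic exon pair strong in one sample (a private new exon
  arising from weak splice sites), with a matching minimal exon GTF.
* heterozygous-variant allele counts: coverage NB with mean 50 (so the
  >= 10-read filter is exercised), balanced variants binomial at 0.5,
  injected mono-allelic variants with alt fraction near 1, and
  population allele frequencies with a rare (< 0.001) subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "MixtureTruth",
    "SimulationConfig",
    "CohortTruth",
    "simulate_expression_counts",
    "simulate_junction_table",
    "simulate_allele_counts",
    "simulate_mixture_observations",
    "write_cohort",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class MixtureTruth:
    """True beta-binomial mixture: shapes shared across annotation
    groups, mixing proportions pi[s, c] group-specific. Component order
    is background, weak, strong."""

    alpha: tuple = (0.5, 1.2, 3.0)
    beta: tuple = (1500.0, 110.0, 1.5)
    # rows: s = 0, 1, 2 annotated sides; columns: background, weak, strong
    pi: tuple = (
        (0.80, 0.17, 0.03),
        (0.35, 0.35, 0.30),
        (0.05, 0.15, 0.80),
    )

    def validate(self):
        a, b = np.asarray(self.alpha), np.asarray(self.beta)
        if a.shape != (3,) or b.shape != (3,) or (a <= 0).any() or (b <= 0).any():
            raise ConfigurationError("mixture shapes must be three positive pairs")
        pi = np.asarray(self.pi)
        if pi.shape != (3, 3) or (pi < 0).any():
            raise ConfigurationError("pi must be a 3x3 nonnegative matrix")
        if not np.allclose(pi.sum(axis=1), 1.0, atol=1e-8):
            raise ConfigurationError("each pi row must sum to 1")


@dataclass
class SimulationConfig:
    """Cohort dimensions, injection rates and generative parameters."""

    n_genes: int = 1000
    n_samples: int = 60
    n_junction_clusters: int = 150
    n_variants: int = 1000
    covariate_levels: dict = field(
        default_factory=lambda: {"batch": 3, "sex": 2, "site": 2}
    )
    outlier_rate_expression: float = 0.002
    outlier_z: float = 6.0
    mixture_truth: MixtureTruth = field(default_factory=MixtureTruth)
    splice_outlier_rate: float = 0.05
    mae_rate: float = 0.003
    rare_af_rate: float = 0.1
    seed: int = 0

    # generative hyper-parameters (documented defaults)
    mean_log_mu: float = float(np.log(250.0))  # log-normal gene baseline
    sd_log_mu: float = 1.5
    dispersion_shape: float = 4.0  # gamma on the 1/alpha scale
    dispersion_scale: float = 5.0  # mean 1/alpha = 20 -> mean alpha ~ 0.05
    covariate_effect_sd: float = 0.1  # log-fold effects ~ N(0, 0.1)
    size_factor_sd: float = 0.2
    junction_coverage: float = 150.0  # cluster reads per sample (NB mean)
    annotated_side_prob: float = 0.85
    mae_coverage: float = 50.0  # NB mean, exercises the >= 10 filter
    mae_alt_beta: tuple = (50.0, 2.0)  # alt fraction of injected MAE variants

    def __post_init__(self):
        for name in ("n_genes", "n_samples", "n_junction_clusters", "n_variants"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in (
            "outlier_rate_expression",
            "splice_outlier_rate",
            "mae_rate",
            "rare_af_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if isinstance(self.mixture_truth, dict):
            self.mixture_truth = MixtureTruth(**self.mixture_truth)
        self.mixture_truth.validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{j:03d}" for j in range(self.n_samples)]


@dataclass
class CohortTruth:
    """Ground-truth labels of a simulated cohort."""

    expression_outliers: set = field(default_factory=set)  # (gene, sample)
    splice_outliers: set = field(default_factory=set)  # (cluster, sample, class)
    mae_variants: set = field(default_factory=set)  # (variant, sample)
    gene_means: pd.Series | None = None
    gene_dispersions: pd.Series | None = None
    junction_classes: dict = field(default_factory=dict)  # junction key -> class
    junction_groups: dict = field(default_factory=dict)  # junction key -> s

    def to_json(self, path) -> None:
        data = {
            "expression_outliers": sorted(map(list, self.expression_outliers)),
            "splice_outliers": sorted(map(list, self.splice_outliers)),
            "mae_variants": sorted(map(list, self.mae_variants)),
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            expression_outliers={tuple(x) for x in data["expression_outliers"]},
            splice_outliers={tuple(x) for x in data["splice_outliers"]},
            mae_variants={tuple(x) for x in data["mae_variants"]},
        )


COMPONENT_NAMES = ["background", "weak", "strong"]


def _annotation_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    levels = config.covariate_levels
    samples = config.sample_ids
    return pd.DataFrame(
        {
            "batch": rng.choice([f"b{i}" for i in range(levels.get("batch", 1))], len(samples)),
            "sex": rng.choice([f"x{i}" for i in range(levels.get("sex", 1))], len(samples)),
            "biopsy_site": rng.choice(
                [f"t{i}" for i in range(levels.get("site", 1))], len(samples)
            ),
            "group_id": samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )


class SimulatedExpression(NamedTuple):
    counts: pd.DataFrame
    annotation: pd.DataFrame
    size_factors: pd.Series
    truth: CohortTruth


def simulate_expression_counts(config: SimulationConfig) -> SimulatedExpression:
    """NB gene counts with covariate effects and injected outliers."""
    rng = np.random.default_rng([config.seed, 1])
    G, S = config.n_genes, config.n_samples
    genes = [f"G{i:05d}" for i in range(G)]
    samples = config.sample_ids
    annotation = _annotation_frame(config, rng)

    mu_base = np.exp(rng.normal(config.mean_log_mu, config.sd_log_mu, G))
    inv_alpha = rng.gamma(config.dispersion_shape, config.dispersion_scale, G)
    alpha = 1.0 / np.maximum(inv_alpha, 1e-3)
    size_factors = np.exp(rng.normal(0.0, config.size_factor_sd, S))
    size_factors /= np.exp(np.mean(np.log(size_factors)))

    log_mu = np.log(mu_base)[:, None] + np.log(size_factors)[None, :]
    for cov in ["batch", "sex", "biopsy_site"]:
        levels = sorted(annotation[cov].unique())
        effects = {
            lv: (np.zeros(G) if k == 0 else rng.normal(0, config.covariate_effect_sd, G))
            for k, lv in enumerate(levels)
        }
        for j, sample in enumerate(samples):
            log_mu[:, j] += effects[annotation.loc[sample, cov]]
    mu = np.exp(log_mu)

    def draw_nb(mu_arr, alpha_arr):
        lam = rng.gamma(1.0 / alpha_arr, alpha_arr * mu_arr)
        return rng.poisson(lam)

    counts = draw_nb(mu, alpha[:, None]).astype(np.int64)

    truth = CohortTruth(
        gene_means=pd.Series(mu_base, index=genes, name="true_mean"),
        gene_dispersions=pd.Series(alpha, index=genes, name="true_dispersion"),
    )

    n_inject = int(round(config.outlier_rate_expression * G * S))
    if n_inject > 0:
        norm = counts / size_factors[None, :]
        sd = np.std(np.log2(norm + 1.0), axis=1, ddof=1)
        q95 = np.percentile(counts, 95, axis=1)
        eligible = np.flatnonzero((q95 >= 10) & (sd > 0))
        pairs = rng.choice(eligible.size * S, size=min(n_inject, eligible.size * S),
                           replace=False)
        for k, flat in enumerate(np.sort(pairs)):
            gi = eligible[flat // S]
            sj = flat % S
            direction = 1.0 if k % 2 == 0 else -1.0
            new_mu = mu[gi, sj] * 2.0 ** (direction * config.outlier_z * sd[gi])
            # the injected count is the scaled mean itself, so the
            # realised |Z| hits the configured target instead of being
            # centred on it with a +/- 1 s.d. spread
            counts[gi, sj] = int(round(new_mu))
            truth.expression_outliers.add((genes[gi], samples[sj]))

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)
    sf = pd.Series(size_factors, index=samples, name="size_factor")
    return SimulatedExpression(counts_df, annotation, sf, truth)


class SimulatedJunctions(NamedTuple):
    junctions: pd.DataFrame
    exons: pd.DataFrame
    annotation: pd.DataFrame
    truth: CohortTruth


def _draw_class(rng, pi_row) -> int:
    return int(rng.choice(3, p=np.asarray(pi_row) / np.sum(pi_row)))


def simulate_junction_table(config: SimulationConfig) -> SimulatedJunctions:
    """Junction clusters from the beta-binomial splice-class mixture.

    Each cluster holds a canonical intron between two exons and a
    cryptic exon pair inside the intron. Injected aberrant events force
    the cryptic pair weak (and the flanking exons annotated) and turn
    it strong in one sample — the private-new-exon mechanism.
    """
    rng = np.random.default_rng([config.seed, 2])
    mix = config.mixture_truth
    alpha_c = np.asarray(mix.alpha)
    beta_c = np.asarray(mix.beta)
    pi = np.asarray(mix.pi)
    S = config.n_samples
    samples = config.sample_ids
    annotation = _annotation_frame(config, np.random.default_rng([config.seed, 1]))

    n_inject = int(round(config.splice_outlier_rate * config.n_junction_clusters))
    injected_clusters = set(
        rng.choice(config.n_junction_clusters, size=n_inject, replace=False).tolist()
    )

    truth = CohortTruth()
    rows = []
    exon_rows = []
    for k in range(config.n_junction_clusters):
        base = 10_000 * k + 1_000
        chrom = "chr1"
        D0, A0 = base + 200, base + 700  # canonical intron, 0-based half-open
        Xa, Xd = base + 400, base + 500  # cryptic exon [Xa, Xd) 0-based
        injected = k in injected_clusters

        ann_d = bool(rng.random() < config.annotated_side_prob)
        ann_a = bool(rng.random() < config.annotated_side_prob)
        if injected:
            ann_d = ann_a = True
        if ann_d:
            exon_rows.append((chrom, base + 1, base + 200, "+", f"gene{k}", f"gene{k}.e1"))
        if ann_a:
            exon_rows.append((chrom, base + 701, base + 900, "+", f"gene{k}", f"gene{k}.e2"))

        s_canon = int(ann_d) + int(ann_a)
        s_ja, s_jb = int(ann_d), int(ann_a)
        c_canon = _draw_class(rng, pi[s_canon])
        c_ja = _draw_class(rng, pi[s_ja])
        c_jb = _draw_class(rng, pi[s_jb])
        if injected:
            c_ja = c_jb = 1  # private exons originate from weak splice sites

        psi_canon = rng.beta(alpha_c[c_canon], beta_c[c_canon])
        psi_ja = rng.beta(alpha_c[c_ja], beta_c[c_ja])
        psi_jb = rng.beta(alpha_c[c_jb], beta_c[c_jb])

        coverage = rng.negative_binomial(
            5, 5 / (5 + config.junction_coverage), S
        )
        psi_mat = np.tile([psi_canon, psi_ja, psi_jb], (S, 1))
        if injected:
            target = int(rng.integers(S))
            psi_mat[target, 1] = rng.beta(alpha_c[2], beta_c[2])
            psi_mat[target, 2] = rng.beta(alpha_c[2], beta_c[2])
            cid = f"{chrom}:{D0}-{A0}"
            truth.splice_outliers.add((cid, samples[target], "new exon"))
        counts = rng.binomial(coverage[:, None], psi_mat)  # S x 3

        keys = [
            (chrom, D0, A0, "+"),
            (chrom, D0, Xa, "+"),
            (chrom, Xd, A0, "+"),
        ]
        classes = [c_canon, c_ja, c_jb]
        groups = [s_canon, s_ja, s_jb]
        for j, key in enumerate(keys):
            rows.append(dict(zip(io.JUNCTION_KEY, key)) | dict(zip(samples, counts[:, j])))
            truth.junction_classes[key] = COMPONENT_NAMES[classes[j]]
            truth.junction_groups[key] = groups[j]

    junctions = pd.DataFrame(rows)
    junctions[samples] = junctions[samples].astype(np.int64)
    exons = pd.DataFrame(
        exon_rows, columns=["chrom", "start", "end", "strand", "gene_id", "exon_id"]
    )
    return SimulatedJunctions(junctions, exons, annotation, truth)


def simulate_mixture_observations(
    config: SimulationConfig,
    n_obs: int = 50_000,
    group_weights: tuple = (1 / 3, 1 / 3, 1 / 3),
    mean_total: float = 2000.0,
) -> pd.DataFrame:
    """Draw (n, N, s) junction-side observations directly from the true
    beta-binomial mixture (for fitting and recovery checks); includes
    the true class per observation."""
    rng = np.random.default_rng([config.seed, 3])
    mix = config.mixture_truth
    s = rng.choice(3, size=n_obs, p=np.asarray(group_weights))
    pi = np.asarray(mix.pi)
    u = rng.random(n_obs)
    cum = np.cumsum(pi[s], axis=1)
    c = (u[:, None] > cum).sum(axis=1)
    psi = rng.beta(np.asarray(mix.alpha)[c], np.asarray(mix.beta)[c])
    N = np.maximum(rng.negative_binomial(2, 2 / (2 + mean_total), n_obs), 1)
    n = rng.binomial(N, psi)
    return pd.DataFrame(
        {"n": n, "N": N, "s": s, "true_class": [COMPONENT_NAMES[i] for i in c]}
    )


class SimulatedAlleleCounts(NamedTuple):
    variants: pd.DataFrame  # wide table, io.write_variants layout
    truth: CohortTruth


def simulate_allele_counts(config: SimulationConfig) -> SimulatedAlleleCounts:
    """Balanced vs mono-allelic heterozygous SNV allele counts."""
    rng = np.random.default_rng([config.seed, 4])
    V, S = config.n_variants, config.n_samples
    samples = config.sample_ids
    bases = ["A", "C", "G", "T"]
    chrom = "chr2"
    pos = 1_000 + 50 * np.arange(V)
    ref = [bases[i % 4] for i in range(V)]
    alt = [bases[(i + 1) % 4] for i in range(V)]

    is_rare = rng.random(V) < config.rare_af_rate
    af = np.where(
        is_rare,
        10.0 ** rng.uniform(-6, np.log10(9e-4), V),
        rng.uniform(0.01, 0.5, V),
    )

    coverage = rng.negative_binomial(5, 5 / (5 + config.mae_coverage), (V, S))
    alt_frac = np.full((V, S), 0.5)
    truth = CohortTruth()
    n_inject = int(round(config.mae_rate * V * S))
    if n_inject > 0:
        flat = rng.choice(V * S, size=n_inject, replace=False)
        a, b = config.mae_alt_beta
        vid = [f"{chrom}:{p}:{r}>{al}" for p, r, al in zip(pos, ref, alt)]
        for f in np.sort(flat):
            vi, sj = f // S, f % S
            alt_frac[vi, sj] = rng.beta(a, b)
            truth.mae_variants.add((vid[vi], samples[sj]))
    alt_counts = rng.binomial(coverage, alt_frac)
    ref_counts = coverage - alt_counts

    base = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "population_af": af}
    )
    count_cols = {}
    for j, sample in enumerate(samples):
        count_cols[f"{sample}_ref"] = ref_counts[:, j]
        count_cols[f"{sample}_alt"] = alt_counts[:, j]
    wide = pd.concat([base, pd.DataFrame(count_cols)], axis=1)
    return SimulatedAlleleCounts(wide, truth)


def write_cohort(config: SimulationConfig, out_dir) -> dict:
    """Simulate all three data types and write them (plus ground truth
    and the config) to ``out_dir``. Returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = simulate_expression_counts(config)
    junc = simulate_junction_table(config)
    mae = simulate_allele_counts(config)

    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "junctions": out / "junctions.tsv",
        "gtf": out / "exons.gtf",
        "variants": out / "variants.tsv",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }
    io.write_counts(expr.counts, paths["counts"])
    io.write_annotation(expr.annotation, paths["annotation"])
    io.write_junction_table(junc.junctions, paths["junctions"])
    io.write_gtf_exons(junc.exons, paths["gtf"])
    io.write_variants(mae.variants, paths["variants"])

    merged = CohortTruth(
        expression_outliers=expr.truth.expression_outliers,
        splice_outliers=junc.truth.splice_outliers,
        mae_variants=mae.truth.mae_variants,
    )
    merged.to_json(paths["truth"])
    cfg = asdict(config)
    Path(paths["config"]).write_text(json.dumps(cfg, indent=1, default=list))
    return {k: str(v) for k, v in paths.items()}
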