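"""Mono-allelic expression of heterozygous variants.

For each heterozygous SNV, the RNA-seq reference and alternative allele
read counts are compared with a negative-binomial model with the
dispersion fixed at alpha = 0.05 for all variants (roughly the average
gene-level dispersion). Each variant is tested independently, without
phasing, within its own sample. A variant is called mono-allelically
expressed when its alternative allele frequency is >= 0.8 — the allele-
frequency form of a 4-fold allelic imbalance cutoff, 4 / (1 + 4) = 0.8
— and its Benjamini-Hochberg adjusted p-value (per sample, across the
testable variants of that sample) is < 0.05. Variants need at least 10
reads of transcriptome coverage to be testable, and rare MAE variants
are those with population minor allele frequency < 0.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bh_adjust

__all__ = [
    "filter_testable",
    "test_mae",
    "call_mae",
    "allele_fraction_cutoff",
    "MAEModel",
    "MAEResults",
]

FIXED_DISPERSION = 0.05
MIN_COVERAGE = 10
AF_THRESHOLD = 0.8
PADJ_THRESHOLD = 0.05
RARE_AF = 0.001


def allele_fraction_cutoff(fold_change: float = 4.0) -> float:
    """Allele-frequency form of an allelic fold-change cutoff:
    r / (1 + r). The default 4-fold imbalance gives exactly 0.8."""
    return fold_change / (1.0 + fold_change)


def filter_testable(variants: pd.DataFrame, min_coverage: int = MIN_COVERAGE) -> pd.DataFrame:
    """Keep variants with at least ``min_coverage`` reads on the
    transcriptome (ref + alt)."""
    total = variants["ref_count"] + variants["alt_count"]
    return variants[total >= min_coverage]


def _nb_loglik_scalar(k: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB log-likelihood per observation; the mu -> 0 limit for k = 0 is
    0 (the saturated contribution of a zero count)."""
    from scipy.special import gammaln

    r = 1.0 / alpha
    k = np.asarray(k, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(k + r)
            - gammaln(r)
            - gammaln(k + 1.0)
            + r * np.log(r / (r + mu))
            + np.where(k > 0, k * np.log(mu / (r + mu)), 0.0)
        )
    return ll


def test_mae(ref_count, alt_count, alpha: float = FIXED_DISPERSION):
    """Likelihood-ratio test of allelic imbalance for one variant.

    The two allele counts are modelled as NB with fixed dispersion
    ``alpha``; the null shares one mean (its MLE is the average of the
    two counts), the alternative gives each allele its own mean (the
    saturated fit, finite at zero counts without any pseudocount). The
    statistic is chi-square with 1 df. Returns (log2_alt_ref, p);
    log2_alt_ref is +/-inf when one allele has no reads and both-zero
    variants are not testable (nan, nan).

    Vectorised over arrays of counts.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    scalar = ref.ndim == 0
    ref, alt = np.atleast_1d(ref), np.atleast_1d(alt)
    total = ref + alt
    mu0 = total / 2.0
    ll_null = _nb_loglik_scalar(ref, mu0, alpha) + _nb_loglik_scalar(alt, mu0, alpha)
    ll_sat = _nb_loglik_scalar(ref, ref, alpha) + _nb_loglik_scalar(alt, alt, alpha)
    lrt = np.maximum(0.0, 2.0 * (ll_sat - ll_null))
    p = stats.chi2.sf(lrt, df=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(alt) - np.log2(ref)
    log2fc = np.where((ref == 0) & (alt == 0), np.nan, log2fc)
    p = np.where(total == 0, np.nan, p)
    if scalar:
        return float(log2fc[0]), float(p[0])
    return log2fc, p


def call_mae(
    results: pd.DataFrame,
    af_threshold: float = AF_THRESHOLD,
    padj_threshold: float = PADJ_THRESHOLD,
    rare_af: float = RARE_AF,
) -> pd.DataFrame:
    """Apply BH adjustment per sample and the MAE filter cascade.

    ``results`` holds one row per testable (variant, sample) with
    ref_count, alt_count, population_af, pvalue and log2_alt_ref. Adds
    alt_frequency, padj, is_mae (alternative-allele MAE), is_mae_ref
    (reference-direction imbalance, reported separately) and is_rare.
    """
    out = results.copy()
    total = out["ref_count"] + out["alt_count"]
    out["alt_frequency"] = out["alt_count"] / total.where(total > 0)
    out["padj"] = np.nan
    for sample, rows in out.groupby("sample").groups.items():
        out.loc[rows, "padj"] = bh_adjust(out.loc[rows, "pvalue"].to_numpy())
    sig = out["padj"] < padj_threshold
    out["is_mae"] = (out["alt_frequency"] >= af_threshold) & sig
    out["is_mae_ref"] = (out["alt_frequency"] <= 1.0 - af_threshold) & sig
    out["is_rare"] = out["population_af"] < rare_af
    return out


class MAEModel:
    """Mono-allelic expression scan over a cohort's heterozygous SNVs.

    Built from a long-format table with one row per (variant, sample):
    variant_id, sample, population_af, ref_count, alt_count (see
    :func:`rnadx.io.variants_to_long` for the wide TSV layout).
    """

    def __init__(self, variants: pd.DataFrame, min_coverage: int = MIN_COVERAGE):
        required = {"variant_id", "sample", "population_af", "ref_count", "alt_count"}
        missing = required - set(variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        self.variants = variants.reset_index(drop=True)
        self.min_coverage = min_coverage

    def fit(
        self,
        alpha: float = FIXED_DISPERSION,
        af_threshold: float = AF_THRESHOLD,
        padj_threshold: float = PADJ_THRESHOLD,
        rare_af: float = RARE_AF,
    ) -> "MAEResults":
        testable = filter_testable(self.variants, self.min_coverage).copy()
        log2fc, p = test_mae(
            testable["ref_count"].to_numpy(),
            testable["alt_count"].to_numpy(),
            alpha=alpha,
        )
        testable["log2_alt_ref"] = log2fc
        testable["pvalue"] = p
        table = call_mae(
            testable,
            af_threshold=af_threshold,
            padj_threshold=padj_threshold,
            rare_af=rare_af,
        )
        cascade = (
            table.groupby("sample")
            .apply(
                lambda d: pd.Series(
                    {
                        "testable": len(d),
                        "mae": int(d["is_mae"].sum()),
                        "rare_mae": int((d["is_mae"] & d["is_rare"]).sum()),
                    }
                ),
                include_groups=False,
            )
            if len(table)
            else pd.DataFrame(columns=["testable", "mae", "rare_mae"])
        )
        return MAEResults(self, table, cascade)


class MAEResults:
    """Per-(variant, sample) allelic-imbalance tests with the filter
    cascade counts (testable -> MAE -> rare MAE) per sample."""

    def __init__(self, model: MAEModel, table: pd.DataFrame, cascade: pd.DataFrame):
        self.model = model
        self.table = table.reset_index(drop=True)
        self.cascade = cascade

    def mae_variants(self, rare_only: bool = False) -> pd.DataFrame:
        sel = self.table["is_mae"]
        if rare_only:
            sel = sel & self.table["is_rare"]
        return self.table[sel].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Mono-allelic expression (fixed-dispersion NB test, BH FDR)",
            f"  variant-sample pairs tested: {len(self.table)}",
            f"  MAE calls:                   {int(self.table['is_mae'].sum())}",
            f"  rare MAE calls:              {int((self.table['is_mae'] & self.table['is_rare']).sum())}",
        ]
        if len(self.cascade):
            lines.append(
                f"  median per sample (testable/MAE/rare): "
                f"{self.cascade['testable'].median():g}/"
                f"{self.cascade['mae'].median():g}/"
                f"{self.cascade['rare_mae'].median():g}"
            )
        return "\n".join(lines)
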