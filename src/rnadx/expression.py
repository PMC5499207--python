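"""Aberrant expression: per-gene one-vs-rest negative-binomial testing.

For each patient of interest, every gene is tested for differential
expression between that patient (including biological replicates) and
all other samples with a negative-binomial GLM

    K_ij ~ NB(mu_ij, alpha_i),  mu_ij = s_j * q_ij,
    log2 q_ij = beta_i0 + beta_i1 * x_j + covariates,

where s_j is the sample size factor, x_j the patient indicator and
alpha_i a gene-specific dispersion. beta_i1 is the log2 fold change of
the patient against the rest; a Wald test on beta_i1 gives the p-value,
Hochberg-adjusted across all genes tested for that patient. Z-scores
divide the fold change by the standard deviation of the gene's
normalised expression, and an expression outlier requires both a large
effect (|Z| > 3) and significance (adjusted p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _nbglm
from .io import ValidationError
from .multitest import hochberg_adjust
from .preprocessing import build_design, prepare

__all__ = [
    "NBFit",
    "fit_gene_nb",
    "compute_zscore",
    "call_expression_outliers",
    "ExpressionOutlierModel",
    "ExpressionOutlierResults",
]

LN2 = np.log(2.0)


@dataclass
class NBFit:
    """Single-gene NB GLM fit for the one-vs-rest contrast."""

    beta0: float
    beta1: float  # log2 fold change, patient vs rest
    alpha: float
    se_beta1: float  # on the log2 scale
    p: float
    testable: bool = True
    mom_fallback: bool = False


def fit_gene_nb(counts_row, design: pd.DataFrame, size_factors) -> NBFit:
    """Fit the NB GLM for a single gene row.

    The design must contain the intercept first and the patient
    indicator second. All-zero genes are flagged not testable.
    """
    y = np.asarray(counts_row, dtype=float)[None, :]
    s = np.asarray(size_factors, dtype=float)
    X = np.asarray(design, dtype=float)
    if y.sum() == 0:
        return NBFit(np.nan, np.nan, np.nan, np.nan, np.nan, testable=False)
    fit = _nbglm.fit_nb_batch(y, X, s)
    se_ln = np.sqrt(fit["cov"][0, 1, 1])
    wald = fit["beta"][0, 1] / se_ln
    p = 2.0 * stats.norm.sf(abs(wald))
    return NBFit(
        beta0=fit["beta"][0, 0] / LN2,
        beta1=fit["beta"][0, 1] / LN2,
        alpha=float(fit["alpha"][0]),
        se_beta1=se_ln / LN2,
        p=float(p),
        testable=True,
        mom_fallback=bool(fit["mom_fallback"][0]),
    )


def compute_zscore(log2fc, normalized_counts_row) -> float:
    """Z-score: fold change divided by the s.d. of the gene's normalised
    expression, log2(count / s + 1), across all samples."""
    norm = np.asarray(normalized_counts_row, dtype=float)
    if norm.size < 3:
        raise ValidationError("need at least 3 samples to compute a Z-score")
    sd = np.std(np.log2(norm + 1.0), ddof=1)
    if sd == 0:
        return np.nan
    return float(log2fc / sd)


class ExpressionOutlierModel:
    """One-vs-rest NB expression-outlier model for a cohort.

    Parameters
    ----------
    counts : DataFrame, genes x samples, integer read counts.
    annotation : DataFrame indexed by sample id with batch, sex,
        biopsy_site and group_id columns (group_id ties replicates of
        one patient together).
    min_reads, quantile : expressed-gene filter; genes whose
        ``quantile`` percentile across samples is below ``min_reads``
        are discarded before testing.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        annotation: pd.DataFrame,
        min_reads: int = 10,
        quantile: float = 0.95,
        covariates: list[str] | None = None,
    ):
        self.covariates = list(covariates) if covariates is not None else None
        if counts.shape[1] < 3:
            raise ValidationError("need at least 3 samples for one-vs-rest testing")
        annotation = annotation.loc[counts.columns]
        self.counts, self.size_factors = prepare(
            counts, annotation, min_reads=min_reads, quantile=quantile
        )
        self.annotation = annotation
        norm = self.counts.to_numpy(float) / self.size_factors.to_numpy()[None, :]
        self._log_norm = np.log2(norm + 1.0)
        self._sd = np.std(self._log_norm, axis=1, ddof=1)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.annotation["group_id"].astype(str)))

    def _test_patient(
        self,
        pat: str,
        yt: np.ndarray,
        s: np.ndarray,
        X_cov: np.ndarray,
        groups: np.ndarray,
        gene_rows: np.ndarray,
        cell_mask: np.ndarray | None,
    ) -> dict:
        """One-vs-rest test of ``pat`` for the testable gene rows in
        ``gene_rows``, with the null fitted on the other samples
        (optionally excluding masked outlier cells)."""
        mask = groups == pat
        m = int(mask.sum())
        y_sub = yt[gene_rows]
        w = None
        if cell_mask is not None:
            w = (~cell_mask[gene_rows][:, ~mask]).astype(float)
        rest = _nbglm.fit_nb_batch(y_sub[:, ~mask], X_cov[~mask], s[~mask], w=w)
        alpha = rest["alpha"]
        eta_pat = np.log(s[mask])[None, :] + rest["beta"] @ X_cov[mask].T
        mu_pat = np.exp(np.clip(eta_pat, -30.0, 30.0))  # (G, m)
        k = y_sub[:, mask]
        # predictive widening: the tail is judged against the mean
        # *predicted* from the other samples, so its estimation
        # variance Var[x'beta] is added to the dispersion, and the
        # dispersion's own estimation uncertainty is integrated out by
        # 3-point Gauss-Hermite quadrature over its profile-likelihood
        # posterior on the log scale
        var_pred = np.einsum("mi,gij,mj->gm", X_cov[mask], rest["cov"], X_cov[mask])
        sd_la = np.sqrt(rest["log_alpha_var"])[:, None]
        log_alpha = np.log(alpha)[:, None]
        p_exact = np.zeros_like(k)
        for node, weight in ((0.0, 2.0 / 3.0), (np.sqrt(3.0), 1.0 / 6.0),
                             (-np.sqrt(3.0), 1.0 / 6.0)):
            a_node = np.exp(log_alpha + node * sd_la)
            r = 1.0 / (a_node + var_pred)
            pnb = r / (r + mu_pat)
            p_less = stats.nbinom.cdf(k, r, pnb)
            p_more = stats.nbinom.sf(k - 1.0, r, pnb)
            p_exact += weight * np.minimum(
                1.0, 2.0 * np.minimum(p_less, p_more)
            )
        pmin = p_exact.min(axis=1)
        p_outlier = 1.0 - (1.0 - pmin) ** m if m > 1 else pmin[:]

        if m == 1:
            # the one-vs-rest GLM factorises: covariate coefficients
            # equal the leave-one-out fit and the patient coefficient
            # saturates its own observation
            k1 = k[:, 0]
            beta1 = np.log(np.maximum(k1, 1e-13)) - eta_pat[:, 0]
            beta1 = np.clip(beta1, -30.0, 30.0)
            with np.errstate(divide="ignore"):
                wt = k1 / (1.0 + alpha * k1)
                var1 = 1.0 / wt + var_pred[:, 0]
            se_ln = np.sqrt(var1)
            mom_fallback = rest["mom_fallback"]
        else:
            design = build_design(self.annotation, pat, covariates=self.covariates)
            full = _nbglm.fit_nb_batch(yt[gene_rows], design.to_numpy(float), s)
            beta1 = full["beta"][:, 1]
            se_ln = np.sqrt(full["cov"][:, 1, 1])
            mom_fallback = full["mom_fallback"]
        with np.errstate(invalid="ignore"):
            wald_p = 2.0 * stats.norm.sf(np.abs(beta1 / se_ln))
        return {
            "log2fc": beta1 / LN2,
            "se_log2fc": se_ln / LN2,
            "pvalue": p_outlier,
            "wald_pvalue": wald_p,
            "dispersion": alpha,
            "mom_fallback": mom_fallback,
        }

    def fit(self, patient: str | None = None) -> "ExpressionOutlierResults":
        """Fit the one-vs-rest NB model for one patient or every patient.

        The null (covariate-only) NB fit for each contrast uses only the
        *other* samples, so the tested patient's own counts cannot drag
        the fitted means or inflate the dispersion of its own test. The
        outlier-test p-value (``pvalue``, the one entering the Hochberg
        adjustment) is the exact two-sided NB tail probability of the
        patient's count under that leave-patient-out fit — calibrated in
        the extreme tails where the single-observation Wald
        approximation is not; for patients with m replicate samples the
        per-sample tail probabilities are Sidak-combined
        (1 - (1 - min p)^m). A second pass masks the cells called in the
        first pass out of every other patient's null fit, so one
        sample's aberrant count cannot distort its neighbours' tests.

        log2fc, its standard error and ``wald_pvalue`` come from the
        one-vs-rest GLM (exact single-sample factorisation, or the full
        IRLS fit for multi-replicate patients).
        """
        patients = [str(patient)] if patient is not None else self.patients
        y = self.counts.to_numpy(dtype=float)
        s = self.size_factors.to_numpy()
        testable = (y.sum(axis=1) > 0) & (self._sd > 0)
        yt = y[testable]
        X_cov = build_design(
            self.annotation, patient=None, covariates=self.covariates
        ).to_numpy(float)
        groups = self.annotation["group_id"].astype(str).to_numpy()
        all_rows = np.arange(yt.shape[0])

        def assemble(pat, rows, res, base=None):
            if base is None:
                tab = pd.DataFrame(
                    {
                        "gene": self.counts.index,
                        "sample": pat,
                        "testable": testable,
                        "log2fc": np.nan,
                        "zscore": np.nan,
                        "pvalue": np.nan,
                        "wald_pvalue": np.nan,
                        "se_log2fc": np.nan,
                        "dispersion": np.nan,
                        "mom_fallback": False,
                    }
                )
            else:
                tab = base
            idx = np.flatnonzero(testable)[rows]
            tab.loc[idx, "log2fc"] = res["log2fc"]
            tab.loc[idx, "zscore"] = res["log2fc"] / self._sd[testable][rows]
            tab.loc[idx, "pvalue"] = res["pvalue"]
            tab.loc[idx, "wald_pvalue"] = res["wald_pvalue"]
            tab.loc[idx, "se_log2fc"] = res["se_log2fc"]
            tab.loc[idx, "dispersion"] = res["dispersion"]
            tab.loc[idx, "mom_fallback"] = res["mom_fallback"]
            return tab

        # pass 1: plain leave-patient-out scan
        tabs = {}
        for pat in patients:
            res = self._test_patient(pat, yt, s, X_cov, groups, all_rows, None)
            tab = assemble(pat, all_rows, res)
            tab["padj"] = hochberg_adjust(tab["pvalue"].to_numpy())
            tabs[pat] = tab

        # pass 2: mask first-pass outlier cells out of the null fits
        cell_mask = np.zeros(yt.shape, dtype=bool)
        gene_pos = {g: i for i, g in enumerate(self.counts.index[testable])}
        for pat, tab in tabs.items():
            called = tab[
                (tab["padj"] < 0.05) & (tab["zscore"].abs() > 3.0)
            ]["gene"]
            cols = np.flatnonzero(groups == pat)
            for g in called:
                if g in gene_pos:
                    cell_mask[gene_pos[g], cols] = True
        if cell_mask.any():
            for pat in patients:
                rest_cols = groups != pat
                rows = np.flatnonzero(cell_mask[:, rest_cols].any(axis=1))
                if rows.size == 0:
                    continue
                res = self._test_patient(
                    pat, yt, s, X_cov, groups, rows, cell_mask
                )
                tabs[pat] = assemble(pat, rows, res, base=tabs[pat])
                tabs[pat]["padj"] = hochberg_adjust(
                    tabs[pat]["pvalue"].to_numpy()
                )

        table = pd.concat(tabs.values(), ignore_index=True)
        return ExpressionOutlierResults(self, table)


class ExpressionOutlierResults:
    """Per-(gene, patient) one-vs-rest estimates with Hochberg-adjusted
    p-values; ``call_outliers`` applies the |Z| and adjusted-p
    thresholds."""

    def __init__(self, model: ExpressionOutlierModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def call_outliers(
        self, padj_threshold: float = 0.05, z_threshold: float = 3.0
    ) -> pd.DataFrame:
        tab = self.table.copy()
        tab["is_outlier"] = (
            (tab["padj"] < padj_threshold)
            & (tab["zscore"].abs() > z_threshold)
        ).fillna(False)
        return tab.sort_values(["sample", "padj"], kind="stable").reset_index(
            drop=True
        )

    def outliers(self, **thresholds) -> pd.DataFrame:
        tab = self.call_outliers(**thresholds)
        return tab[tab["is_outlier"]].reset_index(drop=True)

    def summary(self) -> str:
        calls = self.call_outliers()
        per_sample = calls.groupby("sample")["is_outlier"].sum()
        lines = [
            "Aberrant expression (one-vs-rest NB GLM, Hochberg FWER)",
            f"  genes tested:      {self.table['gene'].nunique()}",
            f"  patients tested:   {self.table['sample'].nunique()}",
            f"  outlier calls:     {int(calls['is_outlier'].sum())}",
            f"  median per sample: {per_sample.median():g}",
        ]
        return "\n".join(lines)


def call_expression_outliers(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    patient: str | None = None,
    padj_threshold: float = 0.05,
    z_threshold: float = 3.0,
) -> pd.DataFrame:
    """Run the expression-outlier scan; returns the full result table
    sorted by adjusted p-value with an ``is_outlier`` flag."""
    model = ExpressionOutlierModel(counts, annotation)
    results = model.fit(patient=patient)
    return results.call_outliers(
        padj_threshold=padj_threshold, z_threshold=z_threshold
    )
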