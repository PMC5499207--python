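"""Expressed-gene filtering, size factors and design matrices.

The one-vs-rest tests downstream operate on a filtered count matrix with
per-sample size factors (DESeq-style median-of-ratios) and a design
matrix carrying an intercept, the patient-of-interest indicator and
dummy-coded technical covariates (batch, sex, biopsy site).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ANNOTATION_COLUMNS, ValidationError, validate_annotation

__all__ = [
    "filter_expressed_genes",
    "estimate_size_factors",
    "build_design",
]

COVARIATES = ["batch", "sex", "biopsy_site"]


def filter_expressed_genes(
    counts: pd.DataFrame, min_reads: int = 10, quantile: float = 0.95
) -> pd.DataFrame:
    """Drop genes that are not expressed.

    A gene is kept when the ``quantile`` percentile (linear interpolation)
    of its counts across samples is at least ``min_reads``; a gene whose
    95th percentile is below 10 reads is considered not expressed.
    Gene order is preserved and the operation is idempotent.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError("empty count matrix")
    if counts.shape[1] < 2:
        raise ValidationError("need at least 2 samples to filter genes")
    q = np.percentile(counts.to_numpy(), 100 * quantile, axis=1)
    return counts.loc[q >= min_reads]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    For each gene with strictly positive counts in every sample, the
    per-sample ratio to the gene's geometric mean is formed; a sample's
    size factor is the median of these ratios.
    """
    k = counts.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has nonzero counts in all samples; filter the matrix "
            "to expressed genes first"
        )
    logk = np.log(k[all_pos])
    log_geo_mean = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - log_geo_mean, axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


def build_design(
    annotation: pd.DataFrame,
    patient: str | None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Design matrix for the one-vs-rest contrast of one patient.

    ``patient`` is a ``group_id`` (or a sample id, resolved to its
    group), so biological replicates of the same patient all receive the
    indicator; ``patient=None`` builds the covariate-only (null) design
    without the indicator column. Covariates are dummy-coded against
    their lexicographically smallest level; single-level covariates are
    dropped silently, and a covariate column that makes the matrix rank
    deficient (e.g. the patient is the only member of a batch) is
    dropped with a warning.
    """
    if covariates is None:
        covariates = COVARIATES
    design = pd.DataFrame({"intercept": 1.0}, index=annotation.index)
    if patient is not None:
        groups = annotation["group_id"].astype(str)
        patient = str(patient)
        if patient in set(groups):
            indicator = (groups == patient).astype(float)
        elif patient in annotation.index:
            indicator = (groups == groups.loc[patient]).astype(float)
        else:
            raise ValidationError(f"patient {patient!r} not found in annotation")
        design["patient"] = indicator
    for cov in covariates:
        if cov not in annotation.columns:
            raise ValidationError(f"covariate {cov!r} missing from annotation")
        levels = sorted(annotation[cov].astype(str).unique())
        for level in levels[1:]:  # reference = lexicographically smallest
            col = (annotation[cov].astype(str) == level).astype(float)
            candidate = design.assign(**{f"{cov}_{level}": col})
            if np.linalg.matrix_rank(candidate.to_numpy()) == candidate.shape[1]:
                design = candidate
            else:
                warnings.warn(
                    f"dropping covariate column {cov}={level}: confounded "
                    f"with the patient indicator or other covariates"
                )
    return design


def prepare(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    min_reads: int = 10,
    quantile: float = 0.95,
) -> tuple[pd.DataFrame, pd.Series]:
    """Validate, filter and normalise a cohort.

    Size factors are computed after gene filtering.
    """
    validate_annotation(counts, annotation)
    filtered = filter_expressed_genes(counts, min_reads=min_reads, quantile=quantile)
    size_factors = estimate_size_factors(filtered)
    return filtered, size_factors
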