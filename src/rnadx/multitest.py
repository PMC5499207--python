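"""Multiple-testing adjustments.

Hochberg's step-up procedure controls the family-wise error rate and is
used for the expression and splicing one-vs-rest scans; Benjamini-
Hochberg controls the false discovery rate and is used for the
mono-allelic expression calls. Both delegate to
:func:`statsmodels.stats.multitest.multipletests`; NaN p-values are
propagated and excluded from the family size.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["hochberg_adjust", "bh_adjust"]


def _adjust(p_values, method: str) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if (p[mask] < 0).any() or (p[mask] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method=method)[1]
    return out


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up FWER adjustment, returned in input order."""
    return _adjust(p_values, "simes-hochberg")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    return _adjust(p_values, "fdr_bh")
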