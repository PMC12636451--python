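"""Multiple-testing adjustments shared by the survival and transcriptome layers.

Holm is implemented directly (the step-down definition vectorizes to a few
array operations); Benjamini-Hochberg delegates to
:func:`statsmodels.stats.multitest.multipletests`.  Both wrappers validate
their inputs the same way and return adjusted p-values in input order.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["holm_adjust", "bh_adjust"]


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D sequence")
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sorted ascending, the i-th p-value is multiplied by (n - i), running
    maxima enforce monotonicity and values are capped at 1, so adjusted
    values are always >= the raw values.
    """
    p = _validate_p(p)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.minimum(np.maximum.accumulate((n - np.arange(n)) * p[order]), 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), input order."""
    p = _validate_p(p)
    return multipletests(p, method="fdr_bh")[1]
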