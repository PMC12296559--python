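"""Benjamini-Hochberg false-discovery-rate control."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["fdr_bh"]


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values).

    NaN entries (undefined tests) are excluded from the family and returned
    as NaN.  The adjusted values satisfy q >= p elementwise.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        flat = p[mask]
        if np.any((flat < 0) | (flat > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[mask] = multipletests(flat, method="fdr_bh")[1]
    return q
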