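"""Time-resolved correlation between pre-trial and post-trial cluster power.

For a pair of clusters -- one from a pre-trial interval (post-S1 or pre-S2),
one from the post-S2 interval -- the correlation matrix holds, at element
(i, j), the Pearson correlation across participants between the pre-trial
cluster's band power at time i and the post-trial cluster's band power at
time j.  Two-sided p-values come from the exact t transform of r; the
Benjamini-Hochberg family is all cells of one cluster-pair matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .fdr import fdr_bh
from .source_lcmv import ClusterTimeSeries

__all__ = ["CorrMatrix", "timewise_correlation", "fdr_threshold"]


@dataclass(frozen=True)
class CorrMatrix:
    """Pre x post time-resolved correlation with p and BH q values."""

    r: np.ndarray
    p: np.ndarray
    q: np.ndarray
    pre_times: np.ndarray
    post_times: np.ndarray
    n: int
    pair: str = ""


def timewise_correlation(
    pre: ClusterTimeSeries, post: ClusterTimeSeries, pair: str = ""
) -> CorrMatrix:
    """Pearson correlation of pre- and post-trial power across participants.

    Requires the same participants in the same order in both series and at
    least four of them.  Time points with zero variance yield undefined
    (NaN) cells that are excluded from the BH family.
    """
    x = pre.power
    y = post.power
    if x.shape[0] != y.shape[0]:
        raise ValueError("pre and post series cover different participant counts")
    if pre.participants and post.participants and pre.participants != post.participants:
        raise ValueError("pre and post series cover different participants")
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least four participants")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(sx, sy)
    r[~np.isfinite(r)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p[np.isnan(r)] = np.nan
    q = fdr_bh(p)
    return CorrMatrix(r, p, q, pre.times, post.times, n, pair)


def fdr_threshold(corr: CorrMatrix, alpha: float = 0.01) -> np.ndarray:
    """Boolean significance mask ``q < alpha`` (NaN cells are False)."""
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(corr.q, nan=np.inf) < alpha
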