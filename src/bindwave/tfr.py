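"""Morlet wavelet time-frequency analysis and sensor-level binding contrasts.

Power is computed per trial by complex Morlet convolution (width = number of
wavelet cycles, default 5).  Wavelets are L2-normalized (unit total energy),
so the expected power of white noise is flat across frequencies.  Samples
closer to the epoch edge than half the wavelet support are flagged invalid.

The binding contrast compares feature repetition (FR) against feature
alternation (FA) band power per channel and time bin with paired t-tests,
Benjamini-Hochberg corrected across the channel x bin family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from mne.time_frequency import morlet as _mne_morlet
from mne.time_frequency import tfr_array_morlet

from .epochs import EpochSet
from .fdr import fdr_bh

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}

__all__ = ["BANDS", "TFRResult", "morlet_tfr", "band_power", "fr_vs_fa_ttests"]


@dataclass(frozen=True)
class TFRResult:
    """Time-frequency power.

    ``power`` has shape (n_trials, n_channels, n_freqs, n_times) in uV^2;
    ``valid[f, t]`` is False where the wavelet at frequency ``f`` overhangs
    the epoch edge.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    width: float
    valid: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", f)


def morlet_tfr(
    epochs: EpochSet, freqs, width: float = 5.0, decim: int = 1
) -> TFRResult:
    """Per-trial Morlet wavelet power of an epoch set.

    ``width`` is the number of cycles of the wavelet at every frequency.
    ``decim`` keeps every ``decim``-th output sample to bound memory.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    nyq = epochs.sfreq / 2.0
    if freqs.max() >= nyq:
        raise ValueError("max frequency must be below Nyquist")
    half_support = np.array(
        [(len(w) // 2) for w in _mne_morlet(epochs.sfreq, freqs, n_cycles=width)]
    )
    if 2 * half_support.max() + 1 > epochs.n_samples:
        raise ValueError("epoch too short for the lowest-frequency wavelet")
    power = tfr_array_morlet(
        epochs.data.astype(float),
        sfreq=epochs.sfreq,
        freqs=freqs,
        n_cycles=width,
        output="power",
        decim=decim,
        zero_mean=True,
    )
    times = epochs.times[::decim]
    idx = np.arange(epochs.n_samples)[::decim]
    valid = (idx[None, :] >= half_support[:, None]) & (
        idx[None, :] < epochs.n_samples - half_support[:, None]
    )
    return TFRResult(power, freqs, times, epochs.sfreq / decim, width, valid)


def band_power(tfr: TFRResult, band, window_ms) -> np.ndarray:
    """Mean power over a frequency band and half-open time window.

    ``band`` is a (low, high) pair in Hz or a named band; frequencies with
    low <= f <= high enter the average.  Returns (n_trials, n_channels).
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    fmask = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    if not fmask.any():
        raise ValueError(f"no computed frequency inside band [{lo}, {hi}] Hz")
    a, b = window_ms
    tmask = (tfr.times >= a - 1e-9) & (tfr.times < b - 1e-9)
    if not tmask.any():
        raise ValueError(f"window [{a}, {b}) ms outside the epoch")
    return tfr.power[:, :, fmask][..., tmask].mean(axis=(2, 3))


def _binned(power_t: np.ndarray, times: np.ndarray, window_ms, bin_ms: float):
    """Average a (..., n_times) array into consecutive time bins."""
    a, b = window_ms
    edges = np.arange(a, b + 1e-9, bin_ms)
    if len(edges) < 2:
        raise ValueError("window shorter than one bin")
    out, starts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (times >= lo - 1e-9) & (times < hi - 1e-9)
        if m.any():
            out.append(power_t[..., m].mean(axis=-1))
            starts.append(lo)
    return np.stack(out, axis=-1), np.asarray(starts)


def fr_vs_fa_ttests(
    power_fr: np.ndarray,
    power_fa: np.ndarray,
    ch_names,
    bin_starts,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired FR-vs-FA t-tests per channel and time bin with BH correction.

    ``power_fr``/``power_fa`` have shape (n_participants, n_channels,
    n_bins): per-participant band power under feature repetition and feature
    alternation within one (band, response-relation) analysis.  The BH family
    is all channel x bin cells of that analysis; cells with degenerate
    difference variance are excluded from the family.
    """
    fr = np.asarray(power_fr, dtype=float)
    fa = np.asarray(power_fa, dtype=float)
    if fr.shape != fa.shape:
        raise ValueError("FR and FA arrays must have identical shape")
    if fr.shape[0] < 2:
        raise ValueError("need at least two participants")
    d = fr - fa
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd > 0, t, np.nan)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), n - 1)
    q = fdr_bh(p)
    ch_idx, bin_idx = np.meshgrid(
        np.arange(len(ch_names)), np.arange(len(bin_starts)), indexing="ij"
    )
    return pd.DataFrame(
        {
            "channel": np.asarray(ch_names)[ch_idx.ravel()],
            "bin_start_ms": np.asarray(bin_starts)[bin_idx.ravel()],
            "mean_diff": mean.ravel(),
            "t": t.ravel(),
            "p": p.ravel(),
            "q": q.ravel(),
            "significant": q.ravel() < alpha,
        }
    )
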