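"""Frequency-domain source power via DICS beamforming.

The DICS beamformer projects a sensor-level cross-spectral density (CSD)
matrix onto source space.  For each voxel with lead field ``l`` the scalar
unit-gain spatial filter is

    w = (l' Cr^-1 l)^-1 l' Cr^-1,    Cr = C + lambda * mean(diag(C)) * I,

where the dipole orientation minimizing ``u' Re(L' Cr^-1 L) u`` (i.e.
maximizing output power) is selected per voxel.  A common filter is computed
from the CSD pooled over all conditions and then applied to per-condition
CSDs, avoiding condition-dependent filter bias.  The feature
repetition/alternation contrast is the normalized power ratio

    ratio = (P_FR - P_FA) / (P_FR + P_FA),

bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .epochs import EpochSet
from .headmodel import LeadField

__all__ = [
    "CSDMatrix",
    "SpatialFilters",
    "SourcePowerMap",
    "csd",
    "dics_filters",
    "source_power",
    "neural_activity_index",
    "power_ratio",
]


@dataclass(frozen=True)
class CSDMatrix:
    """Trial-averaged cross-spectral density over a band and time window."""

    values: np.ndarray
    band: tuple
    window_ms: tuple
    ch_names: tuple
    n_trials: int
    taper: str = "hanning"

    def __post_init__(self):
        v = np.asarray(self.values)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("CSD must be square")
        if np.abs(v - v.conj().T).max() > 1e-10 * max(np.abs(v).max(), 1e-300):
            raise ValueError("CSD must be Hermitian")


@dataclass(frozen=True)
class SpatialFilters:
    """Unit-gain scalar beamformer weights, one row per voxel."""

    weights: np.ndarray  # (n_voxels, n_channels)
    orientations: np.ndarray  # (n_voxels, 3)
    voxel_indices: np.ndarray  # indices into the source grid
    lam: float
    band: tuple | None = None
    ch_names: tuple = ()


@dataclass(frozen=True)
class SourcePowerMap:
    """Per-voxel band power (uV^2), NAI, or FR/FA power ratio."""

    values: np.ndarray
    voxel_indices: np.ndarray
    band: tuple | None
    toi_ms: tuple | None
    kind: str = "power"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.kind == "power" and np.any(v < -1e-12 * max(abs(v).max(), 1e-300)):
            raise ValueError("power must be nonnegative")
        if self.kind == "ratio" and np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValueError("ratio must lie in [-1, 1]")


def csd(epochs: EpochSet, band, window_ms) -> CSDMatrix:
    """Hanning-tapered FFT cross-spectral density, averaged over trials and
    over the FFT bins inside ``band``.

    The window must contain at least one cycle of the band's lowest
    frequency.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("invalid band")
    sl = epochs.window_slice(*window_ms)
    seg = epochs.data[:, :, sl].astype(float)
    n = seg.shape[-1]
    if n / epochs.sfreq < 1.0 / lo:
        raise ValueError("window shorter than one cycle of the band's lowest frequency")
    taper = scipy.signal.windows.hann(n, sym=False)
    seg = seg - seg.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(seg * taper, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.sfreq)
    bins = np.where((freqs >= lo) & (freqs <= hi))[0]
    if bins.size == 0:
        raise ValueError("no FFT bin inside the band; lengthen the window")
    x = spec[:, :, bins]  # (trials, channels, bins)
    scale = 1.0 / (np.sum(taper**2) * epochs.sfreq)
    c = np.einsum("tib,tjb->ij", x, x.conj()) * scale / (epochs.n_trials * bins.size)
    c = 0.5 * (c + c.conj().T)
    return CSDMatrix(c, (float(lo), float(hi)), tuple(window_ms), epochs.ch_names, epochs.n_trials)


def _unit_gain_filters(mat: np.ndarray, leadfield: LeadField, lam: float, voxels=None):
    """Shared DICS/LCMV algebra: regularize, invert, optimize orientation.

    Returns (weights, orientations, voxel_indices).  ``mat`` may be complex
    (CSD) or real (covariance).
    """
    n_ch = mat.shape[0]
    if leadfield.n_channels != n_ch:
        raise ValueError("lead field and matrix channel counts differ")
    mu = float(np.real(np.diag(mat)).mean())
    reg = mat + lam * mu * np.eye(n_ch)
    cond = np.linalg.cond(reg)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"regularized matrix is numerically singular (condition number {cond:.3g})"
        )
    inv = np.linalg.inv(reg)
    vox = np.arange(leadfield.n_voxels) if voxels is None else np.asarray(voxels)
    L = leadfield.gain[:, vox, :]  # (n_ch, n_vox, 3)
    A = np.einsum("ij,jvk->ivk", inv, L)  # Cinv @ L
    G = np.real(np.einsum("ivk,ivm->vkm", L.conj(), A))  # (n_vox, 3, 3)
    evals, evecs = np.linalg.eigh(G)
    # unit-gain output power is 1/(u' G u): minimize the quadratic form
    u = evecs[:, :, 0]  # (n_vox, 3)
    l_eff = np.einsum("ivk,vk->iv", L, u)  # (n_ch, n_vox)
    a_eff = inv @ l_eff
    denom = np.einsum("iv,iv->v", l_eff.conj(), a_eff)
    w = (a_eff / denom[None, :]).T.conj()  # (n_vox, n_ch); w l = 1
    return w, u, vox


def dics_filters(
    csd_common: CSDMatrix, leadfield: LeadField, lam: float = 0.05, voxels=None
) -> SpatialFilters:
    """Common DICS spatial filters from a pooled (all-conditions) CSD."""
    w, u, vox = _unit_gain_filters(csd_common.values, leadfield, lam, voxels)
    return SpatialFilters(w, u, vox, lam, csd_common.band, csd_common.ch_names)


def source_power(filters: SpatialFilters, csd_condition: CSDMatrix) -> SourcePowerMap:
    """Voxel power ``Re(w C w')`` of a condition-specific CSD."""
    if filters.ch_names and tuple(csd_condition.ch_names) != tuple(filters.ch_names):
        raise ValueError("filters and CSD use different channel sets")
    w = filters.weights
    p = np.real(np.einsum("vi,ij,vj->v", w, csd_condition.values, w.conj()))
    p = np.clip(p, 0.0, None)
    return SourcePowerMap(p, filters.voxel_indices, csd_condition.band, csd_condition.window_ms, "power")


def neural_activity_index(filters: SpatialFilters, csd_condition: CSDMatrix) -> SourcePowerMap:
    """Unit-noise-gain normalized power: P / (lambda*mean(diag(C)) * |w|^2).

    Divides each voxel's beamformer power by the power the filter would pass
    from spatially white noise at the regularization level, suppressing the
    depth bias of raw power maps.
    """
    p = source_power(filters, csd_condition)
    noise = filters.lam * float(np.real(np.diag(csd_condition.values)).mean())
    wnorm = np.real(np.einsum("vi,vi->v", filters.weights, filters.weights.conj()))
    return SourcePowerMap(
        p.values / (noise * wnorm), filters.voxel_indices, p.band, p.toi_ms, "nai"
    )


def power_ratio(p_fr: SourcePowerMap, p_fa: SourcePowerMap) -> SourcePowerMap:
    """Normalized FR/FA contrast (P_FR - P_FA)/(P_FR + P_FA), 0 where both 0."""
    if p_fr.values.shape != p_fa.values.shape or not np.array_equal(
        p_fr.voxel_indices, p_fa.voxel_indices
    ):
        raise ValueError("maps must share the same voxels")
    a, b = p_fr.values, p_fa.values
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("power inputs must be nonnegative")
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, (a - b) / np.where(tot > 0, tot, 1.0), 0.0)
    return SourcePowerMap(ratio, p_fr.voxel_indices, p_fr.band, p_fr.toi_ms, "ratio")
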