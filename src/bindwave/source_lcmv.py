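"""Time-domain LCMV reconstruction of cluster time series.

After DBSCAN identifies coherent source clusters, an LCMV beamformer (same
unit-gain algebra as DICS, but on the real time-domain covariance of a time
interval of interest) reconstructs voxel time courses restricted to cluster
members.  Voxel series are averaged within a cluster, then Morlet band power
is computed per trial and averaged, giving one band-power time course per
participant and cluster.  The post-S2 binding interaction is the
participant-wise difference of the FR and FA courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .headmodel import LeadField
from .source_dics import SpatialFilters, _unit_gain_filters
from .tfr import TFRResult, band_power, morlet_tfr

__all__ = [
    "ClusterTimeSeries",
    "covariance",
    "lcmv_filters",
    "cluster_timeseries",
    "stack_participants",
    "interaction_course",
]


@dataclass(frozen=True)
class ClusterTimeSeries:
    """Band-power time course of one cluster.

    ``power`` has shape (n_participants, n_times) in uV^2; ``tag`` names the
    condition or condition contrast the course belongs to.
    """

    power: np.ndarray
    times: np.ndarray
    band: tuple
    toi_ms: tuple
    tag: str = ""
    participants: tuple = ()

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.power, dtype=float))
        object.__setattr__(self, "power", p)
        if p.shape[1] != len(self.times):
            raise ValueError("power and times lengths differ")


def covariance(epochs: EpochSet, toi_ms) -> np.ndarray:
    """Trial-pooled channel covariance of a TOI, demeaned per trial."""
    sl = epochs.window_slice(*toi_ms)
    seg = epochs.data[:, :, sl].astype(float)
    if seg.shape[-1] < 2:
        raise ValueError("TOI must contain at least two samples")
    seg = seg - seg.mean(axis=-1, keepdims=True)
    n_obs = seg.shape[0] * seg.shape[-1]
    return np.einsum("tis,tjs->ij", seg, seg) / n_obs


def lcmv_filters(
    cov: np.ndarray, leadfield: LeadField, lam: float = 0.05, voxels=None
) -> SpatialFilters:
    """Unit-gain scalar LCMV filters from a real TOI covariance."""
    cov = np.asarray(cov, dtype=float)
    w, u, vox = _unit_gain_filters(cov, leadfield, lam, voxels)
    return SpatialFilters(np.real(w), u, vox, lam, None, leadfield.sensors.names)


def cluster_timeseries(
    filters: SpatialFilters,
    epochs: EpochSet,
    cluster_voxels,
    band,
    toi_ms,
    width: float = 5.0,
    decim: int = 1,
) -> ClusterTimeSeries:
    """Trial-averaged band-power course of one cluster for one participant.

    The cluster's voxel series (filter output) are averaged into a single
    virtual-channel time course per trial before the wavelet transform;
    power is averaged over trials and restricted to the TOI.
    """
    cluster_voxels = np.asarray(cluster_voxels, dtype=int)
    if cluster_voxels.size == 0:
        raise ValueError("empty cluster")
    pos = {int(v): i for i, v in enumerate(filters.voxel_indices)}
    try:
        rows = [pos[int(v)] for v in cluster_voxels]
    except KeyError as err:
        raise ValueError(f"cluster voxel {err} has no spatial filter") from None
    w = np.real(filters.weights[rows])  # (n_cvox, n_ch)
    series = np.einsum("vi,tis->tvs", w, epochs.data.astype(float)).mean(axis=1)
    virtual = EpochSet(
        data=series[:, None, :],
        sfreq=epochs.sfreq,
        t0_offset=epochs.t0_offset,
        ch_names=("cluster",),
        conditions=epochs.conditions,
        participant=epochs.participant,
        group=epochs.group,
    )
    freqs = _band_freqs(band)
    tfr = morlet_tfr(virtual, freqs, width=width, decim=decim)
    lo_t, hi_t = toi_ms
    tmask = (tfr.times >= lo_t - 1e-9) & (tfr.times < hi_t - 1e-9)
    if not tmask.any():
        raise ValueError("TOI outside the epoch")
    band_lo, band_hi = _band_range(band)
    fmask = (tfr.freqs >= band_lo) & (tfr.freqs <= band_hi)
    course = tfr.power[:, 0][:, fmask][:, :, tmask].mean(axis=(0, 1))
    return ClusterTimeSeries(
        course[None, :],
        tfr.times[tmask],
        (band_lo, band_hi),
        tuple(toi_ms),
        participants=(epochs.participant,),
    )


def _band_range(band):
    from .tfr import BANDS

    return BANDS[band] if isinstance(band, str) else tuple(band)


def _band_freqs(band):
    lo, hi = _band_range(band)
    step = max(1.0, (hi - lo) / 4.0)
    return np.arange(lo, hi + 1e-9, step)


def stack_participants(courses) -> ClusterTimeSeries:
    """Stack single-participant courses into one group-level object."""
    if not courses:
        raise ValueError("no courses to stack")
    first = courses[0]
    for c in courses[1:]:
        if c.power.shape[1] != first.power.shape[1] or c.band != first.band:
            raise ValueError("courses are not aligned")
    return ClusterTimeSeries(
        np.vstack([c.power for c in courses]),
        first.times,
        first.band,
        first.toi_ms,
        first.tag,
        tuple(p for c in courses for p in c.participants),
    )


def interaction_course(cts_fr: ClusterTimeSeries, cts_fa: ClusterTimeSeries) -> ClusterTimeSeries:
    """Participant-wise FR - FA band-power difference course."""
    if cts_fr.power.shape != cts_fa.power.shape:
        raise ValueError("FR and FA courses must have identical shape")
    if cts_fr.participants and cts_fr.participants != cts_fa.participants:
        raise ValueError("FR and FA courses cover different participants")
    if not np.allclose(cts_fr.times, cts_fa.times):
        raise ValueError("FR and FA courses use different time axes")
    return ClusterTimeSeries(
        cts_fr.power - cts_fa.power,
        cts_fr.times,
        cts_fr.band,
        cts_fr.toi_ms,
        tag="FR-FA",
        participants=cts_fr.participants,
    )
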