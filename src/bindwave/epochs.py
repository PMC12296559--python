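"""Epoched EEG container, basic preprocessing, and automated epoch rejection.

Epochs are stored as ``trials x channels x samples`` arrays in microvolts,
time-locked to the probe stimulus (S2).  Time windows throughout the package
are half-open ``[a, b)`` in milliseconds relative to S2, so the sample at
t = 0 belongs to the post-S2 period and not to the pre-S2 period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import h5py
import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

CONDITIONS = ("RRFR", "RRFA", "RAFR", "RAFA")
CONDITION_SET = frozenset(CONDITIONS) | {"other"}

__all__ = [
    "CONDITIONS",
    "CONDITION_SET",
    "EpochSet",
    "resample",
    "bandpass_notch",
    "reject_epochs",
    "read_brainvision_epochs",
]


@dataclass(frozen=True)
class EpochSet:
    """Epoched multichannel EEG with per-trial condition labels.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Sensor signals in microvolts.
    sfreq : float
        Sampling frequency in Hz.
    t0_offset : float
        Time of the first sample in ms relative to S2 onset.
    ch_names : tuple of str
    conditions : ndarray of str, one of RRFR/RRFA/RAFR/RAFA/other
    participant : str
    group : str
        "GTS", "HC", or "" when not applicable.
    """

    data: np.ndarray
    sfreq: float
    t0_offset: float
    ch_names: tuple
    conditions: np.ndarray
    participant: str = ""
    group: str = ""

    def __post_init__(self):
        d = np.asarray(self.data)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "conditions", np.asarray(self.conditions, dtype=str))
        if d.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.ch_names) != d.shape[1]:
            raise ValueError("one channel name per channel required")
        if self.conditions.shape[0] != d.shape[0]:
            raise ValueError("one condition label per trial required")
        bad = set(self.conditions) - CONDITION_SET
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to S2."""
        return self.t0_offset + np.arange(self.n_samples) * 1000.0 / self.sfreq

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Sample slice for the half-open window [start_ms, stop_ms)."""
        t = self.times
        i0 = int(np.searchsorted(t, start_ms - 1e-9))
        i1 = int(np.searchsorted(t, stop_ms - 1e-9))
        if i0 >= i1:
            raise ValueError(f"window [{start_ms}, {stop_ms}) outside the epoch")
        return slice(i0, i1)

    def select(self, conditions) -> "EpochSet":
        """Subset of trials whose label is in ``conditions``."""
        wanted = {conditions} if isinstance(conditions, str) else set(conditions)
        mask = np.isin(self.conditions, sorted(wanted))
        return replace(self, data=self.data[mask], conditions=self.conditions[mask])

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset(
                "conditions", data=np.asarray(self.conditions, dtype="S16")
            )
            f.create_dataset(
                "ch_names", data=np.asarray(self.ch_names, dtype="S32")
            )
            f.attrs["sfreq"] = self.sfreq
            f.attrs["t0_offset"] = self.t0_offset
            f.attrs["participant"] = self.participant
            f.attrs["group"] = self.group

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                sfreq=float(f.attrs["sfreq"]),
                t0_offset=float(f.attrs["t0_offset"]),
                ch_names=tuple(n.decode() for n in f["ch_names"][()]),
                conditions=np.array([c.decode() for c in f["conditions"][()]]),
                participant=str(f.attrs["participant"]),
                group=str(f.attrs["group"]),
            )


def resample(epochs: EpochSet, target_sfreq: float) -> EpochSet:
    """Anti-aliased polyphase down-sampling to ``target_sfreq``."""
    if target_sfreq > epochs.sfreq:
        raise ValueError("upsampling is not supported")
    if target_sfreq == epochs.sfreq:
        return epochs
    frac = Fraction(target_sfreq / epochs.sfreq).limit_denominator(1000)
    out = scipy.signal.resample_poly(
        epochs.data.astype(float), frac.numerator, frac.denominator, axis=-1
    )
    return replace(epochs, data=out, sfreq=epochs.sfreq * frac.numerator / frac.denominator)


def bandpass_notch(
    epochs: EpochSet,
    low: float = 0.5,
    high: float = 40.0,
    order: int = 8,
    notch: float | None = 50.0,
    notch_q: float = 35.0,
) -> EpochSet:
    """Zero-phase Butterworth band-pass plus power-line notch.

    ``order`` is the total band-pass order (8 per the standard preprocessing
    recipe); the filter is applied forward-backward, so the effective
    magnitude response is squared and the phase is zero.
    """
    nyq = epochs.sfreq / 2.0
    if not (0 < low < high < nyq):
        raise ValueError("require 0 < low < high < Nyquist")
    if order < 2 or order % 2:
        raise ValueError("band-pass order must be a positive even integer")
    sos = scipy.signal.butter(order // 2, [low, high], btype="bandpass", fs=epochs.sfreq, output="sos")
    # pad several time constants of the low edge to limit filtfilt transients
    padlen = min(epochs.n_samples - 1, int(3 * epochs.sfreq / low))
    out = scipy.signal.sosfiltfilt(sos, epochs.data.astype(float), axis=-1, padlen=padlen)
    if notch is not None:
        if not (0 < notch < nyq):
            raise ValueError("notch frequency must be below Nyquist")
        b, a = scipy.signal.iirnotch(notch, notch_q, fs=epochs.sfreq)
        out = scipy.signal.filtfilt(b, a, out, axis=-1, padlen=padlen)
    return replace(epochs, data=out)


def _sliding_minmax(x: np.ndarray, width: int):
    """Min and max over every fully contained sliding window of ``width``.

    Returns arrays over the n - width + 1 valid window positions.
    """
    n = x.shape[-1]
    if width > n:
        width = n
    lo = scipy.ndimage.minimum_filter1d(x, size=width, axis=-1, mode="nearest")
    hi = scipy.ndimage.maximum_filter1d(x, size=width, axis=-1, mode="nearest")
    # centered filter: output j covers [j - width//2, j - width//2 + width - 1];
    # restrict to positions where that window lies fully inside the signal
    j0 = width // 2
    j1 = n - width + width // 2 + 1
    return lo[..., j0:j1], hi[..., j0:j1]


def reject_epochs(
    epochs: EpochSet,
    max_diff_uv: float = 200.0,
    diff_window_ms: float = 200.0,
    max_abs_uv: float = 200.0,
    min_activity_uv: float = 0.5,
    activity_window_ms: float = 100.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Automated amplitude-based epoch rejection.

    A trial is dropped if any channel, in any sliding window (one-sample
    step), shows a peak-to-peak difference above ``max_diff_uv`` within
    ``diff_window_ms``, an absolute value above ``max_abs_uv``, or
    peak-to-peak activity below ``min_activity_uv`` within
    ``activity_window_ms``.  Returns the retained epochs and a per-trial
    report listing which rules fired.
    """
    x = epochs.data.astype(float)
    w_diff = max(2, int(round(diff_window_ms / 1000.0 * epochs.sfreq)))
    w_act = max(2, int(round(activity_window_ms / 1000.0 * epochs.sfreq)))

    lo, hi = _sliding_minmax(x, w_diff)
    rule_diff = ((hi - lo) > max_diff_uv).any(axis=(1, 2))
    rule_abs = (np.abs(x) > max_abs_uv).any(axis=(1, 2))
    lo, hi = _sliding_minmax(x, w_act)
    rule_low = ((hi - lo) < min_activity_uv).any(axis=(1, 2))

    rejected = rule_diff | rule_abs | rule_low
    rows = []
    for t in range(epochs.n_trials):
        fired = []
        if rule_diff[t]:
            fired.append("amplitude_difference")
        if rule_abs[t]:
            fired.append("extreme_value")
        if rule_low[t]:
            fired.append("low_activity")
        rows.append(
            {"trial": t, "kept": not rejected[t], "rules": ",".join(fired)}
        )
    report = pd.DataFrame(rows)
    keep = ~rejected
    kept = replace(epochs, data=epochs.data[keep], conditions=epochs.conditions[keep])
    return kept, report


def read_brainvision_epochs(
    vhdr_path,
    marker: str,
    tmin_ms: float = -7000.0,
    tmax_ms: float = 2000.0,
    conditions=None,
    participant: str = "",
    group: str = "",
) -> EpochSet:
    """Epoch a continuous BrainVision recording around a stimulus marker.

    Thin ingest path over MNE's BrainVision reader; the marker description
    (e.g. ``"Stimulus/S  2"``) identifies S2 onsets.  ``conditions`` supplies
    one label per event in temporal order (defaults to ``"other"``).
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    if marker not in event_id:
        raise ValueError(f"marker {marker!r} not found; available: {sorted(event_id)}")
    onsets = events[events[:, 2] == event_id[marker], 0]
    sfreq = raw.info["sfreq"]
    i0 = int(round(tmin_ms / 1000.0 * sfreq))
    n_samp = int(round((tmax_ms - tmin_ms) / 1000.0 * sfreq))
    sig = raw.get_data() * 1e6  # V -> uV
    trials = []
    used = []
    for k, onset in enumerate(onsets):
        a = onset + i0
        if a < 0 or a + n_samp > sig.shape[1]:
            continue
        trials.append(sig[:, a : a + n_samp])
        used.append(k)
    if not trials:
        raise ValueError("no complete epochs around the requested marker")
    if conditions is None:
        labels = np.array(["other"] * len(trials))
    else:
        labels = np.asarray(conditions, dtype=str)[used]
    return EpochSet(
        data=np.stack(trials),
        sfreq=sfreq,
        t0_offset=i0 * 1000.0 / sfreq,
        ch_names=tuple(raw.ch_names),
        conditions=labels,
        participant=participant,
        group=group,
    )
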