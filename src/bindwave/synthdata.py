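"""Synthetic behavioral tables and forward-modelled EEG epochs.

The generator plants exactly the structure the downstream analysis is built
to detect:

* behavioral partial-repetition costs -- RT means in the partial-repetition
  conditions (RRFA, RAFR) are raised by a binding cost ``delta`` so the
  expected binding score is ``2*delta``; error rates carry an analogous
  planted cost;
* oscillatory dipole sources (theta/alpha/beta) at chosen grid voxels whose
  amplitudes differ by condition and trial period (post-S1, pre-S2,
  post-S2), projected through a spherical lead field with white sensor
  noise;
* a coupling ``rho`` between pre-trial and post-trial source power: each
  participant draws a pair of power modulators from a shared Gaussian latent
  with loading sqrt(rho) (plus independent per-trial jitter), so the
  participant-level band-power correlation downstream recovers ``rho``.

RT noise is a shifted lognormal (positive support, right skew).  Oscillation
phase is uniform per trial; period windows are half-open ``[a, b)`` ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import CONDITIONS, EpochSet
from .headmodel import LeadField

PERIODS = {
    "post_s1": (-2500.0, -1500.0),
    "pre_s2": (-1000.0, 0.0),
    "post_s2": (0.0, 1000.0),
}
BAND_FREQ = {"theta": 6.0, "alpha": 10.0, "beta": 20.0}

__all__ = [
    "PERIODS",
    "BAND_FREQ",
    "BehaviorSimParams",
    "SourceSpec",
    "EEGSimParams",
    "generate_behavior",
    "coupled_modulators",
    "generate_eeg",
]


@dataclass(frozen=True)
class BehaviorSimParams:
    """Behavioral simulator settings for one group.

    384 task trials split over 16 response/feature conditions give 24 trials
    per key condition.  ``binding_cost_ms`` is added to the RT means of the
    partial-repetition conditions (RRFA, RAFR), so the expected RT binding
    score is twice the cost; ``error_binding_cost`` does the same on the
    error probability.
    """

    n_participants: int = 62
    trials_per_condition: int = 24
    base_rt_ms: float = 480.0
    binding_cost_ms: float = 35.0
    rt_sd_ms: float = 100.0
    rt_shift_ms: float = 200.0
    base_rt1_ms: float = 320.0
    rt1_sd_ms: float = 60.0
    error_base: float = 0.05
    error_binding_cost: float = 0.09
    s1_accuracy: float = 0.95
    seed: int = 0

    def __post_init__(self):
        for p in (self.error_base, self.s1_accuracy):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.error_base + self.error_binding_cost <= 1.0:
            raise ValueError("error_base + error_binding_cost must lie in [0, 1]")
        if self.binding_cost_ms < 0:
            raise ValueError("binding cost must be nonnegative")
        if self.trials_per_condition < 2:
            raise ValueError("need at least 2 trials per condition")


def _shifted_lognormal(rng, mean, sd, shift, size):
    """Draws with the requested mean/sd and support above ``shift``."""
    mu_l = mean - shift
    if mu_l <= 0:
        raise ValueError("mean must exceed the shift")
    s2 = np.log1p((sd / mu_l) ** 2)
    mu = np.log(mu_l) - s2 / 2.0
    return shift + rng.lognormal(mu, np.sqrt(s2), size=size)


def generate_behavior(params: BehaviorSimParams, group: str = "HC") -> pd.DataFrame:
    """Simulate a per-trial behavioral table for one group.

    Columns: participant, group, trial, condition, rt1, rt2, s1_correct,
    s2_correct.  Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for s in range(params.n_participants):
        pid = f"{group}{s + 1:03d}"
        for cond in CONDITIONS:
            partial = cond in ("RRFA", "RAFR")
            mean_rt = params.base_rt_ms + params.binding_cost_ms * partial
            n = params.trials_per_condition
            rt2 = _shifted_lognormal(rng, mean_rt, params.rt_sd_ms, params.rt_shift_ms, n)
            rt1 = _shifted_lognormal(rng, params.base_rt1_ms, params.rt1_sd_ms, 100.0, n)
            s1_ok = rng.random(n) < params.s1_accuracy
            p_err = params.error_base + params.error_binding_cost * partial
            s2_ok = rng.random(n) >= p_err
            for k in range(n):
                rows.append(
                    {
                        "participant": pid,
                        "group": group,
                        "condition": cond,
                        "rt1": rt1[k],
                        "rt2": rt2[k],
                        "s1_correct": bool(s1_ok[k]),
                        "s2_correct": bool(s2_ok[k]),
                    }
                )
    df = pd.DataFrame(rows)
    df["trial"] = df.groupby("participant").cumcount()
    return df


@dataclass(frozen=True)
class SourceSpec:
    """One oscillatory dipole source.

    ``amplitudes`` maps period name -> {condition or "all": amplitude}
    (nA*m); a source is silent in periods it does not list.  ``freq``
    defaults to the band's center frequency.
    """

    voxel: int
    band: str = "theta"
    amplitudes: dict = field(default_factory=lambda: {"post_s2": {"all": 20.0}})
    freq: float | None = None
    orientation: tuple = (0.0, 1.0, 0.0)

    def amplitude(self, period: str, condition: str) -> float:
        spec = self.amplitudes.get(period)
        if spec is None:
            return 0.0
        return float(spec.get(condition, spec.get("all", 0.0)))


@dataclass(frozen=True)
class EEGSimParams:
    """EEG simulator settings for one participant.

    ``coupling_rho`` correlates the power modulators of
    ``coupling_periods[0]`` and ``coupling_periods[1]`` across participants
    and trials; ``amp_cv_participant``/``amp_cv_trial`` set the relative
    power spread at the two levels.  ``noise_sd_uv`` is white sensor noise.
    """

    sources: tuple = ()
    trials_per_condition: int = 24
    coupling_rho: float = 0.0
    coupling_periods: tuple = ("post_s1", "post_s2")
    amp_cv_participant: float = 0.25
    amp_cv_trial: float = 0.1
    noise_sd_uv: float = 1.0
    sfreq: float = 256.0
    epoch_window_ms: tuple = (-7000.0, 2000.0)
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("|coupling_rho| must be <= 1")
        a, b = self.epoch_window_ms
        for p0, p1 in PERIODS.values():
            if p0 < a or p1 > b:
                raise ValueError("all periods must lie inside the epoch window")


def coupled_modulators(n: int, rho: float, cv: float, rng) -> np.ndarray:
    """Pairs of positive power modulators with correlation ``rho``.

    A shared standard-normal latent with loading sqrt(rho) drives both
    members; the construction gives exact target correlation of the
    underlying Gaussians.  Returns shape (n, 2), values 1 + cv*z floored at
    a small positive value.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    z = rng.standard_normal(n)
    e = rng.standard_normal((n, 2))
    r = abs(rho)
    pair = np.sqrt(r) * z[:, None] + np.sqrt(1.0 - r) * e
    if rho < 0:
        pair[:, 1] = np.sqrt(r) * -z + np.sqrt(1.0 - r) * e[:, 1]
    return np.clip(1.0 + cv * pair, 0.05, None)


def generate_eeg(
    params: EEGSimParams,
    leadfield: LeadField,
    participant: str = "sim001",
    group: str = "HC",
) -> tuple[EpochSet, pd.DataFrame]:
    """Forward-model one participant's epochs.

    Every trial contains each source's band-limited oscillation windowed to
    its active periods, scaled by the per-trial power modulator, projected
    through the lead field, plus white sensor noise.  Returns the epochs and
    a ground-truth table of the drawn per-trial modulators.
    """
    rng = np.random.default_rng(params.seed)
    n_vox = leadfield.n_voxels
    for src in params.sources:
        if not 0 <= src.voxel < n_vox:
            raise ValueError(f"source voxel {src.voxel} outside the grid")
    a, b = params.epoch_window_ms
    n_samp = int(round((b - a) / 1000.0 * params.sfreq))
    times = a + np.arange(n_samp) * 1000.0 / params.sfreq
    conditions = np.repeat(CONDITIONS, params.trials_per_condition)
    conditions = conditions[rng.permutation(conditions.size)]
    n_trials = conditions.size

    period_masks = {
        name: (times >= p0 - 1e-9) & (times < p1 - 1e-9)
        for name, (p0, p1) in PERIODS.items()
    }

    # participant-level coupled modulators, one pair per source
    part_mod = {}
    for si, src in enumerate(params.sources):
        pair = coupled_modulators(1, params.coupling_rho, params.amp_cv_participant, rng)[0]
        part_mod[si] = dict(zip(params.coupling_periods, pair))

    data = rng.normal(0.0, params.noise_sd_uv, size=(n_trials, leadfield.n_channels, n_samp))
    truth_rows = []
    for t in range(n_trials):
        cond = conditions[t]
        row = {"trial": t, "condition": cond}
        for si, src in enumerate(params.sources):
            freq = src.freq if src.freq is not None else BAND_FREQ[src.band]
            ori = np.asarray(src.orientation, dtype=float)
            ori = ori / np.linalg.norm(ori)
            # lead field is V/(A*m); amplitudes are nA*m and data are uV,
            # so the net conversion is 1e-9 * 1e6 = 1e-3
            gain = (leadfield.gain[:, src.voxel, :] @ ori) * 1e-3
            trial_pair = coupled_modulators(
                1, params.coupling_rho, params.amp_cv_trial, rng
            )[0]
            trial_mod = dict(zip(params.coupling_periods, trial_pair))
            for period, mask in period_masks.items():
                base = src.amplitude(period, cond)
                if base == 0.0:
                    continue
                mod = part_mod[si].get(period, 1.0) * trial_mod.get(period, 1.0)
                amp = base * np.sqrt(mod)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                osc = amp * np.sin(2.0 * np.pi * freq * times[mask] / 1000.0 + phase)
                data[t][:, mask] += gain[:, None] * osc[None, :]
                row[f"src{si}_{period}_power_mod"] = mod * base**2
        truth_rows.append(row)

    epochs = EpochSet(
        data=data,
        sfreq=params.sfreq,
        t0_offset=a,
        ch_names=leadfield.sensors.names,
        conditions=conditions,
        participant=participant,
        group=group,
    )
    return epochs, pd.DataFrame(truth_rows)
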