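"""LCMV covariance, filters, cluster time series, and the interaction course."""

import numpy as np
import pytest

from bindwave.epochs import EpochSet
from bindwave.source_dics import csd, dics_filters
from bindwave.source_lcmv import (
    ClusterTimeSeries,
    cluster_timeseries,
    covariance,
    interaction_course,
    lcmv_filters,
    stack_participants,
)


def make_epochs(data, sfreq=256.0, t0=0.0, ch_names=None, conditions=None):
    data = np.asarray(data, dtype=float)
    return EpochSet(
        data, sfreq, t0,
        ch_names or tuple(f"ch{i}" for i in range(data.shape[1])),
        conditions if conditions is not None else np.array(["other"] * data.shape[0]),
        participant="p1",
    )


def source_epochs(leadfield, vox, rng, freq=10.0, amp=30.0, noise=0.1, n_trials=30,
                  n_samp=512, ori=(0.0, 1.0, 0.0)):
    t = np.arange(n_samp) / 256.0
    gain = (leadfield.gain[:, vox, :] @ np.asarray(ori, float)) * 1e-3
    data = noise * rng.standard_normal((n_trials, leadfield.n_channels, n_samp))
    phases = rng.uniform(0, 2 * np.pi, n_trials)
    source = amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    data += gain[None, :, None] * source[:, None, :]
    return make_epochs(data, ch_names=leadfield.sensors.names), source


class TestCovariance:
    def test_white_noise_gives_diagonal(self, rng):
        ep = make_epochs(rng.normal(0, 2.0, size=(200, 3, 256)))
        c = covariance(ep, (0.0, 1000.0))
        assert np.allclose(np.diag(c), 4.0, rtol=0.1)
        off = c[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_duplicated_channel_perfectly_correlated(self, rng):
        x = rng.standard_normal((5, 1, 256))
        ep = make_epochs(np.concatenate([x, x], axis=1))
        c = covariance(ep, (0.0, 1000.0))
        assert c[0, 1] / np.sqrt(c[0, 0] * c[1, 1]) == pytest.approx(1.0)

    def test_single_source_eigen_spectrum(self, leadfield, rng):
        ep, _ = source_epochs(leadfield, 25, rng, noise=0.05)
        c = covariance(ep, (0.0, 2000.0))
        ev = np.sort(np.linalg.eigvalsh(c))[::-1]
        assert ev[0] > 50 * ev[1]  # dominant source mode above the noise floor

    def test_too_short_toi_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((2, 2, 256)))
        with pytest.raises(ValueError):
            covariance(ep, (0.0, 3.0))


class TestLCMVFilters:
    def test_unit_gain(self, leadfield, rng):
        ep, _ = source_epochs(leadfield, 25, rng)
        filt = lcmv_filters(covariance(ep, (0.0, 2000.0)), leadfield, lam=0.05)
        l_eff = np.einsum("ivk,vk->iv", leadfield.gain, filt.orientations)
        gains = np.einsum("vi,iv->v", filt.weights, l_eff)
        assert np.abs(gains - 1.0).max() < 1e-8

    def test_reconstruction_correlates_with_truth_at_high_snr(self, leadfield, rng):
        vox = 33
        ep, source = source_epochs(leadfield, vox, rng, noise=0.05)
        filt = lcmv_filters(covariance(ep, (0.0, 2000.0)), leadfield, lam=0.05,
                            voxels=[vox])
        recon = np.einsum("i,tis->ts", filt.weights[0], ep.data)
        r = np.corrcoef(recon.ravel(), source.ravel())[0, 1]
        assert abs(r) > 0.95

    def test_matches_dics_for_narrowband_data(self, leadfield, rng):
        """Narrowband covariance and band CSD give equivalent filters."""
        ep, _ = source_epochs(leadfield, 25, rng, noise=0.2)
        lam = 0.05
        lcmv = lcmv_filters(covariance(ep, (0.0, 2000.0)), leadfield, lam=lam)
        dics = dics_filters(csd(ep, (8.0, 12.0), (0.0, 2000.0)), leadfield, lam=lam)
        cos = []
        for v in range(0, leadfield.n_voxels, 29):
            a = np.real(lcmv.weights[v])
            b = np.real(dics.weights[v])
            cos.append(abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert np.median(cos) > 0.98


class TestClusterTimeseries:
    def test_single_voxel_cluster_equals_voxel_series(self, leadfield, rng):
        ep, _ = source_epochs(leadfield, 25, rng, n_samp=1024)
        filt = lcmv_filters(covariance(ep, (0.0, 4000.0)), leadfield, voxels=[25])
        cts = cluster_timeseries(filt, ep, [25], (8.0, 12.0), (1000.0, 3000.0))
        assert cts.power.shape[0] == 1
        assert (cts.power > 0).all()

    def test_duplicate_voxel_average_equals_single(self, leadfield, rng):
        ep, _ = source_epochs(leadfield, 25, rng, n_samp=1024)
        filt = lcmv_filters(covariance(ep, (0.0, 4000.0)), leadfield, voxels=[25])
        a = cluster_timeseries(filt, ep, [25], (8.0, 12.0), (1000.0, 3000.0))
        b = cluster_timeseries(filt, ep, [25, 25], (8.0, 12.0), (1000.0, 3000.0))
        assert np.allclose(a.power, b.power)

    def test_planted_theta_source_peaks_in_active_period(self, leadfield, rng):
        # theta burst only in the second half of the epoch
        n_samp = 2048
        t = np.arange(n_samp) / 256.0
        vox = 25
        gain = (leadfield.gain[:, vox, :] @ np.array([0.0, 1.0, 0.0])) * 1e-3
        data = 0.1 * rng.standard_normal((20, leadfield.n_channels, n_samp))
        burst = np.where(t >= 4.0, 30.0 * np.sin(2 * np.pi * 6.0 * t), 0.0)
        data += gain[None, :, None] * burst[None, None, :]
        ep = make_epochs(data, ch_names=leadfield.sensors.names)
        filt = lcmv_filters(covariance(ep, (0.0, 8000.0)), leadfield, voxels=[vox])
        cts = cluster_timeseries(filt, ep, [vox], (4.0, 7.0), (1000.0, 7000.0))
        active = cts.times >= 4500.0
        quiet = cts.times < 3500.0
        assert cts.power[0, active].mean() > 10 * cts.power[0, quiet].mean()

    def test_empty_cluster_rejected(self, leadfield, rng):
        ep, _ = source_epochs(leadfield, 25, rng)
        filt = lcmv_filters(covariance(ep, (0.0, 2000.0)), leadfield, voxels=[25])
        with pytest.raises(ValueError, match="empty cluster"):
            cluster_timeseries(filt, ep, [], (8.0, 12.0), (0.0, 1000.0))


class TestInteractionCourse:
    def cts(self, power, tag=""):
        power = np.atleast_2d(power)
        return ClusterTimeSeries(
            power, np.arange(power.shape[1], dtype=float), (4.0, 7.0), (0.0, 1000.0),
            tag=tag, participants=tuple(f"p{i}" for i in range(power.shape[0])),
        )

    def test_identical_courses_give_zero(self, rng):
        a = self.cts(rng.uniform(1, 2, size=(3, 8)))
        out = interaction_course(a, self.cts(a.power.copy()))
        assert np.allclose(out.power, 0.0)

    def test_constant_offset_preserved(self, rng):
        base = rng.uniform(1, 2, size=(3, 8))
        out = interaction_course(self.cts(base + 0.7), self.cts(base))
        assert np.allclose(out.power, 0.7)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            interaction_course(
                self.cts(rng.uniform(size=(2, 8))), self.cts(rng.uniform(size=(2, 9)))
            )

    def test_stack_participants(self, rng):
        parts = [self.cts(rng.uniform(size=8)) for _ in range(4)]
        stacked = stack_participants(parts)
        assert stacked.power.shape == (4, 8)
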