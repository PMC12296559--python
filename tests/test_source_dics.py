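"""CSD estimation, DICS filters, source power, and the FR/FA ratio map."""

import numpy as np
import pytest

from bindwave.epochs import EpochSet
from bindwave.experiments import dics_localization
from bindwave.source_dics import (
    CSDMatrix,
    SourcePowerMap,
    csd,
    dics_filters,
    power_ratio,
    source_power,
)


def make_epochs(data, sfreq=256.0):
    data = np.asarray(data, dtype=float)
    return EpochSet(
        data, sfreq, 0.0, tuple(f"ch{i}" for i in range(data.shape[1])),
        np.array(["other"] * data.shape[0]),
    )


class TestCSD:
    def test_duplicated_channel_rows_equal_and_coherent(self, rng):
        x = rng.standard_normal((10, 1, 512))
        ep = make_epochs(np.concatenate([x, x], axis=1))
        c = csd(ep, (8.0, 12.0), (0.0, 2000.0)).values
        assert np.allclose(c[0], c[1])
        coh = np.abs(c[0, 1]) / np.sqrt(c[0, 0].real * c[1, 1].real)
        assert coh == pytest.approx(1.0)

    def test_independent_noise_offdiagonal_vanishes(self, rng):
        ep = make_epochs(rng.standard_normal((400, 2, 256)))
        c = csd(ep, (8.0, 12.0), (0.0, 1000.0)).values
        # off-diagonal should be ~0 relative to the diagonal
        assert np.abs(c[0, 1]) < 3 * c[0, 0].real / np.sqrt(400)

    def test_single_source_gives_rank_one_csd(self, rng):
        t = np.arange(512) / 256.0
        mix = rng.standard_normal(5)
        phases = rng.uniform(0, 2 * np.pi, 20)
        data = mix[None, :, None] * np.sin(
            2 * np.pi * 10.0 * t[None, None, :] + phases[:, None, None]
        )
        c = csd(make_epochs(data), (8.0, 12.0), (0.0, 2000.0)).values
        ev = np.sort(np.linalg.eigvalsh(c))
        assert ev[-1] > 0
        assert ev[-2] < 1e-10 * ev[-1]

    def test_window_shorter_than_one_cycle_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 512)))
        with pytest.raises(ValueError, match="one cycle"):
            csd(ep, (4.0, 7.0), (0.0, 100.0))

    def test_hermitian_invariant(self, rng):
        ep = make_epochs(rng.standard_normal((5, 4, 512)))
        c = csd(ep, (13.0, 30.0), (0.0, 1000.0)).values
        assert np.abs(c - c.conj().T).max() < 1e-12 * np.abs(c).max()


class TestDICSFilters:
    def band_csd(self, leadfield, rng, extra_sources=()):
        t = np.arange(512) / 256.0
        n_tr = 40
        data = 0.1 * rng.standard_normal((n_tr, leadfield.n_channels, 512))
        for vox, freq in extra_sources:
            gain = leadfield.gain[:, vox, :] @ np.array([0.0, 1.0, 0.0]) * 1e-3
            ph = rng.uniform(0, 2 * np.pi, n_tr)
            data += 30.0 * gain[None, :, None] * np.sin(
                2 * np.pi * freq * t[None, None, :] + ph[:, None, None]
            )
        return csd(make_epochs(data), (8.0, 12.0), (0.0, 2000.0))

    def test_unit_gain_constraint(self, leadfield, rng):
        c = self.band_csd(leadfield, rng, [(10, 10.0)])
        filt = dics_filters(c, leadfield, lam=0.05)
        L = leadfield.gain
        l_eff = np.einsum("ivk,vk->iv", L, filt.orientations)
        gains = np.einsum("vi,iv->v", filt.weights, l_eff)
        assert np.abs(gains - 1.0).max() < 1e-8

    def test_identity_csd_gives_minimum_norm_weights(self, leadfield):
        n = leadfield.n_channels
        c = CSDMatrix(np.eye(n, dtype=complex), (8.0, 12.0), (0.0, 1000.0),
                      leadfield.sensors.names, 1)
        filt = dics_filters(c, leadfield, lam=0.0)
        l_eff = np.einsum("ivk,vk->iv", leadfield.gain, filt.orientations)
        for v in range(0, leadfield.n_voxels, 37):
            w = np.real(filt.weights[v])
            l = l_eff[:, v]
            cos = w @ l / (np.linalg.norm(w) * np.linalg.norm(l))
            assert abs(cos) == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficient_unregularized_matrix_raises(self, leadfield):
        n = leadfield.n_channels
        vals = np.zeros((n, n), dtype=complex)
        vals[0, 0] = 1.0
        c = CSDMatrix(vals, (8.0, 12.0), (0.0, 1000.0), leadfield.sensors.names, 1)
        with pytest.raises(np.linalg.LinAlgError, match="condition number"):
            dics_filters(c, leadfield, lam=0.0)

    def test_single_dipole_recovery(self):
        res = dics_localization(n_seeds=20, snr=10.0, seed=202)
        assert res["success_rate"] >= 0.9


class TestSourcePower:
    def test_power_identity_when_condition_equals_common(self, leadfield, rng):
        ep = make_epochs(rng.standard_normal((30, leadfield.n_channels, 512)))
        c = csd(ep, (8.0, 12.0), (0.0, 1000.0))
        lam = 0.05
        filt = dics_filters(c, leadfield, lam=lam)
        p = source_power(filt, c)
        reg = c.values + lam * np.real(np.diag(c.values)).mean() * np.eye(leadfield.n_channels)
        inv = np.linalg.inv(reg)
        l_eff = np.einsum("ivk,vk->iv", leadfield.gain, filt.orientations)
        want = 1.0 / np.real(np.einsum("iv,ij,jv->v", l_eff, inv, l_eff))
        # identity holds up to the regularization term: w C w' = w Cr w' - lam*mu*|w|^2
        mu = lam * np.real(np.diag(c.values)).mean()
        wnorm = np.einsum("vi,vi->v", filt.weights, filt.weights.conj()).real
        assert np.allclose(p.values, want - mu * wnorm, rtol=1e-8)

    def test_power_linear_in_csd_scale(self, leadfield, rng):
        ep = make_epochs(rng.standard_normal((20, leadfield.n_channels, 512)))
        c = csd(ep, (8.0, 12.0), (0.0, 1000.0))
        filt = dics_filters(c, leadfield)
        p1 = source_power(filt, c).values
        c5 = CSDMatrix(5.0 * c.values, c.band, c.window_ms, c.ch_names, c.n_trials)
        p5 = source_power(filt, c5).values
        assert np.allclose(p5, 5.0 * p1)

    def test_two_equal_dipoles_give_two_local_maxima(self, leadfield, rng):
        t = np.arange(512) / 256.0
        va, vb = 20, leadfield.n_voxels - 20
        data = 0.05 * rng.standard_normal((40, leadfield.n_channels, 512))
        for vox in (va, vb):
            gain = leadfield.gain[:, vox, :] @ np.array([0.0, 1.0, 0.0]) * 1e-3
            ph = rng.uniform(0, 2 * np.pi, 40)
            data += 30.0 * gain[None, :, None] * np.sin(
                2 * np.pi * 10.0 * t[None, None, :] + ph[:, None, None]
            )
        c = csd(make_epochs(data), (8.0, 12.0), (0.0, 2000.0))
        filt = dics_filters(c, leadfield)
        from bindwave.source_dics import neural_activity_index

        nai = neural_activity_index(filt, c).values
        pos = leadfield.grid.positions
        spacing = leadfield.grid.spacing
        for vox in (va, vb):
            near = np.linalg.norm(pos - pos[vox], axis=1) <= 1.001 * spacing
            peak = np.argmax(np.where(near, nai, -np.inf))
            far = np.linalg.norm(pos - pos[vox], axis=1) > 2.5 * spacing
            mid = np.median(nai[far])
            assert nai[peak] > 2 * mid


class TestPowerRatio:
    def pmap(self, values):
        v = np.asarray(values, float)
        return SourcePowerMap(v, np.arange(v.size), (8.0, 12.0), (0.0, 1000.0), "power")

    def test_equal_power_gives_zero(self):
        r = power_ratio(self.pmap([1.0, 2.0]), self.pmap([1.0, 2.0]))
        assert np.allclose(r.values, 0.0)

    def test_bounds_and_arithmetic(self):
        r = power_ratio(self.pmap([3.0, 2.0, 0.0]), self.pmap([0.0, 1.0, 0.0]))
        assert r.values[0] == 1.0
        assert r.values[1] == pytest.approx(1.0 / 3.0)
        assert r.values[2] == 0.0

    def test_invariant_to_global_rescaling(self, rng):
        a, b = rng.uniform(0, 5, 20), rng.uniform(0, 5, 20)
        r1 = power_ratio(self.pmap(a), self.pmap(b)).values
        r2 = power_ratio(self.pmap(7.0 * a), self.pmap(7.0 * b)).values
        assert np.allclose(r1, r2)

    def test_negative_power_rejected(self):
        bad = SourcePowerMap(np.array([1.0]), np.array([0]), None, None, "nai")
        bad2 = SourcePowerMap(np.array([-1.0]), np.array([0]), None, None, "nai")
        with pytest.raises(ValueError):
            power_ratio(bad, bad2)
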