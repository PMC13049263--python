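"""Noise covariance, WSVD combination, and the B1+/B1− calibration chain."""
import numpy as np
import pytest

from dmiquant.calibration import (NoiseCovariance, ReceiveMap,
                                  estimate_noise_covariance, joint_wsvd,
                                  extract_amplitudes, fit_b1_receive,
                                  fit_b1_transmit, resample_b1_grid,
                                  roemer_weights, vfa_amplitude,
                                  AmplitudeTable)
from dmiquant.containers import SpectralStack
from dmiquant.grids import GridGeometry
from dmiquant.synthetic import (ProtocolParams, simulate_prescan,
                                simulate_voltage_series,
                                saturation_amplitude)

GRID1 = GridGeometry((1, 1, 1), (10.0, 10.0, 10.0))


def _rank1_stack(b, s, voltage=100.0):
    fids = (b[:, None] * s[None, :])[None, None, None]
    return SpectralStack(fids, GRID1, 1e-3, voltage_v=voltage)


def _random_pd(nc, rng):
    a = rng.standard_normal((nc, nc)) + 1j * rng.standard_normal((nc, nc))
    return a @ a.conj().T + nc * np.eye(nc)


class TestNoiseCovariance:
    def test_iid_unit_variance_recovers_identity(self):
        stack = simulate_prescan(np.eye(4, dtype=complex), 100_000, 4, seed=0)
        xi = estimate_noise_covariance(stack)
        assert np.linalg.norm(xi.xi - np.eye(4)) < 0.05
        assert xi.n_samples_used == 100_000

    def test_duplicated_channels_raise_rank_deficiency(self, rng):
        x = rng.standard_normal((1, 200)) + 1j * rng.standard_normal((1, 200))
        with pytest.raises(ValueError, match="rank-deficient"):
            estimate_noise_covariance(np.vstack([x, x]))

    def test_scaling_is_quadratic(self, rng):
        x = rng.standard_normal((3, 500)) + 1j * rng.standard_normal((3, 500))
        xi1 = estimate_noise_covariance(x)
        xi2 = estimate_noise_covariance((2.0 - 1.0j) * x)
        np.testing.assert_allclose(xi2.xi, abs(2.0 - 1.0j) ** 2 * xi1.xi,
                                   rtol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        x = rng.standard_normal((4, 30)) + 0j
        with pytest.raises(ValueError, match="too few"):
            estimate_noise_covariance(x)


class TestJointWSVD:
    def test_single_channel_identity_up_to_phase(self, rng):
        s = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        stack = _rank1_stack(np.array([1.0 + 0j]), s)
        xi = NoiseCovariance(np.eye(1, dtype=complex), 100)
        weights, combined = joint_wsvd([stack], xi)
        c = combined[0, 0, 0, 0]
        ratio = c / np.fft.fftshift(np.fft.fft(s))
        assert np.allclose(np.abs(ratio), np.abs(ratio[0]))
        # phase convention: largest-magnitude sample real positive
        peak = c[np.argmax(np.abs(c))]
        assert abs(np.imag(peak)) < 1e-10 * abs(peak) and np.real(peak) > 0

    def test_noiseless_rank1_recovers_norm_times_signal(self, rng):
        b = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        s = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        stack = _rank1_stack(b, s)
        xi = NoiseCovariance(np.eye(4, dtype=complex), 100)
        _, combined = joint_wsvd([stack], xi)
        c = combined[0, 0, 0, 0]
        spec = np.fft.fftshift(np.fft.fft(s))
        np.testing.assert_allclose(np.abs(c), np.linalg.norm(b) * np.abs(spec),
                                   rtol=1e-10)

    def test_weights_equal_roemer_up_to_global_phase(self, rng):
        for _ in range(10):
            nc = 4
            xi_mat = _random_pd(nc, rng)
            b = rng.standard_normal(nc) + 1j * rng.standard_normal(nc)
            s = rng.standard_normal(64) + 1j * rng.standard_normal(64)
            weights, _ = joint_wsvd([_rank1_stack(b, s)],
                                    NoiseCovariance(xi_mat, 100))
            w_r = (np.linalg.solve(xi_mat, b)
                   / np.sqrt(np.real(b.conj() @ np.linalg.solve(xi_mat, b))))
            w1 = weights.w[0, 0, 0]
            cos = (abs(np.vdot(w1, w_r))
                   / (np.linalg.norm(w1) * np.linalg.norm(w_r)))
            assert cos > 1 - 1e-8

    def test_zero_signal_voxel_flagged(self):
        fids = np.zeros((1, 1, 1, 2, 32), complex)
        stack = SpectralStack(fids, GRID1, 1e-3, voltage_v=50.0)
        weights, _ = joint_wsvd([stack], NoiseCovariance(np.eye(2,
                                                                dtype=complex),
                                                         100))
        assert not weights.valid[0, 0, 0]

    def test_channel_mismatch_raises(self, rng):
        s = rng.standard_normal(32) + 0j
        stack = _rank1_stack(np.array([1.0, 2.0], dtype=complex), s)
        with pytest.raises(ValueError):
            joint_wsvd([stack], NoiseCovariance(np.eye(3, dtype=complex), 99))


class TestExtractAmplitudes:
    def _table(self, s_m, spectra_by_voltage, rng):
        stacks = []
        nv = len(spectra_by_voltage)
        for j, spec in enumerate(spectra_by_voltage):
            fid = np.fft.ifft(np.fft.ifftshift(spec))
            stacks.append(_rank1_stack(np.array([1.0 + 0j]), np.fft.fft(fid) * 0
                                       + fid, voltage=(j + 1) * 50.0))
        # combined spectra array (1,1,1,nv,npts)
        combined = np.stack([s.spectra()[0, 0, 0, 0]
                             for s in stacks])[None, None, None]
        return stacks, combined

    def test_scalar_multiple_and_orthogonal(self, rng):
        n = 64
        s_m = rng.standard_normal(n) + 1j * rng.standard_normal(n)
        stacks, combined = self._table(s_m, [2.5 * s_m], rng)
        table = extract_amplitudes(stacks, combined,
                                   s_m[None, None, None, :])
        assert table.a_j[0, 0, 0, 0] == pytest.approx(2.5, rel=1e-10)
        assert table.a_kj[0, 0, 0, 0, 0] == pytest.approx(2.5, rel=1e-10)

        orth = np.zeros(n, complex)
        orth[0], s0 = 1.0, np.zeros(n, complex)
        s0[1] = 1.0
        stacks, combined = self._table(s0, [orth], rng)
        table = extract_amplitudes(stacks, combined, s0[None, None, None, :])
        assert abs(table.a_j[0, 0, 0, 0]) < 1e-12

    def test_noiseless_series_reproduces_steady_state_curve(self,
                                                            ref_truth_small):
        protocol = ProtocolParams.voltage_series(128)
        stacks = simulate_voltage_series(ref_truth_small, protocol,
                                         add_noise=False)
        xi = NoiseCovariance(ref_truth_small.noise_cov, 1000)
        weights, combined = joint_wsvd(stacks, xi)
        vox = tuple(np.argwhere(ref_truth_small.mask())[3])
        # model spectrum = the max-signal combined spectrum itself
        per_volt = combined[vox]
        j = int(np.argmax(np.linalg.norm(per_volt, axis=1)))
        s_m = np.zeros(combined.shape[:3] + (combined.shape[-1],), complex)
        s_m[vox] = per_volt[j]
        table = extract_amplitudes(stacks, combined, s_m)
        curve = np.abs(table.a_j[vox])
        theta = (protocol.flip_per_volt_rad * ref_truth_small.b1_plus[vox]
                 * np.asarray(protocol.voltages_v))
        expected = np.abs(saturation_amplitude(theta, protocol.tr_s,
                                               ref_truth_small.t1_map["HDO"]))
        expected *= curve[j] / expected[j]
        np.testing.assert_allclose(curve, expected, rtol=1e-6)


def _amplitude_table_from_curve(curves, voltages):
    """Build a 1×1×n AmplitudeTable from combined-amplitude curves."""
    n = len(curves)
    a_j = np.asarray(curves)[None, None, :, :]
    a_kj = a_j[..., None, :]
    return AmplitudeTable(a_kj=a_kj, a_j=a_j,
                          voltages_v=np.asarray(voltages),
                          valid=np.ones((1, 1, n), bool))


class TestFitB1Transmit:
    protocol = ProtocolParams.voltage_series(64)

    def test_noiseless_recovery_paper_constants(self):
        """B1+ = 0.02 μT/V, TR = 1 s, T1 = 355 ms, 9 voltages."""
        v = np.asarray(self.protocol.voltages_v)
        curve = vfa_amplitude(0.02, 1.3, v, self.protocol, 0.355)
        table = _amplitude_table_from_curve([curve], v)
        grid = GridGeometry((1, 1, 1), (10., 10., 10.))
        tm = fit_b1_transmit(table, self.protocol, 0.355, grid)
        assert tm.valid_mask[0, 0, 0]
        assert abs(tm.b1_plus[0, 0, 0] - 0.02) / 0.02 < 1e-6
        assert abs(tm.k_scale[0, 0, 0] - 1.3) / 1.3 < 1e-6

    def test_zero_field_marked_invalid(self):
        v = np.asarray(self.protocol.voltages_v)
        table = _amplitude_table_from_curve([np.zeros_like(v)], v)
        tm = fit_b1_transmit(table, self.protocol, 0.355,
                             GridGeometry((1, 1, 1), (10., 10., 10.)))
        assert not tm.valid_mask[0, 0, 0]

    def test_monte_carlo_recovery_2pct_noise(self, rng):
        v = np.asarray(self.protocol.voltages_v)
        n_vox = 200
        b1_true = rng.uniform(0.05, 0.15, n_vox)
        curves = []
        for b1 in b1_true:
            c = np.abs(vfa_amplitude(b1, 1.0, v, self.protocol, 0.355))
            curves.append(c + 0.02 * c.max() * rng.standard_normal(v.size))
        table = _amplitude_table_from_curve(curves, v)
        tm = fit_b1_transmit(table, self.protocol, 0.355,
                             GridGeometry((1, 1, n_vox), (10., 10., 10.)))
        rel = np.abs(tm.b1_plus[0, 0] - b1_true) / b1_true
        assert np.median(rel[tm.valid_mask[0, 0]]) < 0.05

    def test_preconditions(self):
        v = np.array([25.0, 50.0])
        table = _amplitude_table_from_curve([np.ones(2)], v)
        with pytest.raises(ValueError):
            fit_b1_transmit(table, ProtocolParams(
                tr_s=1.0, pulse_duration_s=4e-3, voltages_v=(25.0, 50.0),
                spectral_bw_hz=5e3, n_samples=64), 0.355,
                GridGeometry((1, 1, 1), (1., 1., 1.)))

    def test_phase_invariance_of_magnitude_fit(self):
        v = np.asarray(self.protocol.voltages_v)
        curve = vfa_amplitude(0.08, 1.0, v, self.protocol, 0.355)
        rotated = curve * np.exp(1j * 0.77)
        g = GridGeometry((1, 1, 1), (10., 10., 10.))
        t1 = fit_b1_transmit(_amplitude_table_from_curve([curve], v),
                             self.protocol, 0.355, g)
        t2 = fit_b1_transmit(_amplitude_table_from_curve([rotated], v),
                             self.protocol, 0.355, g)
        assert t1.b1_plus[0, 0, 0] == pytest.approx(t2.b1_plus[0, 0, 0],
                                                    rel=1e-12)


class TestFitB1Receive:
    def test_noiseless_chain_recovery(self, ref_truth_small,
                                      noiseless_calibration):
        bundle, _ = noiseless_calibration
        truth = ref_truth_small
        sel = truth.mask() & bundle.receive.valid_mask
        assert sel.sum() > 10
        b_t = truth.b1_minus[sel]
        b_e = bundle.receive.b1_minus[sel]
        # recovered sensitivities match truth up to one complex scale/voxel:
        # check magnitudes (normalized) and relative phases
        for bt, be in zip(b_t[:20], b_e[:20]):
            cos = abs(np.vdot(bt, be)) / (np.linalg.norm(bt)
                                          * np.linalg.norm(be))
            assert cos > 1 - 1e-8

    def test_linearity_in_amplitudes(self):
        protocol = ProtocolParams.voltage_series(64)
        v = np.asarray(protocol.voltages_v)
        curve = vfa_amplitude(0.08, 1.0, v, protocol, 0.355)
        g = GridGeometry((1, 1, 1), (10., 10., 10.))
        table = _amplitude_table_from_curve([curve], v)
        tm = fit_b1_transmit(table, protocol, 0.355, g)
        r1 = fit_b1_receive(table, tm, protocol, 0.355)
        table2 = AmplitudeTable(a_kj=2.0 * table.a_kj, a_j=2.0 * table.a_j,
                                voltages_v=v, valid=table.valid)
        r2 = fit_b1_receive(table2, tm, protocol, 0.355)
        np.testing.assert_allclose(r2.b1_minus, 2.0 * r1.b1_minus, rtol=1e-10)

    def test_weighted_reconstruction_consistency(self, ref_truth_small,
                                                 noiseless_calibration):
        """Σ_k w_k*·B1−_k reproduces the WSVD combined scale on noiseless
        data (both derive from the same rank-1 structure)."""
        bundle, _ = noiseless_calibration
        sel = ref_truth_small.mask() & bundle.weights.valid
        w = bundle.weights.w[sel]
        b = bundle.receive.b1_minus[sel]
        proj = np.abs(np.einsum("vk,vk->v", w.conj(), b))
        norm = np.sqrt(np.real(np.einsum(
            "vk,kl,vl->v", b.conj(),
            np.linalg.inv(bundle.xi.xi), b)))
        np.testing.assert_allclose(proj, norm, rtol=1e-6)


class TestRoemerWeights:
    def _receive(self, b):
        b = np.asarray(b, complex)[None, None, None, :]
        return ReceiveMap(b1_minus=b,
                          phase_reference=np.zeros((1, 1, 1), int),
                          valid_mask=np.ones((1, 1, 1), bool),
                          grid=GRID1)

    def test_single_channel_inverse_sigma(self):
        w = roemer_weights(self._receive([1.0]),
                           NoiseCovariance(np.array([[4.0 + 0j]]), 10))
        assert w.w[0, 0, 0, 0] == pytest.approx(0.5)

    def test_two_channel_hand_example(self):
        w = roemer_weights(self._receive([1.0, 1j]),
                           NoiseCovariance(np.eye(2, dtype=complex), 10))
        np.testing.assert_allclose(w.w[0, 0, 0],
                                   [1 / np.sqrt(2), 1j / np.sqrt(2)],
                                   atol=1e-12)

    def test_unit_output_noise_normalization(self, rng):
        for _ in range(100):
            nc = int(rng.integers(2, 6))
            xi = _random_pd(nc, rng)
            b = rng.standard_normal(nc) + 1j * rng.standard_normal(nc)
            w = roemer_weights(self._receive(b), NoiseCovariance(xi, 10))
            quad = np.real(np.einsum("k,kl,l->", w.w[0, 0, 0].conj(), xi,
                                     w.w[0, 0, 0]))
            assert quad == pytest.approx(1.0, rel=1e-8)

    def test_zero_sensitivity_invalid(self):
        w = roemer_weights(self._receive([0.0, 0.0]),
                           NoiseCovariance(np.eye(2, dtype=complex), 10))
        assert not w.valid[0, 0, 0]


class TestResample:
    src = GridGeometry((16, 16, 8), (220.0, 200.0, 320.0))

    def test_identity_and_constant(self, rng):
        f = rng.standard_normal(self.src.matrix)
        out, extrap = resample_b1_grid(f, self.src, self.src)
        np.testing.assert_allclose(out, f, atol=1e-12)
        assert not extrap.any()
        dst = GridGeometry((20, 20, 10), (220.0, 200.0, 320.0))
        out, _ = resample_b1_grid(np.full(self.src.matrix, 3.3), self.src, dst)
        np.testing.assert_allclose(out, 3.3, atol=1e-12)

    def test_linear_field_exact_at_interior_centers(self):
        dst = GridGeometry((20, 20, 10), (220.0, 200.0, 320.0))
        x, y, z = self.src.center_coordinates_mm()
        f = 1.0 + 0.02 * x - 0.01 * y
        out, extrap = resample_b1_grid(f, self.src, dst)
        xd, yd, _ = dst.center_coordinates_mm()
        expected = 1.0 + 0.02 * xd - 0.01 * yd
        np.testing.assert_allclose(out[~extrap], expected[~extrap],
                                   atol=1e-10)
        assert extrap.any()     # finer grid reaches outside source centers

    def test_fov_mismatch_rejected(self):
        dst = GridGeometry((16, 16, 8), (200.0, 200.0, 320.0))
        with pytest.raises(ValueError):
            resample_b1_grid(np.zeros(self.src.matrix), self.src, dst)


class TestEndToEnd:
    def test_noiseless_calibration_recovers_b1_exactly(self, ref_truth_small,
                                                       noiseless_calibration):
        bundle, _ = noiseless_calibration
        sel = ref_truth_small.mask() & bundle.transmit.valid_mask
        assert sel.sum() == ref_truth_small.mask().sum()
        rel = (np.abs(bundle.transmit.b1_plus[sel]
                      - ref_truth_small.b1_plus[sel])
               / ref_truth_small.b1_plus[sel])
        assert rel.max() < 1e-6
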