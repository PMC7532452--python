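"""SPEN/EPI encoding, effective b-maps and reconstruction."""

import numpy as np
import pytest

from fetomri.io import shots_from_hdf5, shots_to_hdf5
from fetomri.phantom import build_phantom
from fetomri.spen import (
    DiffusionModule,
    EpiSequenceParams,
    GradientWaveform,
    SpenSequenceParams,
    add_rician_noise,
    bvalue_stejskal_tanner,
    default_diffusion_modules,
    effective_bmap,
    encode_epi,
    encode_spen_shot,
    epi_offresonance_shift_voxels,
    pgse_waveform,
    reconstruct_epi,
    reconstruct_spen,
    relaxation_weighted_image,
    simulate_dwi_series,
    spen_bmap_profile,
)

DM_NOMINAL = DiffusionModule(3.2, 10.0, 33.0, (0.0, 1.0, 0.0))


class TestBValues:
    def test_nominal_setting_near_750(self):
        b = bvalue_stejskal_tanner(DM_NOMINAL)
        assert abs(b - 750.0) / 750.0 < 0.10

    def test_zero_gradient_zero_b(self):
        assert bvalue_stejskal_tanner(DiffusionModule(3.2, 10.0, 0.0)) == 0.0

    def test_waveform_integration_matches_closed_form(self):
        wf, flips = pgse_waveform(DM_NOMINAL)
        numeric = float(np.asarray(effective_bmap(wf, flips).b))
        closed = bvalue_stejskal_tanner(DM_NOMINAL)
        assert abs(numeric - closed) / closed < 1e-3

    def test_zero_waveform_zero_b(self):
        wf = GradientWaveform(dt=1e-6, g=np.zeros((3, 5000)))
        assert float(np.asarray(effective_bmap(wf, [2e-3]).b)) == 0.0

    def test_quadratic_scaling_in_gradient(self):
        b1 = effective_bmap(*pgse_waveform(DiffusionModule(3.2, 10.0, 10.0))).b
        b2 = effective_bmap(*pgse_waveform(DiffusionModule(3.2, 10.0, 20.0))).b
        assert float(np.asarray(b2)) / float(np.asarray(b1)) == pytest.approx(
            4.0, rel=1e-6
        )

    def test_positionwise_flip_reduces_to_scalar_limit(self):
        # per-position flip times that are all equal must reproduce the
        # hard-pulse closed form at every position
        dm = DM_NOMINAL
        wf, (t180,) = pgse_waveform(dm)
        b_arr = effective_bmap(wf, [np.full(7, t180)]).b
        closed = bvalue_stejskal_tanner(dm)
        assert np.allclose(b_arr, closed, rtol=1e-3)

    def test_spen_bmap_minimum_positive_without_diffusion(self, spen_params_64):
        b0 = spen_bmap_profile(spen_params_64, None)
        assert b0.min() > 0
        assert b0.max() > 2 * b0.min()  # varies along the SPEN axis

    def test_spen_bmap_with_diffusion_exceeds_encoding_floor(self, spen_params_64):
        b0 = spen_bmap_profile(spen_params_64, None)
        by = spen_bmap_profile(spen_params_64, DM_NOMINAL)
        assert np.all(by > b0)
        assert np.all(by > 600)

    def test_invalid_module(self):
        with pytest.raises(ValueError):
            DiffusionModule(11.0, 10.0, 33.0)
        with pytest.raises(ValueError):
            DiffusionModule(3.2, 10.0, 33.0, (1.0, 1.0, 0.0))


class TestSpenEncoding:
    def test_zero_phantom_zero_samples(self, spen_params_64):
        shot = encode_spen_shot(np.zeros((64, 64)), spen_params_64, shot_index=0)
        assert np.all(shot.samples == 0)

    def test_kshot_offset_is_object_phase_ramp(self, spen_params_64, rng):
        img = rng.random((64, 64)) + 1j * rng.random((64, 64))
        p = spen_params_64
        y = p.spen_positions_cm
        ramp = np.exp(1j * 2 * p.dk_fine * y)[:, None]
        direct = encode_spen_shot(img, p, shot_index=2)
        via_ramp = encode_spen_shot(img * ramp, p, shot_index=0)
        assert np.allclose(direct.samples, via_ramp.samples, atol=1e-10)

    def test_encode_matches_dense_operator_oracle(self, spen_params_64, rng):
        # independent re-derivation: quadratic phase + coarse raster +
        # orthonormal DFT readout, contracted by einsum
        p = spen_params_64
        n, K = p.matrix, p.n_interleaves
        img = rng.random((n, n)) + 1j * rng.random((n, n))
        L = p.fov_cm
        y = (np.arange(n) - n // 2) * (L / n)
        phi = -(np.pi * p.r_factor / L**2) * y**2
        j = np.arange(n // K)
        s = 1
        k = (2 * np.pi / L) * (K * (j - n / (2 * K)) + s)
        enc = np.exp(1j * (phi[None, :] + k[:, None] * y[None, :]))
        x = np.arange(n)
        dft = np.exp(-2j * np.pi * np.outer(x, x) / n) / np.sqrt(n)
        oracle = np.einsum("ly,yx,mx->ml", enc, img, dft)
        shot = encode_spen_shot(img, p, shot_index=s)
        assert np.allclose(shot.samples, oracle, atol=1e-9)

    def test_roundtrip_smooth_phantom(self, spen_params_64, wt_phantom_64):
        p = spen_params_64
        img = relaxation_weighted_image(wt_phantom_64, p.tr, p.te).astype(complex)
        shots = [encode_spen_shot(img, p, shot_index=s) for s in range(4)]
        rec = reconstruct_spen(shots, p)
        nrmse = np.sqrt(np.mean((rec - np.abs(img)) ** 2)) / (
            np.abs(img).max() - np.abs(img).min()
        )
        assert nrmse < 0.05

    def test_point_source_localization(self, spen_params_64):
        e = np.zeros((64, 64))
        e[40, 22] = 1.0
        shots = [encode_spen_shot(e, spen_params_64, shot_index=s) for s in range(4)]
        rec = reconstruct_spen(shots, spen_params_64)
        peak = np.unravel_index(rec.argmax(), rec.shape)
        assert abs(peak[0] - 40) <= 1 and abs(peak[1] - 22) <= 1

    def test_interleaving_improves_resolving_power(self, spen_params_64):
        # a single shot leaves K-fold positional ambiguity (aliases at N/K
        # spacing); the full interleave set concentrates the point response
        p = spen_params_64
        e = np.zeros((64, 64))
        e[40, 22] = 1.0
        shots = [encode_spen_shot(e, p, shot_index=s) for s in range(4)]
        full = reconstruct_spen(shots, p)[:, 22] ** 2
        single = reconstruct_spen(shots[:1], p, allow_partial=True)[:, 22] ** 2

        def concentration(prof):
            idx = np.arange(64)
            near = np.abs(idx - 40) <= 2
            return prof[near].sum() / prof.sum()

        ratio = concentration(full) / concentration(single)
        K = p.n_interleaves
        assert 0.6 * K < ratio < 1.4 * K

    def test_recon_requires_all_distinct_shots(self, spen_params_64):
        img = np.ones((64, 64), dtype=complex)
        shots = [encode_spen_shot(img, spen_params_64, shot_index=s) for s in range(4)]
        with pytest.raises(ValueError, match="shots"):
            reconstruct_spen(shots[:3], spen_params_64)
        with pytest.raises(ValueError, match="duplicate"):
            reconstruct_spen(shots[:3] + [shots[2]], spen_params_64)

    def test_shape_and_matrix_validation(self, spen_params_64):
        with pytest.raises(ValueError, match="shape"):
            encode_spen_shot(np.ones((32, 32)), spen_params_64)
        with pytest.raises(ValueError):
            SpenSequenceParams(matrix=62, n_interleaves=4)


class TestEpi:
    def test_roundtrip(self, wt_phantom_64):
        ep = EpiSequenceParams(fov=30.0, matrix=64, n_interleaves=4)
        img = relaxation_weighted_image(wt_phantom_64, ep.tr, ep.te).astype(complex)
        rec = reconstruct_epi(encode_epi(img, ep), ep)
        nrmse = np.sqrt(np.mean((rec - np.abs(img)) ** 2)) / np.abs(img).max()
        assert nrmse < 0.01

    def test_offresonance_shift_matches_prediction(self, wt_phantom_64):
        from fetomri.experiments import _row_displacement

        ep = EpiSequenceParams(fov=30.0, matrix=64, n_interleaves=4)
        img = relaxation_weighted_image(wt_phantom_64, ep.tr, ep.te).astype(complex)
        ref = reconstruct_epi(encode_epi(img, ep), ep)
        off = reconstruct_epi(
            encode_epi(img, ep, b0_offmap=np.full((64, 64), 300.0)), ep
        )
        measured = _row_displacement(ref, off)
        predicted = epi_offresonance_shift_voxels(ep, 300.0)
        assert abs(measured - predicted) <= 1.0

    def test_spen_less_displaced_than_epi(self, wt_phantom_64, spen_params_64):
        from fetomri.experiments import _row_displacement

        p, ep = spen_params_64, EpiSequenceParams(fov=30.0, matrix=64, n_interleaves=4)
        img = relaxation_weighted_image(wt_phantom_64, p.tr, p.te).astype(complex)
        offmap = np.full((64, 64), 300.0)

        def spen_rec(om):
            shots = [
                encode_spen_shot(img, p, shot_index=s, b0_offmap=om) for s in range(4)
            ]
            return reconstruct_spen(shots, p)

        spen_shift = _row_displacement(spen_rec(None), spen_rec(offmap))
        epi_shift = _row_displacement(
            reconstruct_epi(encode_epi(img, ep), ep),
            reconstruct_epi(encode_epi(img, ep, b0_offmap=offmap), ep),
        )
        assert spen_shift < epi_shift


class TestNoise:
    def test_infinite_snr_identity(self, rng):
        x = rng.random((32, 32))
        assert np.array_equal(add_rician_noise(x, snr=np.inf, seed=0), x)

    def test_seeded_determinism(self, rng):
        x = rng.random((32, 32))
        a = add_rician_noise(x, snr=10, seed=5)
        b = add_rician_noise(x, snr=10, seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, add_rician_noise(x, snr=10, seed=6))

    def test_rayleigh_floor_on_zero_image(self):
        sigma = 0.7
        out = add_rician_noise(np.zeros(100_000), sigma=sigma, seed=3)
        expected = sigma * np.sqrt(np.pi / 2)
        assert abs(out.mean() - expected) / expected < 0.02


class TestDwiSeries:
    def test_requires_b0_entry(self, wt_phantom_64, spen_params_64):
        with pytest.raises(ValueError, match="b≈0"):
            simulate_dwi_series(
                wt_phantom_64, spen_params_64, dms=(DM_NOMINAL,), seed=0
            )

    def test_isotropic_phantom_direction_invariance(self, spen_params_64):
        ph = build_phantom("wildtype", 14.5, (64, 64), seed=3, jitter=False)
        ph.truth_maps["adc"][:] = 1.0e-3
        series = simulate_dwi_series(ph, spen_params_64, seed=0)
        d = series.images[1:]
        rel = np.abs(d - d.mean(axis=0)).max() / d.mean()
        assert rel < 0.05

    def test_zero_adc_images_equal_b0(self, spen_params_64):
        ph = build_phantom("wildtype", 14.5, (64, 64), seed=3, jitter=False)
        ph.truth_maps["adc"][:] = 1e-12
        series = simulate_dwi_series(ph, spen_params_64, seed=0)
        for i in range(1, 4):
            assert np.allclose(series.images[i], series.images[0], rtol=1e-6,
                               atol=1e-9)

    def test_deterministic_given_seed(self, wt_phantom_64, spen_params_64):
        a = simulate_dwi_series(wt_phantom_64, spen_params_64, snr=40, seed=9)
        b = simulate_dwi_series(wt_phantom_64, spen_params_64, snr=40, seed=9)
        assert np.array_equal(a.images, b.images)


def test_shot_hdf5_roundtrip(tmp_path, spen_params_64, rng):
    img = rng.random((64, 64)).astype(complex)
    shots = [encode_spen_shot(img, spen_params_64, shot_index=s) for s in range(4)]
    path = tmp_path / "shots.h5"
    shots_to_hdf5(shots, path)
    back = shots_from_hdf5(path)
    for s0, s1 in zip(shots, back):
        assert np.allclose(s0.samples, s1.samples)
        assert s0.shot_index == s1.shot_index
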