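"""Tilt-series simulation: projection geometry, optics, noise, WBP
reconstruction and subtomogram extraction."""

import numpy as np
import pytest

from tomoshot.phantoms import DensityMap, make_phantom
from tomoshot.simulate import (OpticsParams, SimulationConfig, TiltSeries,
                               add_noise_to_snr, apply_ctf_mtf, backproject,
                               build_dataset, ctf_mtf_transfer,
                               extract_subtomograms, pack_volume,
                               project_tilt_series, reconstruct_wbp)


@pytest.fixture(scope="module")
def ball48():
    return make_phantom({"kind": "sphere", "radius": 10}, 48).grid.astype(float)


class TestProjection:
    def test_zero_tilt_equals_axis_sum(self, ball48):
        ts = project_tilt_series(ball48, [0.0])
        assert np.array_equal(ts.images[0], ball48.sum(axis=2))

    def test_mass_conserved_at_any_angle(self, ball48):
        total = ball48.sum()
        for angle in (-55.0, 17.0, 42.0):
            ts = project_tilt_series(ball48, [angle])
            assert abs(ts.images[0].sum() - total) / total < 0.01

    def test_ball_projection_matches_chord_length(self, ball48):
        # line integral through a uniform unit ball: 2 sqrt(r^2 - d^2)
        r = 10.0
        ts = project_tilt_series(ball48, [33.0])
        profile = ts.images[0][24]  # row through the ball center
        d = np.arange(48) - 24
        chord = 2 * np.sqrt(np.clip(r**2 - d.astype(float) ** 2, 0, None))
        # digitization of the hard sphere edge dominates at the rim; the
        # interior must match the analytic chord to interpolation tolerance
        interior = np.abs(d) <= 8
        assert np.abs(profile - chord)[interior].max() < 1.0
        assert np.sqrt(((profile - chord) ** 2).mean()) < 1.5

    def test_out_of_range_angles_rejected(self, ball48):
        with pytest.raises(ValueError, match="-90, 90"):
            project_tilt_series(ball48, [0.0, 90.0])

    def test_projection_backprojection_adjoint(self, rng):
        v = rng.normal(size=(20, 20, 20))
        angles = [-60.0, -25.0, 0.0, 30.0, 55.0]
        ts = project_tilt_series(v, angles)
        t = rng.normal(size=ts.images.shape)
        lhs = float((ts.images * t).sum())
        rhs = float((v * backproject(TiltSeries(t, angles), v.shape)).sum())
        assert abs(lhs - rhs) / abs(lhs) < 1e-4


class TestOptics:
    def test_disabled_optics_pass_through(self, ball48, rng):
        ts = project_tilt_series(ball48, [0.0, 10.0])
        out = apply_ctf_mtf(ts, OpticsParams(enabled=False))
        assert np.array_equal(out.images, ts.images)

    def test_frequency_multiplication_equals_circular_convolution(self, rng):
        # brute-force oracle: circular spatial convolution with the transfer
        # function's inverse transform
        img = rng.normal(size=(16, 16))
        optics = OpticsParams()
        transfer = ctf_mtf_transfer((16, 16), 10.0, optics)
        out = apply_ctf_mtf(TiltSeries(img[None], [0.0]), optics).images[0]
        kernel = np.real(np.fft.ifft2(transfer))
        brute = np.zeros_like(img)
        for i in range(16):
            for j in range(16):
                for di in range(16):
                    for dj in range(16):
                        brute[i, j] += img[(i - di) % 16, (j - dj) % 16] * kernel[di, dj]
        assert np.abs(out - brute).max() < 1e-6

    def test_mtf_suppresses_high_frequencies(self, ball48):
        ts = project_tilt_series(ball48, [0.0])
        out = apply_ctf_mtf(ts, OpticsParams())
        f_in = np.abs(np.fft.fft2(ts.images[0]))
        f_out = np.abs(np.fft.fft2(out.images[0]))
        freqs = np.fft.fftfreq(48)
        f2 = np.sqrt(freqs[:, None] ** 2 + freqs[None, :] ** 2)
        hi = f2 > 0.8 * 0.5
        assert f_out[hi].sum() < f_in[hi].sum()


class TestNoise:
    def test_infinite_snr_is_identity(self, ball48, rng):
        ts = project_tilt_series(ball48, [0.0])
        out = add_noise_to_snr(ts, np.inf, rng)
        assert np.array_equal(out.images, ts.images)

    def test_noise_variance_hits_target_snr(self, rng):
        signal = rng.normal(size=(1, 600, 600))
        ts = TiltSeries(signal, [0.0])
        out = add_noise_to_snr(ts, 0.5, rng)
        injected = out.images - ts.images
        measured = signal.var() / injected.var()
        assert abs(measured - 0.5) / 0.5 < 0.05

    def test_fixed_seed_reproducible(self, ball48):
        ts = project_tilt_series(ball48, [0.0])
        a = add_noise_to_snr(ts, 1.0, np.random.default_rng(3))
        b = add_noise_to_snr(ts, 1.0, np.random.default_rng(3))
        assert np.array_equal(a.images, b.images)

    def test_nonpositive_snr_rejected(self, ball48, rng):
        ts = project_tilt_series(ball48, [0.0])
        with pytest.raises(ValueError, match="positive"):
            add_noise_to_snr(ts, 0.0, rng)


class TestReconstruction:
    def test_zero_tilt_series_gives_zero_volume(self):
        ts = TiltSeries(np.zeros((5, 16, 16)), np.arange(-20.0, 21.0, 10.0))
        rec = reconstruct_wbp(ts, (16, 16, 16))
        assert not rec.any()

    def test_near_full_range_reconstruction_correlates(self, ball48):
        angles = np.arange(-89.0, 89.01, 1.0)
        ts = project_tilt_series(ball48, angles)
        rec = reconstruct_wbp(ts, ball48.shape)
        corr = np.corrcoef(rec.ravel(), ball48.ravel())[0, 1]
        assert corr > 0.9

    def test_missing_wedge_fourier_suppression(self, ball48):
        ts = project_tilt_series(ball48, np.arange(-60.0, 60.01, 2.0))
        rec = reconstruct_wbp(ts, ball48.shape)
        spec = np.abs(np.fft.fftshift(np.fft.fftn(rec))).mean(axis=0)
        n = ball48.shape[0]
        kw, kd = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                             indexing="ij")
        # beam along D at zero tilt: the unsampled wedge hugs the D axis
        ang = np.degrees(np.arctan2(np.abs(kw), np.abs(kd)))
        radius = np.hypot(kw, kd)
        shell = (radius > 4) & (radius < n // 2)
        wedge = spec[(ang < 25) & shell].mean()
        sampled = spec[(ang > 35) & shell].mean()
        assert wedge < 0.2 * sampled

    def test_single_projection_warns(self, ball48):
        ts = project_tilt_series(ball48, [0.0])
        with pytest.warns(UserWarning, match="ill-posed"):
            reconstruct_wbp(ts, ball48.shape)


class TestPacking:
    def test_zero_particles(self, rng):
        maps = [make_phantom({"kind": "sphere", "radius": 4}, 16)]
        vol, placements = pack_volume(maps, 0, (64, 64, 64), rng)
        assert not vol.any() and placements == []

    def test_single_particle_conserves_mass(self, rng):
        maps = [make_phantom({"kind": "sphere", "radius": 4}, 16)]
        vol, placements = pack_volume(maps, 1, (64, 64, 64), rng)
        assert len(placements) == 1
        total = maps[0].grid.sum()
        assert abs(vol.sum() - total) / total < 0.02

    def test_bounding_spheres_do_not_overlap(self, rng):
        maps = [make_phantom({"kind": "sphere", "radius": 4}, 16)]
        vol, placements = pack_volume(maps, 50, (100, 100, 100), rng)
        centers = np.array([p[2] for p in placements], dtype=float)
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                assert np.linalg.norm(centers[i] - centers[j]) > 8.0

    def test_overfull_volume_warns_and_truncates(self, rng):
        maps = [make_phantom({"kind": "sphere", "radius": 5}, 16)]
        with pytest.warns(UserWarning, match="packing stopped"):
            _, placements = pack_volume(maps, 500, (40, 40, 40), rng,
                                        max_retries=50)
        assert 0 < len(placements) < 500


class TestExtraction:
    def _setup(self, rng):
        maps = [make_phantom({"kind": "sphere", "radius": 5}, 32)]
        vol, placements = pack_volume(
            maps, 5, (96, 96, 96), rng, margin=16)
        return maps, vol, placements

    def test_center_placement_is_exact_crop(self, rng):
        maps, vol, placements = self._setup(rng)
        recs = extract_subtomograms(vol, placements, 32,
                                    {m.name: m for m in maps})
        for rec, (name, pose, pos) in zip(recs, placements):
            sl = tuple(slice(p - 16, p + 16) for p in pos)
            assert np.array_equal(rec.volume, vol[sl].astype(np.float32))

    def test_out_of_bounds_placements_skipped(self, rng):
        maps, vol, placements = self._setup(rng)
        near_face = [(placements[0][0], placements[0][1], np.array([3, 48, 48]))]
        with pytest.warns(UserWarning, match="skipped"):
            recs = extract_subtomograms(vol, placements + near_face, 32,
                                        {m.name: m for m in maps})
        assert len(recs) == len(placements)

    def test_record_count_matches_in_bounds_placements(self, rng):
        maps, vol, placements = self._setup(rng)
        recs = extract_subtomograms(vol, placements, 32,
                                    {m.name: m for m in maps})
        assert len(recs) == len(placements)


@pytest.fixture(scope="module")
def tiny_config():
    return SimulationConfig(tomogram_shape=(72, 72, 64), n_particles=12,
                            tilt_step=10.0, seed=11, n_test_classes=2)


class TestBuildDataset:
    def test_split_is_class_disjoint(self, tiny_config):
        from tomoshot.phantoms import phantom_library

        ds = build_dataset(tiny_config, phantom_library()[:6])
        assert not set(ds.train_classes) & set(ds.test_classes)
        for r in ds.records:
            expected = "test" if r.class_label in ds.test_classes else "train"
            assert r.split == expected

    def test_same_seed_reproducible(self, tiny_config):
        from tomoshot.phantoms import phantom_library

        maps = phantom_library()[:4]
        a = build_dataset(tiny_config, maps)
        b = build_dataset(tiny_config, maps)
        assert len(a.records) == len(b.records)
        for ra, rb in zip(a.records, b.records):
            assert ra.class_label == rb.class_label
            assert np.array_equal(ra.volume, rb.volume)

    def test_too_many_test_classes_rejected(self, tiny_config):
        from tomoshot.phantoms import phantom_library

        with pytest.raises(ValueError, match="hold out"):
            build_dataset(SimulationConfig(n_test_classes=2, seed=0),
                          phantom_library()[:2])


class TestPipelineProperties:
    def test_end_to_end_linearity_noiseless(self, rng):
        # simulate(v1 + v2) == simulate(v1) + simulate(v2) for the linear
        # chain projection -> optics -> reconstruction
        v1 = rng.random((24, 24, 24))
        v2 = rng.random((24, 24, 24))
        angles = np.arange(-60.0, 60.01, 15.0)
        optics = OpticsParams()

        def sim(v):
            ts = project_tilt_series(v, angles)
            ts = apply_ctf_mtf(ts, optics)
            return reconstruct_wbp(ts, v.shape)

        lhs = sim(v1 + v2)
        rhs = sim(v1) + sim(v2)
        assert np.abs(lhs - rhs).max() < 1e-5 * max(1.0, np.abs(lhs).max())

    def test_reconstruction_error_grows_as_snr_drops(self, ball48):
        angles = np.arange(-60.0, 60.01, 4.0)
        ts = project_tilt_series(ball48, angles)
        clean = reconstruct_wbp(ts, ball48.shape)
        errors = []
        for snr in (np.inf, 1000.0, 0.5):
            noisy = add_noise_to_snr(ts, snr, np.random.default_rng(5))
            rec = reconstruct_wbp(noisy, ball48.shape)
            errors.append(float(((rec - clean) ** 2).mean()))
        assert errors[0] < errors[1] < errors[2]
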