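"""Simulator statistics: Poisson placement, photon accounting, noise model."""

import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import erf

from patchsmlm import (
    AstigmaticCalibration,
    EmitterList,
    NoiseParams,
    SimulationConfig,
    VideoStack,
    render_frame,
    render_frame_3d,
    simulate_emitters,
    simulate_video,
)
from patchsmlm.simulator import accumulate_gaussians, simulate_two_region_video

PATCH_NM = 64 * 233.0  # 14.9 um patch side


class TestSimulateEmitters:
    def test_zero_density_gives_empty_list(self):
        em = simulate_emitters(PATCH_NM, PATCH_NM, 0.0, n_frames=10, seed=0)
        assert len(em) == 0

    def test_mean_count_matches_poisson_rate(self):
        # rho = 2.0 on a 14.9 um square: lambda = 2.0 * 14.912^2 = 444.7 per frame
        em = simulate_emitters(14.9e3, 14.9e3, 2.0, n_frames=10_000, seed=1)
        lam = 2.0 * 14.9**2
        counts = em.df.groupby("frame").size().reindex(range(10_000), fill_value=0)
        se = math.sqrt(lam / 10_000)
        assert abs(counts.mean() - lam) < 3 * se

    def test_counts_pass_poisson_goodness_of_fit(self):
        rho, side_nm = 1.0, 10_000.0
        lam = rho * (side_nm / 1000.0) ** 2  # 100 per frame
        em = simulate_emitters(side_nm, side_nm, rho, n_frames=10_000, seed=2)
        counts = em.df.groupby("frame").size().reindex(range(10_000), fill_value=0).to_numpy()
        # bin the Poisson distribution so every expected count is >= 5
        edges = np.arange(lam - 40, lam + 41, 5)
        obs, _ = np.histogram(counts, bins=edges)
        cdf = sps.poisson.cdf(edges - 1, lam)
        exp = np.diff(cdf) * len(counts)
        keep = exp >= 5
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_positions_inside_half_open_fov(self):
        em = simulate_emitters(1000.0, 2000.0, 5.0, n_frames=50, seed=3)
        assert (em.df.x_nm >= 0).all() and (em.df.x_nm < 1000.0).all()
        assert (em.df.y_nm >= 0).all() and (em.df.y_nm < 2000.0).all()

    @pytest.mark.parametrize("bad", [dict(density_um2=-1.0), dict(fov_w_nm=-5.0), dict(n_frames=0)])
    def test_invalid_inputs_rejected(self, bad):
        kw = dict(fov_w_nm=1000.0, fov_h_nm=1000.0, density_um2=1.0, n_frames=5, seed=0)
        kw.update(bad)
        with pytest.raises(ValueError):
            simulate_emitters(**kw)

    def test_seed_reproducibility(self):
        a = simulate_emitters(5000.0, 5000.0, 1.0, 20, seed=7)
        b = simulate_emitters(5000.0, 5000.0, 1.0, 20, seed=7)
        assert a.df.equals(b.df)


class TestRenderFrame:
    def test_no_emitters_no_noise_gives_zero_frame(self, default_optics):
        noise = NoiseParams(background_photons=0, gauss_mean=0, gauss_std=0, poisson_enabled=False)
        frame = render_frame(EmitterList().df, 1.5, noise, default_optics, (32, 32), seed=0)
        assert np.all(frame == 0)

    def test_photon_conservation_centered_emitter(self, default_optics):
        # pixel-integrated Gaussian: in-frame mass of a centered sigma=1.5 spot
        # differs from the total photons by the erf tail only
        noise = NoiseParams(background_photons=0, gauss_mean=0, gauss_std=0, poisson_enabled=False)
        p = default_optics.pixel_size_nm
        em = EmitterList.from_arrays([0], [32.0 * p], [32.0 * p], [1000.0])
        frame = render_frame(em.df, 1.5, noise, default_optics, (64, 64), seed=0)
        assert abs(frame.sum() - 1000.0) < 5.0  # within 0.5 %

    def test_peak_pixel_matches_erf_oracle(self, default_optics):
        # emitter at the center of pixel (16, 16): peak = N * erf(0.5/(sigma sqrt 2))^2
        noise = NoiseParams(background_photons=0, gauss_mean=0, gauss_std=0, poisson_enabled=False)
        p = default_optics.pixel_size_nm
        sigma = 1.5
        em = EmitterList.from_arrays([0], [16.5 * p], [16.5 * p], [1000.0])
        frame = render_frame(em.df, sigma, noise, default_optics, (32, 32), seed=0)
        expected = 1000.0 * erf(0.5 / (sigma * math.sqrt(2))) ** 2
        assert frame[16, 16] == pytest.approx(expected, rel=1e-6)
        assert frame.argmax() == 16 * 32 + 16

    def test_invalid_sigma_rejected(self, default_optics, default_noise):
        with pytest.raises(ValueError):
            render_frame(EmitterList().df, 0.0, default_noise, default_optics, (8, 8))

    def test_out_of_frame_mass_is_lost(self, default_optics):
        noise = NoiseParams(background_photons=0, gauss_mean=0, gauss_std=0, poisson_enabled=False)
        p = default_optics.pixel_size_nm
        em = EmitterList.from_arrays([0], [0.5 * p], [16.0 * p], [1000.0])  # at the left edge
        frame = render_frame(em.df, 1.5, noise, default_optics, (32, 32), seed=0)
        assert frame.sum() < 700.0


class TestRenderFrame3d:
    def test_symmetric_at_focus(self, default_optics):
        calib = AstigmaticCalibration()
        assert calib.sigma_x(300.0) != calib.sigma_y(300.0)  # astigmatic off focus
        sym = AstigmaticCalibration(gamma_nm=0.0)
        assert sym.sigma_x(123.0) == pytest.approx(sym.sigma_y(123.0))
        noise = NoiseParams(background_photons=0, gauss_mean=0, gauss_std=0, poisson_enabled=False)
        p = default_optics.pixel_size_nm
        em = EmitterList.from_arrays([0], [16.5 * p], [16.5 * p], [1000.0], z_nm=[0.0])
        frame = render_frame_3d(em.df, sym, noise, default_optics, (32, 32), seed=0)
        assert np.allclose(frame, frame.T, atol=1e-9)

    def test_aspect_ratio_monotone_in_z(self):
        calib = AstigmaticCalibration()
        zs = np.linspace(0, 400, 6)
        ratios = calib.sigma_x(zs) / calib.sigma_y(zs)
        assert np.all(np.diff(ratios) < 0)  # x narrows relative to y with +z

    def test_z_outside_range_rejected(self, default_optics, default_noise):
        calib = AstigmaticCalibration(z_range_nm=(-500.0, 500.0))
        em = EmitterList.from_arrays([0], [100.0], [100.0], [10.0], z_nm=[900.0])
        with pytest.raises(ValueError):
            render_frame_3d(em.df, calib, default_noise, default_optics, (16, 16))

    def test_background_only_without_emitters(self, default_optics):
        noise = NoiseParams(background_photons=5.0, gauss_mean=0, gauss_std=0, poisson_enabled=False)
        frame = render_frame_3d(EmitterList().df, AstigmaticCalibration(), noise, default_optics, (16, 16), seed=0)
        assert np.all(frame == 5.0)


class TestSimulateVideo:
    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_frames=0)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_frames=5, width_px=32, height_px=32, density_um2=0.5, snr=6.0)
        v1, e1 = simulate_video(cfg, seed=11)
        v2, e2 = simulate_video(cfg, seed=11)
        assert np.array_equal(v1.frames, v2.frames)
        assert e1.df.equals(e2.df)

    def test_tiff_and_csv_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_frames=4, width_px=32, height_px=32, density_um2=0.5, snr=8.0)
        tif = tmp_path / "stack.tif"
        csv = tmp_path / "truth.csv"
        video, truth = simulate_video(cfg, seed=4, tiff_path=tif, csv_path=csv)
        reloaded = VideoStack.from_tiff(tif)
        assert np.array_equal(video.frames, reloaded.frames)  # bit-exact integer frames
        assert reloaded.optics.pixel_size_nm == cfg.optics.pixel_size_nm
        back = EmitterList.from_csv(csv)
        assert len(back) == len(truth)
        np.testing.assert_allclose(back.df.x_nm, truth.df.x_nm, rtol=1e-12)

    def test_two_region_video_places_emitters_per_side(self):
        left = SimulationConfig(n_frames=5, width_px=32, height_px=32, density_um2=2.0, snr=8.0)
        right = left.replace(density_um2=0.0)
        video, em = simulate_two_region_video(left, right, seed=9)
        assert video.frames.shape == (5, 32, 64)
        assert (em.df.x_nm < 32 * 233.0).all()


class TestAccumulateGaussians:
    def test_matches_dense_erf_rendering(self, rng):
        # oracle: brute-force per-pixel erf integral over the full frame
        xs, ys = rng.uniform(5, 25, 4), rng.uniform(5, 25, 4)
        photons = rng.uniform(100, 1000, 4)
        sigma = 1.2
        out = accumulate_gaussians((30, 30), xs, ys, photons, sigma)
        cols = np.arange(31, dtype=float)
        dense = np.zeros((30, 30))
        for x, y, n in zip(xs, ys, photons):
            gx = 0.5 * np.diff(erf((cols - x) / (sigma * math.sqrt(2))))
            gy = 0.5 * np.diff(erf((cols - y) / (sigma * math.sqrt(2))))
            dense += n * np.outer(gy, gx)
        np.testing.assert_allclose(out, dense, atol=5e-3)  # window truncation at 4 sigma

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            accumulate_gaussians((8, 8), [4.0], [4.0], [10.0], 0.0)
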