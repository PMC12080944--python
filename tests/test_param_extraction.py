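"""Parameter extraction: PSF fitting, peak detection, density and SNR estimates."""

import math

import numpy as np
import pytest
from scipy.special import erf

from patchsmlm import (
    EmitterList,
    GlobalFrameStats,
    NoiseParams,
    PSFStats,
    SimulationConfig,
    characterize_psf,
    detect_peaks,
    estimate_density,
    estimate_snr,
    global_stats,
    patch_stats,
    photons_for_peak_snr,
    render_frame,
    signal_noise_mask,
    simulate_video,
)
from patchsmlm.simulator import VideoStack, simulate_two_region_video

from conftest import noiseless_config


def context_video(density, snr, n_frames=30, seed=0):
    """Target condition on the left half, near-empty background on the right.

    Mirrors real acquisitions, where the full field of view used for the
    global statistics always contains structure-free regions.
    """
    cfg = SimulationConfig(n_frames=n_frames, density_um2=density, snr=snr)
    return simulate_two_region_video(cfg, cfg.replace(density_um2=0.05), seed=seed)


class TestGlobalStats:
    def test_constant_frames(self):
        video = VideoStack(frames=np.full((3, 16, 16), 7.0))
        gs = global_stats(video)
        assert gs.image_mean == 7.0
        assert gs.image_std == 0.0

    def test_iid_gaussian_mean_within_clt_bound(self, rng):
        frame = rng.normal(100.0, 5.0, (64, 64))
        video = VideoStack(frames=np.clip(frame, 0, None)[None])
        gs = global_stats(video)
        se = 5.0 / 64.0  # sigma / sqrt(n pixels)
        assert abs(gs.image_mean - 100.0) < 3 * se

    def test_rough_density_within_25_percent(self):
        video, _ = context_video(1.0, 8.0, seed=3)
        gs = global_stats(video, n_frames=30)
        # left half carries rho=1.0, right half 0.05: FOV average 0.525
        assert gs.rough_density_um2 == pytest.approx(0.525, rel=0.25)


class TestDetectPeaks:
    def test_constant_patch_has_no_peaks(self):
        gs = GlobalFrameStats(image_mean=5.0, image_std=0.0)
        assert len(detect_peaks(np.full((16, 16), 5.0), gs)) == 0

    def test_single_emitter_detected_as_exactly_one_peak(self, default_optics, default_noise):
        photons = photons_for_peak_snr(8.0, 0.5, default_noise)
        gs = GlobalFrameStats(
            image_mean=default_noise.gauss_mean + default_noise.background_photons,
            image_std=default_noise.total_noise_std,
        )
        hits = 0
        n = 400
        for seed in range(n):
            sub = np.random.default_rng(50_000 + seed)
            x = (8 + sub.uniform(-0.5, 0.5)) * 233.0
            y = (8 + sub.uniform(-0.5, 0.5)) * 233.0
            em = EmitterList.from_arrays([0], [x], [y], [photons])
            frame = render_frame(em.df, 0.5, default_noise, default_optics, (16, 16), seed=seed)
            hits += len(detect_peaks(frame, gs)) == 1
        assert hits / n >= 0.99

    def test_two_emitters_four_sigma_apart_give_two_peaks(self, default_optics):
        noise = NoiseParams()
        sigma = 1.5
        photons = photons_for_peak_snr(8.0, sigma, noise)
        gs = GlobalFrameStats(image_mean=120.0, image_std=noise.total_noise_std)
        p = default_optics.pixel_size_nm
        hits = 0
        for seed in range(50):
            em = EmitterList.from_arrays([0, 0], [10.5 * p, 16.5 * p], [13.5 * p, 13.5 * p], [photons] * 2)
            frame = render_frame(em.df, sigma, noise, default_optics, (27, 27), seed=seed)
            hits += len(detect_peaks(frame, gs, min_separation=3)) == 2
        assert hits >= 45


class TestDensityAndMask:
    def test_density_is_count_over_area(self):
        assert estimate_density(np.empty((0, 2)), 222.01) == 0.0
        peaks = np.zeros((10, 2), int)
        assert estimate_density(peaks, 14.9**2) == pytest.approx(10 / 222.01, rel=1e-3)
        per_frame = [np.zeros((3, 2)), np.zeros((5, 2))]
        assert estimate_density(per_frame, 100.0) == pytest.approx(0.04)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.zeros((1, 2)), 0.0)

    def test_mask_disk_radius_and_partition(self, known_psf):
        psf15 = PSFStats(sigma_mean=1.5, sigma_std=0.0, amp_mean=1.0, amp_std=0.0, n_fits=1)
        mask = signal_noise_mask((21, 21), np.array([[10, 10]]), psf15)
        yy, xx = np.mgrid[:21, :21]
        expected = (yy - 10) ** 2 + (xx - 10) ** 2 <= 9  # radius ceil(2 * 1.5) = 3
        assert np.array_equal(mask, expected)
        # partition identity: signal + noise pixels = all pixels
        assert mask.sum() + (~mask).sum() == 21 * 21

    def test_no_peaks_gives_empty_mask(self, known_psf):
        assert signal_noise_mask((8, 8), np.empty((0, 2)), known_psf).sum() == 0


class TestEstimateSnr:
    def test_pure_noise_patch_gives_zero_snr(self, known_psf, rng):
        patch = rng.normal(100, 10, (32, 32))
        st = estimate_snr(patch, np.zeros((32, 32), bool), np.empty((0, 2)))
        assert st.snr == 0.0

    def test_noiseless_signal_gives_top_bin_sentinel(self, known_psf):
        patch = np.zeros((16, 16))
        patch[8, 8] = 50.0
        mask = signal_noise_mask((16, 16), np.array([[8, 8]]), known_psf)
        st = estimate_snr(patch, mask, np.array([[8, 8]]))
        assert math.isinf(st.snr)

    def test_amplitude_80_over_noise_10_gives_snr_8(self, default_optics):
        # pixel-centered emitters with peak amplitude 80 counts over a
        # sigma=10 Gaussian background: SNR estimate approx 8 within 15 %
        noise = NoiseParams(background_photons=0.0, gauss_mean=100.0, gauss_std=10.0, poisson_enabled=False)
        sigma = 0.5
        photons = 80.0 / (erf(0.5 / (sigma * math.sqrt(2))) ** 2)
        psf = PSFStats(sigma_mean=sigma, sigma_std=0.0, amp_mean=1.0, amp_std=0.0, n_fits=1)
        p = default_optics.pixel_size_nm
        gs = GlobalFrameStats(image_mean=100.0, image_std=10.0)
        snrs = []
        for seed in range(100):
            xs = (np.array([8, 24, 8, 24]) + 0.5) * p
            ys = (np.array([8, 8, 24, 24]) + 0.5) * p
            em = EmitterList.from_arrays([0] * 4, xs, ys, [photons] * 4)
            frame = render_frame(em.df, sigma, noise, default_optics, (32, 32), seed=seed)
            peaks = detect_peaks(frame, gs)
            mask = signal_noise_mask(frame.shape, peaks, psf)
            snrs.append(estimate_snr(frame, mask, peaks).snr)
        assert np.mean(snrs) == pytest.approx(8.0, rel=0.15)

    def test_mask_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_snr(rng.normal(size=(8, 8)), np.zeros((4, 4), bool), np.empty((0, 2)))


class TestCharacterizePsf:
    def test_noiseless_sigma_recovered_within_2_percent(self):
        cfg = noiseless_config(n_frames=60, width_px=128, height_px=128, density_um2=0.02, psf_sigma_px=1.5)
        video, _ = simulate_video(cfg, seed=3)
        psf = characterize_psf(video, max_events=100, sigma_guess=1.5)
        assert psf.sigma_mean == pytest.approx(1.5, rel=0.02)

    def test_sigma_recovered_within_5_percent_at_snr_8(self):
        cfg = SimulationConfig(n_frames=60, width_px=128, height_px=128, density_um2=0.05, snr=8.0)
        video, _ = simulate_video(cfg, seed=4)
        psf = characterize_psf(video, max_events=100, sigma_guess=1.0)
        assert psf.sigma_mean == pytest.approx(0.5, rel=0.05)

    def test_pure_noise_raises(self, rng):
        video = VideoStack(frames=np.clip(rng.normal(100, 10, (10, 64, 64)), 0, None))
        with pytest.raises(ValueError, match="no emission events"):
            characterize_psf(video)

    def test_event_budget_respected(self):
        cfg = SimulationConfig(n_frames=80, width_px=128, height_px=128, density_um2=0.05, snr=8.0)
        video, _ = simulate_video(cfg, seed=6)
        psf = characterize_psf(video, max_events=100, sigma_guess=1.0)
        assert psf.n_fits <= 100
        small = characterize_psf(video, max_events=20, sigma_guess=1.0)
        assert small.n_fits <= 20


class TestPatchStats:
    def test_density_recovered_within_20_percent_at_snr8(self, known_psf):
        ests = []
        for seed in range(8):
            video, _ = context_video(2.0, 8.0, seed=seed)
            gs = global_stats(video, n_frames=30)
            st = patch_stats(video.frames[:, :, :64], gs, known_psf, 233.0, n_frames=30)
            ests.append(st.density_um2)
        assert np.mean(ests) == pytest.approx(2.0, rel=0.20)

    def test_empty_patch_has_zero_density_and_snr(self, known_psf, rng):
        frames = np.clip(rng.normal(120, 10.95, (20, 64, 64)), 0, None)
        gs = GlobalFrameStats(image_mean=120.0, image_std=10.95)
        st = patch_stats(frames, gs, known_psf, 233.0)
        assert st.density_um2 < 0.05
        assert st.snr < 1.0

    def test_density_monotone_in_true_density_at_snr8(self, known_psf):
        means = []
        for rho in (0.5, 1.0, 1.5, 2.0):
            ests = []
            for seed in range(6):
                video, _ = context_video(rho, 8.0, n_frames=20, seed=10 + seed)
                gs = global_stats(video, n_frames=20)
                ests.append(patch_stats(video.frames[:, :, :64], gs, known_psf, 233.0, n_frames=20).density_um2)
            means.append(np.mean(ests))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_snr_monotone_in_true_snr_at_low_density(self, known_psf):
        means = []
        for snr in (2.0, 4.0, 6.0, 8.0):
            ests = []
            for seed in range(6):
                video, _ = context_video(0.5, snr, n_frames=20, seed=20 + seed)
                gs = global_stats(video, n_frames=20)
                ests.append(patch_stats(video.frames[:, :, :64], gs, known_psf, 233.0, n_frames=20).snr)
            means.append(np.mean(ests))
        assert all(a < b for a, b in zip(means, means[1:]))
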