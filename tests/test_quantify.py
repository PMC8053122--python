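"""Image quantification: detection, selection, intensities, rim thickness."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, shift as nd_shift, rotate as nd_rotate
from scipy.special import ndtr

from dropletkd.quantify import (
    DropletImage,
    DropletROI,
    QuantifyError,
    detect_droplets,
    estimate_epsilon,
    inner_intensity,
    peripheral_intensity,
    quantify_image,
    radial_profile,
    select_droplets,
)

PX = 0.5  # um per pixel used by the constructed fixtures


def disk_image(shape=(201, 201), center=(100, 100), r_px=45.0,
               interior=100.0, ring=None, ring_width_px=None, bg=0.0):
    """A synthetic droplet: uniform disk, optional rim annulus."""
    yy, xx = np.indices(shape)
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    img = np.full(shape, bg, float)
    img[d2 <= r_px ** 2] = interior
    if ring is not None:
        inner = r_px - ring_width_px
        mask = (d2 <= r_px ** 2) & (d2 > inner ** 2)
        img[mask] = ring
    return DropletImage(pixels=img, pixel_size=PX)


def roi_for(center=(100, 100), r_px=45.0, touching=False):
    return DropletROI(center=center, r0=r_px * PX, touching=touching)


class TestDetect:
    def test_single_disk_radius_within_one_pixel(self):
        img = disk_image()
        rois = detect_droplets(img)
        assert len(rois) == 1
        assert rois[0].r0 == pytest.approx(22.5, abs=PX)
        assert rois[0].center[0] == pytest.approx(100, abs=1)
        assert rois[0].center[1] == pytest.approx(100, abs=1)

    def test_tangent_disks_flagged_touching(self):
        shape = (200, 320)
        img = np.zeros(shape)
        yy, xx = np.indices(shape)
        for cx, cy, r in ((60, 100, 30), (120, 100, 30), (250, 100, 30)):
            img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2] = 100.0
        rois = detect_droplets(DropletImage(pixels=img, pixel_size=PX))
        assert len(rois) == 3
        assert sorted(r.touching for r in rois) == [False, True, True]

    def test_blank_image_yields_empty_list(self):
        img = DropletImage(pixels=np.zeros((64, 64)), pixel_size=PX)
        assert detect_droplets(img) == []

    def test_ring_only_threshold_recovers_full_disk(self):
        # Bright rim with dim interior: the fitted circle must span the
        # droplet, not just the annulus.
        img = disk_image(interior=20.0, ring=300.0, ring_width_px=6)
        rois = detect_droplets(img)
        assert len(rois) == 1
        assert rois[0].r0 == pytest.approx(22.5, abs=PX)


class TestSelect:
    def test_size_window_and_touching_filter(self):
        rois = [roi_for(r_px=30), roi_for(r_px=45), roi_for(r_px=48),
                roi_for(r_px=45, touching=True)]
        kept = select_droplets(rois, d_min=40, d_max=50)
        assert sorted(2 * r.r0 for r in kept) == [45.0, 48.0]

    def test_empty_input(self):
        assert select_droplets([]) == []

    def test_all_touching_rejected(self):
        rois = [roi_for(r_px=45, touching=True) for _ in range(3)]
        assert select_droplets(rois) == []


class TestInnerIntensity:
    def test_uniform_disk(self):
        img = disk_image(interior=100.0)
        mean, sd = inner_intensity(img, roi_for())
        assert mean == pytest.approx(100.0)
        assert sd == 0.0

    def test_rim_excluded_from_inner_disk(self):
        img = disk_image(interior=100.0, ring=300.0, ring_width_px=4)
        mean, _ = inner_intensity(img, roi_for())
        assert mean == pytest.approx(100.0)

    def test_noisy_disk_within_standard_error(self, rng):
        img = disk_image(interior=100.0)
        noisy = DropletImage(
            pixels=img.pixels + rng.normal(0, 10, img.pixels.shape),
            pixel_size=PX)
        mean, sd = inner_intensity(noisy, roi_for())
        n = np.pi * (0.5 * 45) ** 2
        assert mean == pytest.approx(100.0, abs=3 * 10 / np.sqrt(n))
        assert sd == pytest.approx(10.0, rel=0.15)

    def test_degenerate_roi_raises(self):
        img = disk_image()
        tiny = DropletROI(center=(100, 100), r0=1.0 * PX)
        with pytest.raises(QuantifyError):
            inner_intensity(img, tiny)


class TestPeripheralIntensity:
    def test_noiseless_ring_peak(self):
        img = disk_image(interior=100.0, ring=300.0, ring_width_px=5)
        mean, sd = peripheral_intensity(img, roi_for())
        assert mean == pytest.approx(300.0, rel=1e-3)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_uniform_image_returns_uniform_value(self):
        img = DropletImage(pixels=np.full((201, 201), 42.0), pixel_size=PX)
        mean, _ = peripheral_intensity(img, roi_for())
        assert mean == pytest.approx(42.0)

    def test_blurred_ring_matches_1d_convolution_oracle(self):
        """Per-line maximum equals the peak of the 1-D blurred profile."""
        width_px, sigma_px = 6, 2.0
        img = disk_image(interior=100.0, ring=300.0, ring_width_px=width_px)
        blurred = DropletImage(pixels=gaussian_filter(img.pixels, sigma_px),
                               pixel_size=PX)
        mean, _ = peripheral_intensity(blurred, roi_for())
        # 1-D oracle: step profile along a radius convolved with the Gaussian
        t = np.linspace(0, 90, 9001)
        prof = np.where(t <= 45, np.where(t > 45 - width_px, 300.0, 100.0), 0.0)
        dt = t[1] - t[0]
        kernel_x = np.arange(-8 * sigma_px, 8 * sigma_px + dt, dt)
        kernel = np.exp(-0.5 * (kernel_x / sigma_px) ** 2)
        kernel /= kernel.sum()
        oracle_peak = np.convolve(prof, kernel, mode="same").max()
        assert mean == pytest.approx(oracle_peak, rel=0.01)

    def test_rotation_and_translation_invariance(self):
        img = disk_image(interior=100.0, ring=300.0, ring_width_px=6)
        smooth = gaussian_filter(img.pixels, 1.0)
        base, _ = peripheral_intensity(
            DropletImage(pixels=smooth, pixel_size=PX), roi_for())
        rot = nd_rotate(smooth, 36.0, reshape=False, order=3)
        m_rot, _ = peripheral_intensity(
            DropletImage(pixels=rot, pixel_size=PX), roi_for())
        assert m_rot == pytest.approx(base, rel=0.005)
        sh = nd_shift(smooth, (3, -2), order=0)
        m_sh, _ = peripheral_intensity(
            DropletImage(pixels=sh, pixel_size=PX), roi_for((98, 103)))
        assert m_sh == pytest.approx(base, rel=0.005)

    def test_too_close_to_border_raises(self):
        img = disk_image(shape=(100, 100), center=(50, 50), r_px=45.0)
        with pytest.raises(QuantifyError, match="lines"):
            peripheral_intensity(img, DropletROI(center=(50, 50), r0=45 * PX))


class TestEstimateEpsilon:
    def test_tophat_ring_no_blur(self):
        width_px = 4  # 2 um at 0.5 um/px
        img = disk_image(interior=100.0, ring=300.0, ring_width_px=width_px)
        eps = estimate_epsilon(img, roi_for(), method="fwhm")
        assert eps == pytest.approx(2.0, abs=PX)

    def test_thin_ring_fwhm_matches_convolution_oracle(self):
        """A thin blurred ring's FWHM approaches 2.355 * sigma_effective."""
        sigma_um = 0.8
        sigma_px = sigma_um / PX
        width_px = 1
        img = disk_image(interior=50.0, ring=1000.0, ring_width_px=width_px)
        blurred = DropletImage(pixels=gaussian_filter(img.pixels, sigma_px),
                               pixel_size=PX)
        eps = estimate_epsilon(blurred, roi_for(), method="fwhm")
        # 1-D oracle: convolve the radial top-hat and measure its FWHM,
        # including the droplet-edge contribution the estimator sees.
        t = np.arange(0, 60, 0.01)
        prof = np.where(t <= 45, np.where(t > 45 - width_px, 1000.0, 50.0), 0.0)
        kernel_x = np.arange(-8 * sigma_px, 8 * sigma_px + 0.01, 0.01)
        kernel = np.exp(-0.5 * (kernel_x / sigma_px) ** 2)
        kernel /= kernel.sum()
        conv = np.convolve(prof, kernel, mode="same") - 50.0
        pk = conv.argmax()
        half = 0.5 * conv[pk]
        above = np.nonzero(conv >= half)[0]
        oracle_fwhm = (t[above[-1]] - t[above[0]]) * PX
        assert eps == pytest.approx(oracle_fwhm, rel=0.05)
        # and the oracle itself is near the Gaussian limit
        assert oracle_fwhm == pytest.approx(2.355 * sigma_um, rel=0.15)

    def test_profile_fit_deconvolves_ring_width(self):
        width_px, sigma_px = 6, 1.0
        img = disk_image(interior=100.0, ring=300.0, ring_width_px=width_px)
        blurred = DropletImage(pixels=gaussian_filter(img.pixels, sigma_px),
                               pixel_size=PX)
        eps = estimate_epsilon(blurred, roi_for(), method="profile_fit")
        assert eps == pytest.approx(width_px * PX, rel=0.1)

    def test_flat_image_raises_with_guidance(self):
        img = DropletImage(pixels=np.full((201, 201), 7.0), pixel_size=PX)
        with pytest.raises(QuantifyError, match="supply eps"):
            estimate_epsilon(img, roi_for())


class TestPipelineProperties:
    def test_noiseless_measured_ratio_matches_forward_model(self):
        """Before PSF blur, measured I_peri/I_in equals the generator's
        equilibrium ratio to within 1%."""
        from dropletkd.synth import SyntheticGroundTruth, make_droplet_image

        gt = SyntheticGroundTruth(kd_um=0.5, noise_model="none",
                                  psf_sigma_um=0.0, seed=3)
        img, truth = make_droplet_image(gt, n_droplets=4)
        rois = detect_droplets(img)
        assert len(rois) == 4
        for roi in rois:
            row = truth.iloc[
                ((truth.cx - roi.center[0]) ** 2
                 + (truth.cy - roi.center[1]) ** 2).idxmin()]
            I_in, _ = inner_intensity(img, roi)
            I_peri, _ = peripheral_intensity(img, roi)
            assert I_peri / I_in == pytest.approx(row.ratio, rel=0.01)

    def test_quantify_image_table_schema(self):
        from dropletkd.synth import SyntheticGroundTruth, make_droplet_image

        gt = SyntheticGroundTruth(kd_um=0.5, seed=9)
        img, _ = make_droplet_image(gt, n_droplets=4)
        table = quantify_image(img)
        assert list(table.columns) == [
            "droplet_id", "cx", "cy", "r0_um", "I_in", "I_peri",
            "sd_in", "sd_peri", "eps_um", "selected"]
        assert len(table) == 4
        assert table.selected.all()
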