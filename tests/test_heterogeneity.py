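"""Nucleus segmentation, COV statistic, masks, volume, size-density."""

import numpy as np
import pandas as pd
import pytest

from nucphase.config import SimConfig
from nucphase.sim import gen_chromatin_field, two_level_field
from nucphase.heterogeneity import (
    compute_cov,
    estimate_background,
    interior_periphery,
    mid_plane,
    nuclear_volume,
    segment_nucleus,
    size_density_correlation,
)

PX = 0.133


def _disk_image(radius_um, n=256, lo=100.0, hi=1000.0):
    yy, xx = np.mgrid[0:n, 0:n]
    r_px = radius_um / PX
    img = np.full((n, n), lo)
    img[((yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= r_px**2] = hi
    return img


class TestSegmentation:
    def test_bright_disk_one_mask(self):
        img = _disk_image(radius_um=4.0)  # ~50 um^2
        masks = segment_nucleus(img, PX)
        assert len(masks) == 1
        assert abs(masks[0].area_um2 - np.pi * 16) / (np.pi * 16) < 0.1

    def test_small_disk_filtered_by_min_size(self):
        img = _disk_image(radius_um=1.26)  # ~5 um^2 < 10 um^2 cutoff
        assert segment_nucleus(img, PX) == []

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            assert segment_nucleus(np.full((64, 64), 5.0), PX) == []

    def test_segments_synthetic_nucleus(self):
        cfg = SimConfig(seed=3)
        gt = gen_chromatin_field(0.3, (10.0, 14.0), cfg)
        masks = segment_nucleus(gt.intensity_field, cfg.pixel_size)
        assert len(masks) == 1
        overlap = (masks[0].mask & gt.nucleus_mask).sum() / gt.nucleus_mask.sum()
        assert overlap > 0.9


class TestBackground:
    def test_constant_outside_masks(self):
        img = _disk_image(4.0)
        region = img == 100.0
        assert estimate_background(img, region) == 100.0

    def test_poisson_background_median(self, rng):
        img = rng.poisson(100, (128, 128)).astype(float)
        region = np.ones_like(img, dtype=bool)
        assert abs(estimate_background(img, region) - 100) <= 1

    def test_region_overlapping_mask_rejected(self):
        img = _disk_image(4.0)
        masks = segment_nucleus(img, PX)
        region = np.ones_like(img, dtype=bool)
        with pytest.raises(ValueError, match="overlaps"):
            estimate_background(img, region, masks)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background(np.ones((8, 8)), np.zeros((8, 8), bool))


class TestCov:
    def test_uniform_zero(self):
        img = np.full((32, 32), 500.0)
        res = compute_cov(img, np.ones_like(img, bool), 100.0)
        assert res.cov == 0.0

    def test_two_level_exact_one(self):
        img, mask = two_level_field()
        assert np.isclose(compute_cov(img, mask, 0.0).cov, 1.0)

    def test_mean_below_background_rejected(self):
        img = np.full((16, 16), 50.0)
        with pytest.raises(ValueError, match="background"):
            compute_cov(img, np.ones_like(img, bool), 100.0)

    def test_gain_invariance(self, rng):
        """Multiplying intensities and background by a constant leaves COV
        unchanged; shifting intensities without co-shifting background does
        not."""
        img = rng.uniform(200, 800, (64, 64))
        mask = np.ones_like(img, bool)
        base = compute_cov(img, mask, 100.0).cov
        scaled = compute_cov(3.7 * img, mask, 370.0).cov
        assert np.isclose(base, scaled)
        shifted = compute_cov(img + 500.0, mask, 100.0).cov
        assert not np.isclose(base, shifted)

    def test_2d_equals_3d_on_z_uniform_stack(self, rng):
        plane = rng.uniform(200, 900, (64, 64))
        stack = np.stack([plane] * 5)
        mask2d = plane > 0
        mask3d = stack > 0
        c2 = compute_cov(plane, mask2d, 50.0, "2d").cov
        c3 = compute_cov(stack, mask3d, 50.0, "3d").cov
        assert np.isclose(c2, c3)

    def test_recomputable_from_stored_fields(self, rng):
        img = rng.uniform(300, 700, (32, 32))
        mask = np.ones_like(img, bool)
        res = compute_cov(img, mask, 120.0)
        assert np.isclose(
            res.cov, res.std_intensity / (res.mean_intensity - res.background)
        )


class TestInteriorPeriphery:
    def _disk_mask(self, radius=20, n=64):
        yy, xx = np.mgrid[0:n, 0:n]
        return ((yy - n / 2) ** 2 + (xx - n / 2) ** 2) <= radius**2

    def test_partition_identities_exact(self):
        mask = self._disk_mask()
        interior, periphery = interior_periphery(mask, 3)
        assert np.array_equal(interior | periphery, mask)
        assert not (interior & periphery).any()

    def test_disk_periphery_area_fraction(self):
        """Disk radius 20 px eroded by 3 px: periphery fraction
        1 - (17/20)^2 = 0.2775 up to discretization."""
        mask = self._disk_mask(radius=20)
        interior, periphery = interior_periphery(mask, 3)
        frac = periphery.sum() / mask.sum()
        assert abs(frac - 0.2775) < 0.03

    def test_erosion_annihilating_mask_rejected(self):
        mask = self._disk_mask(radius=2)
        with pytest.raises(ValueError, match="annihilates"):
            interior_periphery(mask, 5)


class TestVolume:
    def _sphere_masks(self, radius_um=5.0, px=0.13, z_step=0.3):
        z = np.arange(-radius_um, radius_um + z_step, z_step)
        n = int(2.2 * radius_um / px)
        yy, xx = np.mgrid[0:n, 0:n]
        cy = cx = n / 2
        slices = []
        for zz in z:
            r2 = radius_um**2 - zz**2
            if r2 <= 0:
                slices.append(np.zeros((n, n), bool))
            else:
                slices.append(
                    ((yy - cy) ** 2 + (xx - cx) ** 2) * px**2 <= r2
                )
        return np.stack(slices)

    def test_sphere_volume_within_three_percent(self):
        masks = self._sphere_masks()
        res = nuclear_volume(masks, 0.13, 0.3)
        expected = 4 / 3 * np.pi * 125
        assert abs(res.volume_um3 - expected) / expected < 0.03

    def test_volume_linear_in_z_step(self):
        masks = self._sphere_masks()
        v1 = nuclear_volume(masks, 0.13, 0.3).volume_um3
        v2 = nuclear_volume(masks, 0.13, 0.6).volume_um3
        assert np.isclose(v2, 2 * v1)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            nuclear_volume(np.ones((1, 8, 8), bool), 0.13)

    def test_mid_plane_is_largest_slice(self):
        masks = self._sphere_masks()
        assert mid_plane(masks) == masks.reshape(len(masks), -1).sum(1).argmax()


class TestSizeDensityCorrelation:
    def _setup(self, rng, anticorrelated=True):
        n = 128
        img = rng.uniform(200, 1000, (n, n))
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, 4)
        mask = np.ones((n, n), bool)
        rows = []
        pos = rng.uniform(20, 100, (20, 2))
        for i, (r, c) in enumerate(pos):
            density = img[int(r), int(c)]
            size = (
                (1500 - density) / 500 + rng.normal(0, 0.05)
                if anticorrelated
                else 1.0
            )
            rows.append(
                {
                    "x_um": (c + 0.5) * PX,
                    "y_um": (r + 0.5) * PX,
                    "equivalent_diameter_um": max(size, 0.1),
                }
            )
        return pd.DataFrame(rows), img, mask

    def test_anticorrelated_construction_negative_r(self, rng):
        droplets, img, mask = self._setup(rng)
        res = size_density_correlation(droplets, img, mask, PX)
        assert res["r"] < 0 and not res["degenerate"]
        # matches the textbook formula on the same pairs
        from scipy import stats

        sizes = droplets["equivalent_diameter_um"].to_numpy()
        assert res["p"] <= 1.0

    def test_constant_sizes_degenerate(self, rng):
        droplets, img, mask = self._setup(rng, anticorrelated=False)
        res = size_density_correlation(droplets, img, mask, PX)
        assert res["degenerate"]

    def test_too_few_droplets_rejected(self, rng):
        droplets, img, mask = self._setup(rng)
        with pytest.raises(ValueError):
            size_density_correlation(droplets.head(3), img, mask, PX)
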