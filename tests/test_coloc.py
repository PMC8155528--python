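"""Colocalization, rotation control, spot correlation, radial quartiles, IQR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import star_mask
from oracles import brute_quartiles_linear, brute_radial_bins
from synq.coloc import (
    iqr_filter,
    normalized_radius_map,
    pearson_coloc,
    radial_quartile_profile,
    rotation_control,
    spot_channel_correlation,
)
from synq.synthetic import disk_mask, make_cell_scene

PX = 0.1


def _grid(shape):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx + 0.5) * PX, (yy + 0.5) * PX


class TestPearson:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.mask = disk_mask((100, 100), (5.0, 5.0), 4.0, PX)
        self.a = rng.uniform(0, 10, (100, 100))

    def test_identical_channels_score_one(self):
        assert pearson_coloc(self.a, self.a, self.mask).r == pytest.approx(1.0)

    def test_inverted_channel_scores_minus_one(self):
        assert pearson_coloc(self.a, 12.0 - self.a, self.mask).r == pytest.approx(-1.0)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        mask = np.ones((120, 120), bool)  # 1.44e4 pixels
        a = rng.uniform(0, 1, mask.shape)
        b = rng.uniform(0, 1, mask.shape)
        assert abs(pearson_coloc(a, b, mask).r) < 0.05

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(0, 5, self.a.shape)
        r0 = pearson_coloc(self.a, b, self.mask).r
        r1 = pearson_coloc(3.0 * self.a + 7.0, 0.5 * b + 1.0, self.mask).r
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_coloc(self.a, np.ones_like(self.a), self.mask)

    def test_tiny_mask_rejected(self):
        tiny = np.zeros((100, 100), bool)
        tiny[0, :5] = True
        with pytest.raises(ValueError, match="10"):
            pearson_coloc(self.a, self.a, tiny)


class TestRotationControl:
    def test_radially_symmetric_partner_unchanged(self):
        mask = disk_mask((128, 128), (6.4, 6.4), 4.0, PX)
        x, y = _grid((128, 128))
        r2 = (x - 6.4) ** 2 + (y - 6.4) ** 2
        ch_b = np.exp(-r2 / 4.0)
        rng = np.random.default_rng(3)
        ch_a = ch_b + rng.normal(0, 0.05, ch_b.shape) ** 2
        res = rotation_control(ch_a, ch_b, mask)
        assert res.r_rotated == pytest.approx(res.r, abs=0.02)

    def test_off_axis_colocalized_spots_decorrelate(self):
        mask = disk_mask((128, 128), (6.4, 6.4), 5.0, PX)
        x, y = _grid((128, 128))
        spot = np.exp(-((x - 8.5) ** 2 + (y - 6.4) ** 2) / (2 * 0.4**2))
        ch_a = spot + 0.01
        ch_b = spot * 2.0 + 0.02
        res = rotation_control(ch_a, ch_b, mask)
        assert res.r > 0.99
        assert res.r_rotated < res.r - 0.3

    def test_full_turn_restores_r(self):
        rng = np.random.default_rng(4)
        mask = disk_mask((128, 128), (6.4, 6.4), 4.0, PX)
        ch_a = rng.uniform(0, 5, (128, 128))
        ch_b = rng.uniform(0, 5, (128, 128))
        base = pearson_coloc(ch_a, ch_b, mask).r
        res = rotation_control(ch_a, ch_b, mask, angle_deg=360.0)
        assert res.r_rotated == pytest.approx(base, abs=1e-6)


class TestSpotChannelCorrelation:
    def _movie(self, partner_from_spot, n_spots=30, seed=5):
        rng = np.random.default_rng(seed)
        positions = [tuple(p) for p in rng.uniform(5, 23, (n_spots, 2))]
        amps = rng.uniform(40, 160, n_spots)
        shape = (288, 288)
        x, y = _grid(shape)
        spot_ch = np.full(shape, 1.0)
        for (sx, sy), a in zip(positions, amps):
            spot_ch += a * np.exp(-((x - sx) ** 2 + (y - sy) ** 2) / (2 * 0.25**2))
        partner = partner_from_spot(spot_ch)
        from synq.io import ImageStack

        movie = ImageStack.from_array(
            np.stack([spot_ch, partner]), "CYX", pixel_size_um=PX
        )
        mask = np.ones(shape, bool)
        return movie, [mask]

    def test_uniform_partner_has_flat_groups_and_no_rank_correlation(self):
        movie, masks = self._movie(lambda s: np.full_like(s, 3.0) + 0.0)
        per_spot, grouped, rho = spot_channel_correlation(
            movie, 0, 1, masks, quality_threshold=2.0
        )
        assert len(per_spot) >= 20
        assert grouped["partner_mean"].max() == pytest.approx(
            grouped["partner_mean"].min(), rel=1e-6
        )

    def test_anticorrelated_partner_gives_decreasing_groups(self):
        movie, masks = self._movie(lambda s: s.max() * 1.1 - s)
        per_spot, grouped, rho = spot_channel_correlation(
            movie, 0, 1, masks, quality_threshold=2.0
        )
        assert rho < -0.5
        means = grouped.sort_values("group")["partner_mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_frame_gain_cancels_in_normalization(self):
        movie, masks = self._movie(lambda s: 0.5 * s + 1.0)
        doubled = movie.with_pixels(movie.pixels * 2.0)
        a = spot_channel_correlation(movie, 0, 1, masks, quality_threshold=2.0)
        b = spot_channel_correlation(doubled, 0, 1, masks, quality_threshold=2.0)
        np.testing.assert_allclose(
            a[0][["spot_norm", "partner_norm"]].to_numpy(),
            b[0][["spot_norm", "partner_norm"]].to_numpy(),
            rtol=1e-9,
        )

    def test_recovers_planted_monotone_relationship(self):
        # sign of the rank correlation recovered across seeded replicates
        hits = 0
        for seed in range(10):
            movie, masks = self._movie(lambda s: 2.0 * s + 5.0, seed=seed)
            _, _, rho = spot_channel_correlation(movie, 0, 1, masks, quality_threshold=2.0)
            hits += rho > 0
        assert hits >= 10 * 0.95


class TestRadialQuartiles:
    def test_uniform_disk_has_equal_quartile_mfis(self):
        mask = disk_mask((128, 128), (6.4, 6.4), 5.0, PX)
        prof = radial_quartile_profile(np.full(mask.shape, 7.0), mask)
        np.testing.assert_allclose(prof.quartile_mfi, 7.0, rtol=1e-9)

    def test_central_gaussian_peaks_in_first_quartile(self):
        mask = disk_mask((128, 128), (6.4, 6.4), 5.0, PX)
        x, y = _grid((128, 128))
        ch = np.exp(-((x - 6.4) ** 2 + (y - 6.4) ** 2) / (2 * 0.8**2))
        prof = radial_quartile_profile(ch, mask)
        assert prof.quartile_mfi[0] > prof.quartile_mfi[1:].max()

    def test_peripheral_ring_peaks_in_fourth_quartile(self):
        mask = disk_mask((128, 128), (6.4, 6.4), 5.0, PX)
        x, y = _grid((128, 128))
        r = np.hypot(x - 6.4, y - 6.4)
        ch = np.where((r > 4.4) & (r <= 5.0), 10.0, 0.1)
        prof = radial_quartile_profile(ch, mask)
        assert prof.quartile_mfi[3] > prof.quartile_mfi[:3].max()

    def test_quartiles_partition_all_pixels_and_conserve_intensity(self):
        rng = np.random.default_rng(6)
        mask = star_mask(rng=rng)
        ch = rng.uniform(0, 10, mask.shape)
        prof = radial_quartile_profile(ch, mask)
        assert prof.quartile_counts.sum() == mask.sum()
        total = (prof.quartile_mfi * prof.quartile_counts).sum()
        assert total == pytest.approx(ch[mask].sum(), rel=1e-9)

    def test_ray_cast_oracle_agreement_on_random_star_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            mask = star_mask(shape=(48, 48), r0=16.0, rng=rng)
            rmap, _ = normalized_radius_map(mask)
            bins_oracle, rnorm_oracle = brute_radial_bins(mask)
            rows, cols = np.nonzero(mask)
            mismatches = 0
            for r, c in zip(rows, cols):
                rn = rmap[r, c]
                if abs(rn * 4 - round(rn * 4)) < 1e-9:
                    continue  # exactly on a quartile edge: either bin is valid
                if min(int(rn * 4), 3) != bins_oracle[(r, c)]:
                    mismatches += 1
            assert mismatches == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            radial_quartile_profile(np.zeros((10, 10)), np.zeros((10, 10), bool))


class TestIqrFilter:
    def test_textbook_example(self):
        kept, rejected = iqr_filter([1, 2, 3, 4, 100])
        # Q1 = 2, Q3 = 4 by linear interpolation, upper fence 7
        assert list(rejected) == [100]
        assert sorted(kept) == [1, 2, 3, 4]
        q1, q3 = brute_quartiles_linear([1, 2, 3, 4, 100])
        assert (q1, q3) == (2.0, 4.0)

    def test_all_equal_values_keep_everything(self):
        kept, rejected = iqr_filter([5.0] * 6)
        assert len(kept) == 6 and len(rejected) == 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=60))
    def test_partition_property(self, values):
        kept, rejected = iqr_filter(values)
        assert len(kept) + len(rejected) == len(values)
        assert sorted(np.concatenate([kept, rejected])) == sorted(values)
        q1, q3 = brute_quartiles_linear(values)
        iqr = q3 - q1
        assert np.all(kept >= q1 - 1.5 * iqr) and np.all(kept <= q3 + 1.5 * iqr)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1.0, 2.0, 3.0])
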