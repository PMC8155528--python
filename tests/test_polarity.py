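"""Positional index extremes, invariances and closed-form checks."""

import numpy as np
import pytest

from synq.io import ImageStack
from synq.polarity import (
    antigen_extraction,
    bead_recruitment,
    center_recruitment,
    centrosome_density_index,
    centrosome_nucleus_distance,
    polarity_index,
    z_profile,
)
from synq.segment import CellGeometry, bead_region, fit_center_ellipse
from synq.synthetic import disk_mask, make_cell_scene

PX = 0.1


@pytest.fixture(scope="module")
def geometry():
    _, truth = make_cell_scene({"c": {"kind": "uniform"}})
    return CellGeometry(
        cell_mask=truth.cell_mask, bead_mask=truth.bead_mask,
        centrosome_xy=None, pixel_size_um=PX,
    ), truth


class TestPolarityIndex:
    @pytest.mark.parametrize(
        "where,expected",
        [("bmc", 1.0), ("cmc", 0.0), ("mirror", -1.0), ("midpoint", 0.5)],
    )
    def test_landmark_positions_give_exact_indices(self, geometry, where, expected):
        geo, _ = geometry
        cmc, bmc = np.array(geo.cmc_xy), np.array(geo.bmc_xy)
        pos = {
            "bmc": bmc,
            "cmc": cmc,
            "mirror": cmc - (bmc - cmc),
            "midpoint": (cmc + bmc) / 2,
        }[where]
        geo.centrosome_xy = tuple(pos)
        assert polarity_index(geo).index == pytest.approx(expected, abs=1e-12)

    def test_off_axis_centrosome_projects_orthogonally(self, geometry):
        geo, _ = geometry
        cmc, bmc = np.array(geo.cmc_xy), np.array(geo.bmc_xy)
        axis = bmc - cmc
        normal = np.array([-axis[1], axis[0]]) / np.hypot(*axis)
        # displacing the centrosome perpendicular to the axis must not change the index
        geo.centrosome_xy = tuple(cmc + 0.4 * axis + 2.0 * normal)
        res = polarity_index(geo)
        assert res.index == pytest.approx(0.4, abs=1e-12)
        proj = np.array(res.cent_proj_xy)
        assert np.dot(proj - cmc, normal) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        # rotating the whole geometry by 90 deg must leave the index unchanged
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        cent = (20.0, 15.0)
        geo = CellGeometry(
            cell_mask=truth.cell_mask, bead_mask=truth.bead_mask,
            centrosome_xy=cent, pixel_size_um=PX,
        )
        h = truth.cell_mask.shape[0] * PX
        rot_cell = np.rot90(truth.cell_mask, k=-1)  # (x,y) -> (h-y, x)
        rot_bead = np.rot90(truth.bead_mask, k=-1)
        rot_cent = (h - cent[1], cent[0])
        geo_rot = CellGeometry(
            cell_mask=rot_cell, bead_mask=rot_bead,
            centrosome_xy=rot_cent, pixel_size_um=PX,
        )
        assert polarity_index(geo_rot).index == pytest.approx(
            polarity_index(geo).index, abs=1e-12
        )

    def test_out_of_range_flagged_not_clamped(self, geometry):
        geo, _ = geometry
        cmc, bmc = np.array(geo.cmc_xy), np.array(geo.bmc_xy)
        geo.centrosome_xy = tuple(cmc + 1.2 * (bmc - cmc))
        res = polarity_index(geo)
        assert res.index == pytest.approx(1.2, abs=1e-12)
        assert res.out_of_range

    def test_zero_axis_is_an_error(self):
        mask = disk_mask((64, 64), (3.0, 3.0), 2.0, PX)
        geo = CellGeometry(
            cell_mask=mask, bead_mask=mask, centrosome_xy=(3.0, 3.0), pixel_size_um=PX
        )
        with pytest.raises(ValueError, match="zero-length"):
            polarity_index(geo)


class TestBeadRecruitment:
    def test_all_fluorescence_at_bead_scores_100(self):
        _, truth = make_cell_scene({"ag": {"kind": "bead", "intensity": 80.0}})
        region = bead_region(truth.bead_mask, PX)
        assert bead_recruitment(truth.clean_channels["ag"], region, truth.cell_mask) == 100.0

    def test_no_fluorescence_at_bead_scores_0(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform", "intensity": 50.0}})
        region = bead_region(truth.bead_mask, PX)
        # uniform cytosol only: zero intensity in the bead region (bead is outside cell)
        ch = truth.clean_channels["c"].copy()
        ch[region] = 0.0
        assert bead_recruitment(ch, region, truth.cell_mask) == 0.0

    def test_uniform_intensity_is_proportional_to_region_share(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        region = bead_region(truth.bead_mask, PX)
        union = truth.cell_mask | region
        ch = np.where(union, 3.0, 0.0)
        expected = 100.0 * region.sum() / union.sum()
        assert bead_recruitment(ch, region, truth.cell_mask) == pytest.approx(expected)

    def test_bounds_on_random_scenes(self):
        rng = np.random.default_rng(0)
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        region = bead_region(truth.bead_mask, PX)
        for _ in range(10):
            ch = rng.uniform(0, 10, truth.cell_mask.shape)
            assert 0.0 <= bead_recruitment(ch, region, truth.cell_mask) <= 100.0

    def test_zero_total_is_an_error(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        region = bead_region(truth.bead_mask, PX)
        with pytest.raises(ValueError, match="zero total"):
            bead_recruitment(np.zeros_like(truth.clean_channels["c"]), region, truth.cell_mask)


class TestCentrosomeDensityIndex:
    def test_uniform_scene_scores_one(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform", "intensity": 42.0}})
        res = centrosome_density_index(
            truth.clean_channels["c"], truth.centrosome_xy, truth.cell_mask, PX
        )
        assert res.value == pytest.approx(1.0, abs=0.02)

    def test_all_fluorescence_in_circle(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        from synq.polarity import circle_mask

        circ = circle_mask(truth.cell_mask.shape, truth.centrosome_xy, 1.0, PX)
        ch = np.where(circ, 5.0, 0.0)
        res = centrosome_density_index(ch, truth.centrosome_xy, truth.cell_mask, PX)
        a_cell = truth.cell_mask.sum() * PX**2
        assert res.value == pytest.approx(a_cell / res.a_cent_um2, rel=1e-9)

    def test_zero_in_circle_scores_zero(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        from synq.polarity import circle_mask

        circ = circle_mask(truth.cell_mask.shape, truth.centrosome_xy, 1.0, PX)
        ch = np.where(truth.cell_mask & ~circ, 5.0, 0.0)
        res = centrosome_density_index(ch, truth.centrosome_xy, truth.cell_mask, PX)
        assert res.value == 0.0

    def test_center_outside_cell_rejected(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        with pytest.raises(ValueError, match="outside"):
            centrosome_density_index(
                truth.clean_channels["c"], (0.5, 0.5), truth.cell_mask, PX
            )


class TestCenterRecruitment:
    def test_uniform_scores_zero(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform", "intensity": 9.0}})
        assert center_recruitment(
            truth.clean_channels["c"], truth.cell_mask, PX
        ) == pytest.approx(0.0, abs=0.02)

    def test_all_center_scores_two(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        center = fit_center_ellipse(truth.cell_mask, PX)
        ch = np.where(center, 4.0, 0.0)
        assert center_recruitment(
            ch, truth.cell_mask, PX, center_mask=center
        ) == pytest.approx(2.0, abs=0.05)

    def test_all_periphery_scores_minus_one_exactly(self):
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        center = fit_center_ellipse(truth.cell_mask, PX)
        ch = np.where(truth.cell_mask & ~center, 4.0, 0.0)
        assert center_recruitment(ch, truth.cell_mask, PX, center_mask=center) == -1.0

    def test_lower_bound(self):
        rng = np.random.default_rng(1)
        _, truth = make_cell_scene({"c": {"kind": "uniform"}})
        for _ in range(5):
            ch = rng.uniform(0, 10, truth.cell_mask.shape)
            assert center_recruitment(ch, truth.cell_mask, PX) >= -1.0


class TestZProfile:
    def _stack_with_spot_at(self, z_center, n_z=10, sigma_z=0.7):
        z = np.arange(n_z)
        profile = np.exp(-((z - z_center) ** 2) / (2 * sigma_z**2))
        planes = np.stack([np.full((32, 32), p) for p in profile])
        return ImageStack.from_array(
            planes, "ZYX", pixel_size_um=PX, z_step_um=0.5
        )

    def test_coverslip_spot_is_synaptic(self):
        st = self._stack_with_spot_at(0.0)
        mask = np.ones((32, 32), bool)
        prof = z_profile(st, 0, mask, n_fractions=10, z_top=9)
        assert prof.peak_fraction == 1
        assert prof.synaptic

    def test_mid_height_spot_peaks_in_the_middle(self):
        st = self._stack_with_spot_at(4.5)
        prof = z_profile(st, 0, np.ones((32, 32), bool), n_fractions=10, z_top=9)
        assert prof.peak_fraction in (5, 6)
        assert not prof.synaptic

    def test_uniform_signal_is_flat(self):
        planes = np.full((10, 16, 16), 3.0)
        st = ImageStack.from_array(planes, "ZYX", pixel_size_um=PX, z_step_um=0.5)
        prof = z_profile(st, 0, np.ones((16, 16), bool), n_fractions=5, z_top=9)
        assert prof.fraction_means.max() / prof.fraction_means.min() <= 1.0 + 1e-9

    def test_empty_mask_is_an_error(self):
        st = self._stack_with_spot_at(0.0)
        with pytest.raises(ValueError, match="empty"):
            z_profile(st, 0, np.zeros((32, 32), bool))


class TestAntigenExtraction:
    @pytest.mark.parametrize("before,after,expected", [(10.0, 10.0, 0.0), (5.0, 0.0, 100.0), (10.0, 4.0, 60.0)])
    def test_arithmetic(self, before, after, expected):
        pct, flagged = antigen_extraction(before, after)
        assert pct == pytest.approx(expected)
        assert not flagged

    def test_gain_floored_and_flagged(self):
        pct, flagged = antigen_extraction(10.0, 12.0)
        assert pct == 0.0 and flagged

    def test_zero_before_rejected(self):
        with pytest.raises(ValueError):
            antigen_extraction(0.0, 1.0)


class TestCentrosomeNucleusDistance:
    def test_inside_and_on_boundary_is_zero(self):
        nuc = disk_mask((128, 128), (6.0, 6.0), 3.0, PX)
        assert centrosome_nucleus_distance((6.0, 6.0), nuc, PX) == 0.0
        assert centrosome_nucleus_distance((8.9, 6.0), nuc, PX) == 0.0

    def test_two_micron_offset(self):
        nuc = disk_mask((160, 160), (8.0, 8.0), 3.0, PX)
        d = centrosome_nucleus_distance((13.0, 8.0), nuc, PX)
        assert d == pytest.approx(2.0, abs=0.15)

    def test_rotation_invariance(self):
        nuc = disk_mask((160, 160), (8.0, 8.0), 3.0, PX)
        d0 = centrosome_nucleus_distance((13.0, 8.0), nuc, PX)
        h = nuc.shape[0] * PX
        nuc_rot = np.rot90(nuc, k=-1)
        d1 = centrosome_nucleus_distance((h - 8.0, 13.0), nuc_rot, PX)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_missing_nucleus(self):
        with pytest.raises(ValueError):
            centrosome_nucleus_distance((1.0, 1.0), np.zeros((8, 8), bool), PX)
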