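"""3D FISH analysis: masking, thresholding, objects, distances, colocalization."""

import math

import numpy as np
import pytest

from sinefactory.imaging import (
    ColocRecord,
    ImageStack,
    NucleusMask,
    colocalize,
    compare_colocalization,
    count_factories,
    detect_objects,
    nearest_positive_distance,
    particle_intensities,
    positive_voxels,
    segment_nucleus,
)
from sinefactory.synthetic import ImageSimSpec, gen_image_stack


def stack_of(arr, voxel=(100.0, 100.0, 200.0), name="rnap", extra=None):
    channels = {name: np.asarray(arr, float)}
    if extra:
        channels.update(extra)
    return ImageStack(channels=channels, voxel_nm=voxel)


def full_mask(shape):
    return NucleusMask(np.ones(shape, dtype=bool))


class TestSegmentNucleus:
    def test_synthetic_ellipsoid_recovered(self, rng):
        spec = ImageSimSpec(shape=(16, 48, 48), n_foci=5, noise_sd=1.0,
                            spot_distances_nm=())
        stack, truth = gen_image_stack(spec, rng)
        mask = segment_nucleus(stack)
        cz, cy, cx = (np.array(truth["nucleus_center_nm"])[::-1])
        # true ellipsoid voxel set
        dz, dy, dx = 200.0, 100.0, 100.0
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in spec.shape), indexing="ij")
        sx, sy, sz = truth["nucleus_semiaxes_nm"]
        inside = (
            (((xx + 0.5) * dx - truth["nucleus_center_nm"][0]) / sx) ** 2
            + (((yy + 0.5) * dy - truth["nucleus_center_nm"][1]) / sy) ** 2
            + (((zz + 0.5) * dz - truth["nucleus_center_nm"][2]) / sz) ** 2
        ) <= 1.0
        assert mask.mask[inside].mean() >= 0.99

    def test_all_zero_stack_rejected(self):
        stack = stack_of(np.zeros((4, 8, 8)), name="dapi")
        with pytest.raises(ValueError, match="no nucleus"):
            segment_nucleus(stack)

    def test_two_nuclei_largest_returned(self):
        img = np.zeros((6, 30, 30))
        img[1:5, 2:12, 2:12] = 100.0  # 10x10 block
        img[2:4, 20:25, 20:25] = 100.0  # smaller block
        mask = segment_nucleus(stack_of(img, name="dapi"), "dapi")
        assert mask.mask[2, 5, 5] and not mask.mask[3, 22, 22]


class TestPositiveVoxels:
    def test_constant_channel_has_no_positives(self):
        stack = stack_of(np.full((2, 2, 2), 7.0))
        with pytest.warns(UserWarning, match="constant"):
            pos = positive_voxels(stack, "rnap", full_mask((2, 2, 2)))
        assert not pos.any()

    def test_mean_plus_sd_cut_worked_example(self):
        # {10,10,10,30}: mean 15, population SD ~8.66, cut 23.66 -> only 30 positive
        arr = np.array([10.0, 10.0, 10.0, 30.0]).reshape(1, 1, 4)
        pos = positive_voxels(stack_of(arr), "rnap", full_mask((1, 1, 4)), k=1.0)
        assert pos.ravel().tolist() == [False, False, False, True]

    def test_positive_set_nonincreasing_in_k(self, rng):
        arr = rng.normal(50, 10, (6, 10, 10))
        stack = stack_of(arr)
        mask = full_mask(arr.shape)
        prev = positive_voxels(stack, "rnap", mask, k=0.0)
        for k in (0.5, 1.0, 2.0, 3.0):
            cur = positive_voxels(stack, "rnap", mask, k=k)
            assert not (cur & ~prev).any()
            prev = cur


class TestDetectObjects:
    def test_empty_stack_no_objects(self):
        stack = stack_of(np.zeros((4, 8, 8)))
        assert detect_objects(stack, "rnap", full_mask((4, 8, 8)), threshold=1.0) == []

    def test_two_separated_spots_with_accurate_centroids(self, rng):
        spec = ImageSimSpec(shape=(16, 48, 48), n_foci=2, noise_sd=0.5,
                            spot_distances_nm=(), min_separation_nm=1500.0)
        stack, truth = gen_image_stack(spec, rng)
        mask = segment_nucleus(stack)
        objs = detect_objects(stack, "rnap", mask, k=3.0)
        assert len(objs) == 2
        found = sorted(o.centroid_nm for o in objs)
        planted = sorted(tuple(f) for f in truth["foci_nm"])
        for got, want in zip(found, planted):
            err = math.dist(got, want)
            assert err <= math.sqrt(100**2 + 100**2 + 200**2)  # within one voxel

    def test_min_volume_filter_drops_small_spot(self):
        img = np.zeros((5, 10, 10))
        img[2, 2, 2] = 100.0  # single voxel
        img[2, 6:8, 6:8] = 100.0  # 4 voxels
        stack = stack_of(img)
        objs = detect_objects(stack, "rnap", full_mask(img.shape), threshold=50.0, min_volume=2)
        assert len(objs) == 1 and objs[0].volume == 4


class TestNearestPositiveDistance:
    voxel = (100.0, 100.0, 200.0)

    def test_centroid_on_positive_voxel_center_is_zero(self):
        pos = np.zeros((4, 4, 4), bool)
        pos[1, 2, 3] = True
        c = ((3 + 0.5) * 100, (2 + 0.5) * 100, (1 + 0.5) * 200)
        assert nearest_positive_distance(c, pos, self.voxel) == 0.0

    def test_two_voxels_along_x(self):
        pos = np.zeros((1, 1, 5), bool)
        pos[0, 0, 4] = True
        c = ((2 + 0.5) * 100, 0.5 * 100, 0.5 * 200)
        assert nearest_positive_distance(c, pos, self.voxel) == pytest.approx(200.0)

    def test_diagonal_offset_anisotropic(self):
        pos = np.zeros((3, 3, 3), bool)
        pos[1, 1, 1] = True
        c = (0.5 * 100, 0.5 * 100, 0.5 * 200)
        d = nearest_positive_distance(c, pos, self.voxel)
        assert d == pytest.approx(math.sqrt(100**2 + 100**2 + 200**2))

    def test_no_positive_voxel_flagged_infinite(self):
        with pytest.warns(UserWarning, match="no positive voxel"):
            d = nearest_positive_distance((0, 0, 0), np.zeros((2, 2, 2), bool), self.voxel)
        assert math.isinf(d)

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(5):
            pos = rng.random((8, 12, 10)) < 0.03
            if not pos.any():
                pos[0, 0, 0] = True
            c = tuple(rng.uniform(0, 1000, 3))
            dx, dy, dz = self.voxel
            oracle = min(
                math.sqrt(
                    ((x + 0.5) * dx - c[0]) ** 2
                    + ((y + 0.5) * dy - c[1]) ** 2
                    + ((z + 0.5) * dz - c[2]) ** 2
                )
                for z in range(8) for y in range(12) for x in range(10)
                if pos[z, y, x]
            )
            assert nearest_positive_distance(c, pos, self.voxel) == pytest.approx(oracle)

    def test_scale_covariance(self, rng):
        pos = rng.random((6, 6, 6)) < 0.1
        pos[3, 3, 3] = True
        c = (220.0, 330.0, 440.0)
        d1 = nearest_positive_distance(c, pos, (100, 100, 200))
        d3 = nearest_positive_distance(tuple(3 * v for v in c), pos, (300, 300, 600))
        assert d3 == pytest.approx(3 * d1)


class TestColocalize:
    def test_threshold_inclusive_boundary(self):
        recs = colocalize([200.0, 225.0, 300.0])
        assert [r.colocalized for r in recs] == [True, True, False]

    def test_record_tuples_carried_through(self):
        recs = colocalize([("c1", "KCl", "cFos", 100.0)])
        assert recs[0] == ColocRecord("c1", "KCl", "cFos", 100.0, True)

    def test_scale_covariant_calls(self, rng):
        d = rng.uniform(0, 500, 20)
        base = [r.colocalized for r in colocalize(d.tolist(), 225.0)]
        scaled = [r.colocalized for r in colocalize((3 * d).tolist(), 3 * 225.0)]
        assert base == scaled


class TestCompareColocalization:
    def test_identical_proportions_p_one(self):
        assert compare_colocalization((5, 10), (5, 10)) == 1.0
        assert compare_colocalization((0, 30), (0, 30)) == 1.0

    def test_small_table_enumeration_value(self):
        assert compare_colocalization((2, 2), (0, 2)) == pytest.approx(1 / 3)

    def test_invalid_totals_rejected(self):
        with pytest.raises(ValueError):
            compare_colocalization((0, 0), (1, 2))


class TestParticleIntensities:
    def test_no_particles_total_zero(self):
        stack = stack_of(np.zeros((4, 8, 8)), name="fish")
        total, table = particle_intensities(stack, "fish", full_mask((4, 8, 8)), threshold=1.0)
        assert total == 0.0 and len(table) == 0

    def test_uniform_particle_total_is_m_times_v(self):
        img = np.zeros((5, 10, 10))
        img[2, 3:6, 3:6] = 40.0  # 9 voxels at 40
        stack = stack_of(img, name="fish")
        total, table = particle_intensities(stack, "fish", full_mask(img.shape), threshold=10.0)
        assert total == pytest.approx(9 * 40.0)
        assert table.iloc[0]["volume"] == 9

    def test_three_planted_particles_sum_within_tolerance(self, rng):
        spec = ImageSimSpec(shape=(16, 48, 48), n_foci=3, noise_sd=0.0,
                            spot_distances_nm=(), min_separation_nm=1200.0,
                            background=0.0)
        stack, truth = gen_image_stack(spec, rng)
        mask = NucleusMask(np.ones(spec.shape, bool))
        # analytic integrated intensity of each planted Gaussian
        per_blob = spec.focus_amplitude * (2 * np.pi) ** 1.5 * (
            spec.focus_sigma_nm**3 / (100 * 100 * 200)
        )
        total, table = particle_intensities(stack, "rnap", mask, threshold=1.0, min_volume=2)
        assert len(table) == 3
        assert total == pytest.approx(3 * per_blob, rel=0.25)


class TestRotationInvariance:
    def test_in_plane_rotation_preserves_counts_and_distances(self, rng):
        spec = ImageSimSpec(shape=(14, 40, 40), n_foci=8, noise_sd=0.0,
                            spot_distances_nm=(400.0,), min_separation_nm=900.0)
        stack, truth = gen_image_stack(spec, rng)
        mask = segment_nucleus(stack)
        n0 = count_factories(stack, "rnap", mask)
        rot = ImageStack(
            channels={k: np.rot90(v, axes=(1, 2)).copy() for k, v in stack.channels.items()},
            voxel_nm=stack.voxel_nm,
        )
        mask_r = segment_nucleus(rot)
        assert count_factories(rot, "rnap", mask_r) == n0
        pos0 = positive_voxels(stack, "rnap", mask)
        pos_r = positive_voxels(rot, "rnap", mask_r)
        spot = detect_objects(stack, "fish", mask, k=3.0)[0]
        spot_r = detect_objects(rot, "fish", mask_r, k=3.0)[0]
        d0 = nearest_positive_distance(spot.centroid_nm, pos0, stack.voxel_nm)
        d_r = nearest_positive_distance(spot_r.centroid_nm, pos_r, rot.voxel_nm)
        assert d_r == pytest.approx(d0, abs=1e-6)
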