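import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_axis_ratio, brute_force_otsu, flood_fill_labels
from gliaquant.droplet3d import (
    FilterParams,
    LabeledObject,
    apply_tracheal_filter,
    binarize_and_label,
    build_glia_mask,
    extract_lipid_content,
    measure_all_objects,
    measure_shape,
    otsu_threshold_3d,
    run_lipid_pipeline,
)
from gliaquant.io_stack import GeometryError, ImageStack, Polygon2D


def _rasterize_ellipsoid(semi_axes, center, shape):
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    a, b, c = semi_axes
    cz, cy, cx = center
    return (((zz - cz) / a) ** 2 + ((yy - cy) / b) ** 2 + ((xx - cx) / c) ** 2) <= 1


class TestOtsu:
    def test_bimodal_volume_separates_modes(self):
        vox = np.full(1000, 10.0)
        vox[:100] = 200.0
        thr = otsu_threshold_3d(ImageStack(vox.reshape(10, 10, 10)))
        assert 10.0 < thr < 200.0

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold_3d(ImageStack(np.full((4, 4, 4), 7.0)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(4, 33, size=3))
        if seed % 2:
            vox = rng.integers(0, 256, size=shape).astype(float)
        else:  # bimodal mixture, closer to real stain statistics
            vox = np.where(rng.random(shape) < 0.1,
                           rng.normal(180, 20, shape), rng.normal(30, 10, shape))
            vox = np.clip(vox, 0, None)
        stack = ImageStack(vox)
        assert otsu_threshold_3d(stack) == brute_force_otsu(stack.voxels)


class TestBinarizeAndLabel:
    def test_separated_spheres_get_two_labels(self):
        vox = np.zeros((10, 20, 10))
        vox[4, 4, 4] = vox[4, 14, 4] = 100.0
        labels = binarize_and_label(ImageStack(vox), 50.0)
        assert labels.max() == 2

    def test_corner_touching_depends_on_connectivity(self):
        # two voxels sharing only a corner: one component at 26, two at 6
        vox = np.zeros((4, 4, 4))
        vox[1, 1, 1] = vox[2, 2, 2] = 100.0
        stack = ImageStack(vox)
        for conn in (6, 18, 26):
            got = binarize_and_label(stack, 50.0, connectivity=conn).max()
            assert got == flood_fill_labels(vox > 50.0, conn)
        assert binarize_and_label(stack, 50.0, connectivity=26).max() == 1
        assert binarize_and_label(stack, 50.0, connectivity=6).max() == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_random_volumes_match_flood_fill(self, seed):
        rng = np.random.default_rng(seed + 100)
        binary = rng.random((8, 8, 8)) < 0.15
        stack = ImageStack(binary.astype(float) * 100)
        for conn in (6, 18, 26):
            got = binarize_and_label(stack, 50.0, connectivity=conn).max()
            assert got == flood_fill_labels(binary, conn)

    def test_empty_foreground_gives_no_labels(self):
        labels = binarize_and_label(ImageStack(np.ones((4, 4, 4))), 10.0)
        assert labels.max() == 0


class TestMeasureShape:
    def test_single_voxel_is_isotropic(self):
        lab = np.zeros((3, 3, 3), dtype=int)
        lab[1, 1, 1] = 1
        n, lengths, ratio = measure_shape(lab, 1)
        assert n == 1
        assert ratio == 1.0
        assert lengths[0] == lengths[1] == lengths[2]

    def test_elongated_ellipsoid_ratio_matches_brute_force(self):
        """Aliasing-averaged ratio of a 10:2 ellipsoid is ~5; every placement
        agrees exactly with brute-force voxel moments."""
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(12):
            center = 13 + rng.uniform(0, 1), 5 + rng.uniform(0, 1), 5 + rng.uniform(0, 1)
            ell = _rasterize_ellipsoid((10, 2, 2), center, (27, 11, 11))
            _, _, ratio = measure_shape(ell.astype(int), 1)
            assert ratio == pytest.approx(brute_force_axis_ratio(np.argwhere(ell)), rel=1e-9)
            ratios.append(ratio)
        assert np.mean(ratios) == pytest.approx(5.0, abs=0.3)

    def test_ball_is_round_with_analytic_volume(self):
        ball = _rasterize_ellipsoid((6, 6, 6), (7, 7, 7), (15, 15, 15))
        n, _, ratio = measure_shape(ball.astype(int), 1)
        assert ratio <= 1.1
        assert n == pytest.approx(4 / 3 * np.pi * 6**3, rel=0.05)

    def test_axis_ratio_invariant_under_axis_permutation(self):
        ell = _rasterize_ellipsoid((8, 3, 2), (10, 5, 4), (21, 11, 9))
        base = measure_shape(ell.astype(int), 1)[2]
        for perm in ((1, 0, 2), (2, 1, 0), (1, 2, 0)):
            assert measure_shape(np.transpose(ell, perm).astype(int), 1)[2] == pytest.approx(
                base, rel=1e-12
            )

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            measure_shape(np.zeros((2, 2, 2), dtype=int), 3)

    def test_physical_mode_uses_spacing(self):
        # a z-column of voxels: isotropic spacing ratio >> anisotropic-corrected
        lab = np.zeros((10, 3, 3), dtype=int)
        lab[2:8, 1, 1] = 1
        _, _, voxel_ratio = measure_shape(lab, 1, spacing_mode="voxel")
        _, _, phys_ratio = measure_shape(lab, 1, spacing=(0.3, 1, 1), spacing_mode="physical")
        assert phys_ratio < voxel_ratio


class TestTrachealFilter:
    @pytest.mark.parametrize(
        "ratio,volume,kept",
        [
            (6.0, 100, False),    # elongated: removed
            (2.0, 5001, False),   # oversized: removed
            (5.0, 5000, True),    # boundary values survive (strict inequality)
            (1.0, 1, True),
        ],
    )
    def test_strict_inequality_semantics(self, ratio, volume, kept):
        obj = LabeledObject(1, volume, (1, 1, 1), ratio)
        apply_tracheal_filter([obj])
        assert obj.kept is kept

    @given(
        ratios=st.lists(st.floats(1.0, 20.0), min_size=1, max_size=30),
        volumes=st.lists(st.integers(1, 10000), min_size=1, max_size=30),
        bump=st.floats(0.0, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_thresholds_never_drops_kept_count(self, ratios, volumes, bump):
        objs = [
            LabeledObject(i, v, (1, 1, 1), r)
            for i, (r, v) in enumerate(zip(ratios, volumes), start=1)
        ]
        base = FilterParams()
        kept_before = sum(o.kept for o in apply_tracheal_filter(objs, base))
        wider = FilterParams(ratio_threshold=base.ratio_threshold + bump,
                             volume_threshold_voxels=base.volume_threshold_voxels + int(bump * 100))
        kept_after = sum(o.kept for o in apply_tracheal_filter(objs, wider))
        assert kept_after >= kept_before


class TestGliaMask:
    def test_prism_count_is_area_times_depth(self):
        poly = Polygon2D(((0, 0), (0, 10), (10, 10), (10, 0)))
        mask = build_glia_mask(poly, (5, 20, 20))
        assert mask.voxel_count == 500

    def test_z_range_restriction(self):
        poly = Polygon2D(((0, 0), (0, 10), (10, 10), (10, 0)))
        mask = build_glia_mask(poly, (5, 20, 20), z_range=(1, 3))
        assert mask.voxel_count == 200

    def test_polygon_outside_bounds_rejected(self):
        poly = Polygon2D(((100, 100), (100, 110), (110, 110), (110, 100)))
        with pytest.raises(GeometryError):
            build_glia_mask(poly, (5, 20, 20))

    def test_in_mask_pixels_lie_inside_polygon(self):
        from gliaquant.io_stack import points_in_polygon

        poly = Polygon2D(((2.5, 1.5), (2.5, 15.5), (14.0, 12.0), (10.0, 3.0)))
        mask = build_glia_mask(poly, (3, 18, 18))
        zs, ys, xs = np.nonzero(mask.volume)
        assert points_in_polygon(poly, ys.astype(float), xs.astype(float)).all()


class TestExtraction:
    def test_straddling_object_matches_per_voxel_sum(self):
        rng = np.random.default_rng(5)
        vox = rng.uniform(0, 100, size=(6, 20, 20))
        labels = np.zeros((6, 20, 20), dtype=int)
        labels[2:5, 8:13, 8:13] = 1  # straddles the x=10 mask boundary
        poly = Polygon2D(((0, 0), (0, 10), (20, 10), (20, 0)))
        mask = build_glia_mask(poly, (6, 20, 20))
        objs = [LabeledObject(1, int((labels == 1).sum()), (1, 1, 1), 1.0)]
        result = extract_lipid_content(ImageStack(vox), labels, objs, mask)
        brute = sum(
            vox[z, y, x]
            for z, y, x in np.argwhere(labels == 1)
            if mask.volume[z, y, x]
        )
        assert result.total_lipid_content == pytest.approx(brute, rel=1e-12)

    def test_object_outside_mask_contributes_zero_but_stays(self):
        vox = np.full((3, 20, 20), 50.0)
        labels = np.zeros((3, 20, 20), dtype=int)
        labels[1, 15:18, 15:18] = 1
        poly = Polygon2D(((0, 0), (0, 10), (10, 10), (10, 0)))
        mask = build_glia_mask(poly, (3, 20, 20))
        objs = [LabeledObject(1, 9, (1, 1, 1), 1.0)]
        result = extract_lipid_content(ImageStack(vox), labels, objs, mask)
        assert result.total_lipid_content == 0.0
        assert len(result.objects) == 1

    def test_shape_mismatch_rejected(self):
        poly = Polygon2D(((0, 0), (0, 5), (5, 5), (5, 0)))
        mask = build_glia_mask(poly, (2, 10, 10))
        with pytest.raises(GeometryError):
            extract_lipid_content(
                ImageStack(np.ones((3, 10, 10))), np.zeros((3, 10, 10), dtype=int), [], mask
            )


class TestPipeline:
    def test_ground_truth_recovery_noise_free(self, noise_free_scene):
        spec, channels, truth = noise_free_scene
        result = run_lipid_pipeline(channels, spec.glia_polygon)
        assert result.n_kept == len(spec.droplets)
        assert result.n_filtered == len(spec.tubes)
        assert result.total_lipid_content == pytest.approx(truth.total_lipid_content, rel=1e-12)

    def test_conservation_total_bounded_by_mask_intensity(self, noisy_scene):
        spec, channels, truth = noisy_scene
        result = run_lipid_pipeline(channels, spec.glia_polygon)
        mask3d = np.broadcast_to(truth.glia_mask_2d, spec.shape)
        assert result.total_lipid_content <= channels["lipid"].voxels[mask3d].sum()

    def test_empty_scene_yields_zero(self):
        from gliaquant.synthetic import SceneSpec, render_scene

        poly = Polygon2D(((4, 4), (4, 20), (20, 20), (20, 4)))
        spec = SceneSpec(shape=(4, 24, 24), droplets=(), tubes=(),
                         glia_polygon=poly, noise_sd=1.0, seed=3)
        channels, _ = render_scene(spec)
        result = run_lipid_pipeline(channels, poly)
        # noise-only scene: whatever speckle survives Otsu has negligible mass
        assert result.total_lipid_content <= 0.05 * channels["lipid"].voxels.sum()

    def test_same_seed_identical_result(self):
        from gliaquant import random_scene, render_scene

        frames = []
        for _ in range(2):
            spec = random_scene(seed=11)
            channels, _ = render_scene(spec)
            frames.append(run_lipid_pipeline(channels, spec.glia_polygon).to_frame())
        assert frames[0].equals(frames[1])

    def test_measure_all_objects_counts_every_label(self, noise_free_scene):
        spec, channels, truth = noise_free_scene
        thr = otsu_threshold_3d(channels["lipid"])
        labels = binarize_and_label(channels["lipid"], thr)
        objs = measure_all_objects(labels)
        assert len(objs) == len(spec.droplets) + len(spec.tubes)
        assert sum(o.voxel_count for o in objs) == int((labels > 0).sum())
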