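"""Image pipeline: preprocessing, Otsu, skeletonization, graph extraction, area."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lnvasc as lv
from lnvasc import imaging
from lnvasc.core import BinaryMask, VoxelVolume

from conftest import make_cylinder_graph


def vol(data, voxel=1.0):
    return VoxelVolume(np.asarray(data), voxel)


class TestTo8bit:
    def test_constant_volume_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = imaging.to_8bit(vol(np.full((4, 4, 4), 7.0)))
        assert out.data.dtype == np.uint8
        assert not out.data.any()

    def test_endpoints_map_to_endpoints(self):
        data = np.zeros((2, 2, 2), dtype=np.uint16)
        data[0, 0, 0] = 65535
        out = imaging.to_8bit(vol(data))
        assert set(np.unique(out.data)) == {0, 255}

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_elementwise_formula(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 65536, size=(5, 5, 5)).astype(np.uint16)
        if data.min() == data.max():
            return
        out = imaging.to_8bit(vol(data))
        lo, hi = data.min(), data.max()
        expected = np.rint(255.0 * (data.astype(float) - lo) / (hi - lo))
        assert np.array_equal(out.data, expected.astype(np.uint8))


class TestMedianFilter:
    def test_constant_volume_unchanged(self):
        out = imaging.median_filter_3(vol(np.full((5, 5, 5), 9.0)))
        assert np.all(out.data == 9.0)

    def test_impulse_rejected(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 100.0
        out = imaging.median_filter_3(vol(data))
        assert not out.data.any()

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 255, (5, 5, 5))
        out = imaging.median_filter_3(vol(data))
        padded = np.pad(data, 1, mode="symmetric")  # edge-inclusive reflection
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    hood = padded[i : i + 3, j : j + 3, k : k + 3].ravel()
                    assert out.data[i, j, k] == pytest.approx(np.sort(hood)[13])


class TestExclusionMask:
    def test_all_false_is_identity(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 255, (4, 4, 4))
        out = imaging.apply_exclusion_mask(
            vol(data), BinaryMask(np.zeros((4, 4, 4), bool), 1.0)
        )
        assert np.array_equal(out.data, data)

    def test_all_true_blanks_everything(self):
        out = imaging.apply_exclusion_mask(
            vol(np.ones((4, 4, 4))), BinaryMask(np.ones((4, 4, 4), bool), 1.0)
        )
        assert not out.data.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            imaging.apply_exclusion_mask(
                vol(np.ones((4, 4, 4))), BinaryMask(np.ones((3, 3, 3), bool), 1.0)
            )

    def test_cone_mask_matches_per_voxel_membership(self):
        shape = (21, 21, 21)
        apex = np.array([10.0, 10.0, 10.0])
        axis = np.array([0.0, 0.0, 1.0])
        mask = imaging.cone_mask(shape, apex, axis, 45.0, voxel_size=1.0)
        brute = np.zeros(shape, bool)
        for idx in np.ndindex(shape):
            rel = np.asarray(idx, float) - apex
            n = np.linalg.norm(rel)
            brute[idx] = n == 0 or rel @ axis >= n * np.cos(np.deg2rad(45.0))
        assert np.array_equal(mask.data, brute)


def otsu_exhaustive(counts):
    """Exhaustive 256-level between-class-variance argmax (lowest tie)."""
    total = counts.sum()
    levels = np.arange(256)
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[: t + 1] * counts[: t + 1]).sum() / w0
        mu1 = (levels[t + 1 :] * counts[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-9 * max(best_v, 1.0):
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_delta_histogram_lowest_tie(self):
        data = np.concatenate([np.full(500, 50), np.full(500, 200)])
        volume = vol(data.reshape(10, 10, 10).astype(np.uint8))
        mask = imaging.otsu_segment(volume)
        assert mask.threshold_used == 50  # lowest maximizing bin
        assert mask.foreground_count() == 500

    def test_single_valued_histogram_rejected(self):
        with pytest.raises(imaging.PipelineError, match="single-valued"):
            imaging.otsu_segment(vol(np.full((4, 4, 4), 3, dtype=np.uint8)))

    @pytest.mark.parametrize("seed", range(30))
    def test_threshold_equals_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        n_modes = rng.integers(2, 5)
        samples = np.concatenate(
            [
                rng.normal(rng.uniform(20, 230), rng.uniform(2, 30), rng.integers(50, 500))
                for _ in range(n_modes)
            ]
        )
        data = np.clip(np.rint(samples), 0, 255).astype(np.uint8)
        data = np.resize(data, 1000).reshape(10, 10, 10)
        mask = imaging.otsu_segment(vol(data))
        expected = otsu_exhaustive(np.bincount(data.ravel(), minlength=256))
        assert mask.threshold_used == expected

    def test_phantom_foreground_count_near_truth(self, small_phantom, small_phantom_spec):
        from dataclasses import replace

        spec = replace(small_phantom_spec, noise_sd=8.0)
        volume = lv.rasterize_graph(small_phantom, spec)
        truth_count = int(
            (lv.rasterize_graph(small_phantom, small_phantom_spec).data > 100).sum()
        )
        mask = imaging.otsu_segment(imaging.to_8bit(volume))
        assert mask.foreground_count() == pytest.approx(truth_count, rel=0.05)


def cylinder_mask(shape, p0, p1, radius, voxel=1.0):
    idx = np.moveaxis(np.indices(shape), 0, -1).astype(float) * voxel
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    axis = p1 - p0
    t = ((idx - p0) @ axis) / (axis @ axis)
    closest = p0 + t[..., None] * axis
    dist = np.linalg.norm(idx - closest, axis=-1)
    return BinaryMask((dist <= radius) & (t >= 0) & (t <= 1), voxel)


class TestSkeletonize:
    def test_cylinder_skeleton_hugs_axis(self):
        mask = cylinder_mask((120, 31, 31), [10, 15, 15], [110, 15, 15], 5.0)
        skel = imaging.skeletonize(mask)
        pts = np.argwhere(skel)
        assert np.abs(pts[:, 1:] - 15).max() <= 1  # Hausdorff to the axis

    def test_ball_collapses_to_few_voxels(self):
        idx = np.moveaxis(np.indices((31, 31, 31)), 0, -1)
        ball = np.linalg.norm(idx - 15, axis=-1) <= 10
        skel = imaging.skeletonize(BinaryMask(ball, 1.0))
        assert skel.sum() <= 10

    def test_torus_retains_one_cycle(self):
        idx = np.moveaxis(np.indices((41, 41, 15)), 0, -1).astype(float)
        xy = idx[..., :2] - 20.0
        ring = np.abs(np.linalg.norm(xy, axis=-1) - 12.0)
        torus = np.sqrt(ring**2 + (idx[..., 2] - 7.0) ** 2) <= 4.0
        skel = imaging.skeletonize(BinaryMask(torus, 1.0))
        graph = imaging.extract_graph(skel, BinaryMask(torus, 1.0))
        # cycle count = E − V + C on the extracted graph
        g = graph.to_networkx()
        import networkx as nx

        cycles = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
        assert cycles == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(imaging.PipelineError, match="empty"):
            imaging.skeletonize(BinaryMask(np.zeros((4, 4, 4), bool), 1.0))


class TestExtractGraph:
    def test_single_cylinder_one_segment(self):
        mask = cylinder_mask((220, 31, 31), [10, 15, 15], [210, 15, 15], 5.0)
        skel = imaging.skeletonize(mask)
        g = imaging.extract_graph(skel, mask)
        assert len(g.segments) == 1
        kinds = [n.kind for n in g.nodes.values()]
        assert sorted(kinds) == ["end", "end"]
        seg = next(iter(g.segments.values()))
        # thinning retracts ~r from each flat end; 5% covers that at L = 20 d
        assert seg.length_um == pytest.approx(200.0, rel=0.05)

    def test_y_junction_three_segments(self):
        shape = (80, 80, 21)
        center = [40.0, 40.0, 10.0]
        masks = [
            cylinder_mask(shape, center, [40.0, 5.0, 10.0], 3.0),
            cylinder_mask(shape, center, [10.0, 70.0, 10.0], 3.0),
            cylinder_mask(shape, center, [70.0, 70.0, 10.0], 3.0),
        ]
        mask = BinaryMask(np.logical_or.reduce([m.data for m in masks]), 1.0)
        skel = imaging.skeletonize(mask)
        g = imaging.extract_graph(skel, mask)
        assert len(g.segments) == 3
        assert sum(1 for n in g.nodes.values() if n.kind == "branch") == 1
        assert sum(1 for n in g.nodes.values() if n.kind == "end") == 3

    def test_voxel_partition_conserves_mask_volume(self, small_phantom, small_phantom_spec):
        volume = lv.rasterize_graph(small_phantom, small_phantom_spec)
        mask = imaging.otsu_segment(imaging.to_8bit(volume))
        skel = imaging.skeletonize(mask)
        g = imaging.extract_graph(skel, mask)
        assert sum(s.voxel_count for s in g.segments.values()) == mask.foreground_count()
        assert g.total_volume_um3() == pytest.approx(mask.foreground_volume_um3())

    def test_hint_outside_mask_rejected(self):
        mask = cylinder_mask((60, 21, 21), [5, 10, 10], [55, 10, 10], 4.0)
        skel = imaging.skeletonize(mask)
        with pytest.raises(imaging.PipelineError, match="outside the mask"):
            imaging.extract_graph(skel, mask, inlet_hint=np.array([0.0, 0.0, 0.0]))

    def test_disconnected_inlet_outlet_reported(self):
        m1 = cylinder_mask((100, 41, 21), [5, 10, 10], [95, 10, 10], 3.0)
        m2 = cylinder_mask((100, 41, 21), [5, 30, 10], [95, 30, 10], 3.0)
        mask = BinaryMask(m1.data | m2.data, 1.0)
        skel = imaging.skeletonize(mask)
        with pytest.raises(imaging.PipelineError, match="components"):
            imaging.extract_graph(
                skel, mask,
                inlet_hint=np.array([5.0, 10.0, 10.0]),
                outlet_hint=np.array([95.0, 30.0, 10.0]),
            )


class TestDiameterEstimate:
    def test_algebraic_identity(self):
        assert imaging.estimate_diameter(100 * np.pi, 100.0) == pytest.approx(2.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            imaging.estimate_diameter(10.0, 0.0)

    def test_voxel_volume_at_081(self):
        assert 0.81**3 == pytest.approx(0.53, abs=0.005)

    @pytest.mark.parametrize("d_vox", [6, 8, 10])
    @pytest.mark.parametrize("oblique", [False, True])
    def test_cylinder_recovery_within_5pct(self, d_vox, oblique):
        d = float(d_vox)
        length = 20 * d
        if oblique:  # 30° from the x-axis
            p1 = np.array([15 + length * np.cos(np.pi / 6), 15 + length * np.sin(np.pi / 6), 24.0])
        else:
            p1 = np.array([15 + length, 15.0, 24.0])
        p0 = np.array([15.0, 15.0, 24.0])
        pad = 30
        shape = (int(p1[0]) + pad, int(p1[1]) + pad, 48)
        spec = lv.PhantomSpec(
            domain_size=tuple(float(s) for s in shape), voxel_size=1.0,
        )
        g = make_cylinder_graph(p0, p1, d)
        volume = lv.rasterize_graph(g, spec, flat_caps=True)
        mask = imaging.otsu_segment(imaging.to_8bit(volume))
        skel = imaging.skeletonize(mask)
        graph = imaging.extract_graph(skel, mask)
        assert len(graph.segments) == 1
        seg = next(iter(graph.segments.values()))
        assert seg.diameter_um == pytest.approx(d, rel=0.05)


class TestSurfaceArea:
    def test_cube_area_analytic(self):
        data = np.zeros((60, 60, 60), bool)
        data[10:50, 10:50, 10:50] = True  # side 40 voxels
        mask = BinaryMask(data, 1.0)
        bm, total_mm2 = imaging.surface_area_blockwise(mask, 16)
        assert bm.total() == pytest.approx(6 * 40**2, rel=0.05)

    def test_cylinder_area_analytic(self):
        mask = cylinder_mask((160, 31, 31), [5, 15, 15], [155, 15, 15], 5.0)
        area = imaging.surface_area_total(mask)
        assert area == pytest.approx(np.pi * 10.0 * 150.0, rel=0.10)

    @pytest.mark.parametrize("block", [16, 25, 37])
    def test_blockwise_sum_matches_whole_volume(self, block, small_phantom, small_phantom_spec):
        volume = lv.rasterize_graph(small_phantom, small_phantom_spec)
        mask = imaging.otsu_segment(imaging.to_8bit(volume))
        bm, total_mm2 = imaging.surface_area_blockwise(mask, block)
        whole = imaging.surface_area_total(mask)
        assert bm.total() == pytest.approx(whole, rel=0.02)

    def test_empty_mask_zero_map(self):
        bm, total = imaging.surface_area_blockwise(
            BinaryMask(np.zeros((20, 20, 20), bool), 1.0), 10
        )
        assert total == 0.0 and not bm.values.any()
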