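import numpy as np
import pytest

from nrrs.evaluation import (
    auto_mean_shift_refine,
    bifurcation_deviation,
    information_extraction_rate,
    intensity_extraction,
    make_mip,
    mean_shift_refine,
    radius_estimate,
    run_benchmark,
    skeleton_deviation,
    storage_size,
    summarize,
)
from nrrs.gd_tracer import ImageBlock
from nrrs.swc_core import swc_bytes, write_swc
from nrrs.synthetic import SyntheticSample, TubeModel, generate_skeleton, render_image

from conftest import make_tube, tree_from_rows


def line_tree(y=10.0, n=21, radius=2.0):
    rows = [(1, 1, 4, y, 10, radius, -1)] + [
        (i, 3, 4.0 + (i - 1), y, 10, radius, i - 1) for i in range(2, n + 1)
    ]
    return tree_from_rows(rows)


class TestSkeletonDeviation:
    def test_identical_trees_zero(self, y_tree):
        assert skeleton_deviation(y_tree, y_tree) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_shift_equals_offset(self):
        assert skeleton_deviation(line_tree(10), line_tree(13)) == pytest.approx(3.0, abs=1e-9)

    def test_chord_vs_arc_matches_dense_oracle(self):
        # quarter arc of radius 20 vs its chord
        theta = np.linspace(0, np.pi / 2, 40)
        arc = np.stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros_like(theta)], axis=1)
        rows = [(1, 1, *arc[0], 1.0, -1)] + [
            (i, 3, *arc[i - 1], 1.0, i - 1) for i in range(2, len(arc) + 1)
        ]
        arc_tree = tree_from_rows(rows)
        chord_tree = tree_from_rows(
            [(1, 1, 20, 0, 0, 1.0, -1), (2, 3, 0, 20, 0, 1.0, 1)]
        )
        got = skeleton_deviation(chord_tree, arc_tree, resample_step=2.0)
        # brute-force oracle: same 2 µm stations on the chord, distances
        # against a densely sampled true arc (no shared code path)
        a, b = np.array([20.0, 0, 0]), np.array([0.0, 20, 0])
        length = np.linalg.norm(b - a)
        stations = np.append(np.arange(0.0, length, 2.0), length)
        chord = a + (stations / length)[:, None] * (b - a)
        tt = np.linspace(0, np.pi / 2, 3142)
        dense_arc = np.stack([20 * np.cos(tt), 20 * np.sin(tt), np.zeros_like(tt)], axis=1)
        d = np.linalg.norm(chord[:, None, :] - dense_arc[None, :, :], axis=2).min(axis=1)
        assert got == pytest.approx(float(d.mean()), rel=0.02)

    def test_translation_symmetric(self):
        a, b = line_tree(10), line_tree(12)
        shifted_a, shifted_b = line_tree(30), line_tree(32)
        assert skeleton_deviation(a, b) == pytest.approx(
            skeleton_deviation(shifted_a, shifted_b), rel=1e-9
        )


class TestBifurcationDeviation:
    def test_identical_zero(self, y_tree):
        assert bifurcation_deviation(y_tree, y_tree) == 0.0

    def test_single_displacement(self, y_tree):
        moved = y_tree.copy()
        moved.bifurcations()[0].position += np.array([0.0, 0, 4])
        assert bifurcation_deviation(moved, y_tree) == pytest.approx(4.0)

    def test_mean_of_two(self):
        rows = [
            (1, 1, 0, 0, 0, 1, -1), (2, 3, 0, 4, 0, 1, 1),
            (3, 3, -3, 8, 0, 1, 2), (4, 3, 3, 8, 0, 1, 2),
            (5, 3, -6, 12, 0, 1, 3), (6, 3, -1, 12, 0, 1, 3),
        ]
        gt = tree_from_rows(rows)
        moved = gt.copy()
        moved.node(2).position += np.array([2.0, 0, 0])
        moved.node(3).position += np.array([0.0, 0, 6])
        assert bifurcation_deviation(moved, gt) == pytest.approx(4.0)

    def test_topology_mismatch_raises(self, y_tree, chain_tree):
        with pytest.raises(ValueError, match="topology"):
            bifurcation_deviation(chain_tree, y_tree)

    def test_no_bifurcations_nan(self, chain_tree):
        assert np.isnan(bifurcation_deviation(chain_tree, chain_tree))


class TestRadiusEstimate:
    def test_on_center_matches_half_amplitude_radius(self):
        tube = TubeModel(radius=3.0, noise_sigma=0.0)
        tree = line_tree(24, radius=3.0)
        img = render_image(tree, (30, 48, 20), tube, seed=0)
        thr = tube.background_level + (tube.peak_intensity - tube.background_level) / 2
        est = radius_estimate(tree, img, thr)
        mid = [n.radius for n in est.nodes][5:-5]
        assert abs(np.mean(mid) - 3.0) <= 1.0

    def test_off_center_smaller(self):
        tube = TubeModel(radius=3.0, noise_sigma=0.0)
        tree = line_tree(24, radius=3.0)
        img = render_image(tree, (30, 48, 20), tube, seed=0)
        thr = tube.background_level + (tube.peak_intensity - tube.background_level) / 2
        on = radius_estimate(tree, img, thr)
        off = radius_estimate(line_tree(26, radius=3.0), img, thr)
        assert np.mean([n.radius for n in off.nodes]) < np.mean([n.radius for n in on.nodes])

    def test_dark_region_zero(self):
        img = ImageBlock(np.zeros((30, 48, 20), dtype=np.uint8))
        est = radius_estimate(line_tree(24), img, bg_threshold=10)
        assert all(n.radius == 0.0 for n in est.nodes)


class TestIntensityExtraction:
    def test_on_centerline_peak(self):
        b = make_tube(shape=(30, 20, 20), p0=(2, 10, 10), p1=(28, 10, 10))
        t = tree_from_rows(
            [(1, 1, 5, 10, 10, 1, -1), (2, 3, 15, 10, 10, 1, 1), (3, 3, 25, 10, 10, 1, 2)]
        )
        assert intensity_extraction(t, b) == pytest.approx(200.0, rel=1e-6)

    def test_background_and_mean(self):
        data = np.zeros((20, 20, 20))
        data[:10] = 100.0
        b = ImageBlock(data)
        bright = tree_from_rows([(1, 1, 2, 10, 10, 1, -1), (2, 3, 6, 10, 10, 1, 1)])
        dark = tree_from_rows([(1, 1, 14, 10, 10, 1, -1), (2, 3, 18, 10, 10, 1, 1)])
        mixed = tree_from_rows([(1, 1, 2, 10, 10, 1, -1), (2, 3, 18, 10, 10, 1, 1)])
        assert intensity_extraction(bright, b) == pytest.approx(100.0)
        assert intensity_extraction(dark, b) == pytest.approx(0.0)
        assert intensity_extraction(mixed, b) == pytest.approx(50.0)


class TestInformationExtractionRate:
    def test_self_overlap_is_one(self):
        assert information_extraction_rate(line_tree(), line_tree()) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert information_extraction_rate(line_tree(30), line_tree(10)) == pytest.approx(0.0)

    def test_shifted_tube_matches_voxel_oracle(self):
        gt, test = line_tree(10), line_tree(12)
        got = information_extraction_rate(test, gt, resample_step=2.0)
        # brute-force voxel enumeration over the union bounding box
        from nrrs.evaluation import resampled_points

        gp, gr = resampled_points(gt, 2.0)
        tp, tr = resampled_points(test, 2.0)
        lo = np.floor(np.minimum(gp.min(0), tp.min(0)) - 3).astype(int)
        hi = np.ceil(np.maximum(gp.max(0), tp.max(0)) + 3).astype(int)
        sg, st = set(), set()
        for x in range(lo[0], hi[0] + 1):
            for y in range(lo[1], hi[1] + 1):
                for z in range(lo[2], hi[2] + 1):
                    v = np.array([x, y, z], float)
                    if np.min(np.linalg.norm(gp - v, axis=1) - gr) <= 0:
                        sg.add((x, y, z))
                    if np.min(np.linalg.norm(tp - v, axis=1) - tr) <= 0:
                        st.add((x, y, z))
        assert got == pytest.approx(len(sg & st) / len(sg), abs=1e-9)


class TestStorage:
    def test_counts_and_bytes(self, y_tree, tmp_path):
        n, size = storage_size(y_tree)
        assert n == 5
        p = tmp_path / "t.swc"
        write_swc(y_tree, p)
        assert size == p.stat().st_size
        assert size == len(swc_bytes(y_tree))

    def test_finer_resampling_more_nodes(self):
        from nrrs.evaluation import resample_tree

        t = line_tree()
        coarse = resample_tree(t, 4.0)
        fine = resample_tree(t, 1.0)
        assert storage_size(fine)[0] > storage_size(coarse)[0]


class TestMeanShift:
    def test_symmetric_sphere_fixed_point(self):
        ax = np.arange(21, dtype=float)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        d2 = (gx - 10) ** 2 + (gy - 10) ** 2 + (gz - 10) ** 2
        img = ImageBlock(200 * np.exp(-d2 / 18))
        t = tree_from_rows(
            [(1, 1, 10, 10, 4, 1, -1), (2, 3, 10, 10, 10, 1, 1), (3, 3, 10, 10, 16, 1, 2)]
        )
        out = mean_shift_refine(t, img, search_radius=4.0)
        assert np.linalg.norm(out.node(2).position - [10, 10, 10]) < 1e-6

    def test_off_axis_node_converges_to_tube(self):
        b = make_tube(shape=(30, 20, 20), p0=(2, 10, 10), p1=(28, 10, 10))
        t = tree_from_rows(
            [(1, 1, 5, 10, 10, 1, -1), (2, 3, 15, 12, 10, 1, 1), (3, 3, 25, 10, 10, 1, 2)]
        )
        out = mean_shift_refine(t, b, search_radius=4.0)
        assert np.linalg.norm(out.node(2).position[1:] - [10, 10]) < 0.5

    def test_far_from_signal_unmoved(self):
        data = np.zeros((40, 30, 20))
        data[5:8, 5:8, 5:8] = 200.0
        b = ImageBlock(data)
        t = tree_from_rows(
            [(1, 1, 30, 25, 15, 1, -1), (2, 3, 33, 25, 15, 1, 1), (3, 3, 36, 25, 15, 1, 2)]
        )
        out = mean_shift_refine(t, b, search_radius=5.0)
        assert np.array_equal(out.node(2).position, t.node(2).position)

    def test_displacement_capped_by_search_radius(self):
        b = make_tube(shape=(30, 24, 20), p0=(2, 18, 10), p1=(28, 18, 10))
        t = tree_from_rows(
            [(1, 1, 5, 10, 10, 1, -1), (2, 3, 15, 10, 10, 1, 1), (3, 3, 25, 10, 10, 1, 2)]
        )
        out = mean_shift_refine(t, b, search_radius=3.0)
        assert np.linalg.norm(out.node(2).position - t.node(2).position) <= 3.0 + 1e-9


class TestAutoMeanShift:
    def test_node_count_grows(self):
        b = make_tube(shape=(30, 20, 20), p0=(2, 10, 10), p1=(28, 10, 10))
        t = tree_from_rows(
            [(1, 1, 4, 10, 10, 2, -1), (2, 3, 15, 10, 10, 2, 1), (3, 3, 26, 10, 10, 2, 2)]
        )
        out = auto_mean_shift_refine(t, b, bg_threshold=100.0)
        assert len(out.nodes) >= len(t.nodes)

    def test_dark_region_nodes_unmoved(self):
        img = ImageBlock(np.zeros((30, 20, 20), dtype=np.uint8))
        t = tree_from_rows(
            [(1, 1, 4, 10, 10, 2, -1), (2, 3, 15, 10, 10, 2, 1), (3, 3, 26, 10, 10, 2, 2)]
        )
        out = auto_mean_shift_refine(t, img, bg_threshold=10.0)
        for n in out.nodes:
            assert n.position[1] == 10.0 and n.position[2] == 10.0


class TestMip:
    def test_single_bright_voxel(self):
        data = np.zeros((10, 12, 6), dtype=np.uint8)
        data[3, 7, 2] = 255
        m = make_mip(ImageBlock(data), axis="z")
        assert m.shape == (10, 12)
        assert m[3, 7] == 255 and m.sum() == 255

    def test_zero_volume(self):
        assert make_mip(np.zeros((4, 4, 4))).max() == 0

    def test_max_preserved(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 255, (8, 8, 8)).astype(np.uint8)
        for axis in ("x", "y", "z"):
            assert make_mip(data, axis=axis).max() == data.max()


class TestBenchmark:
    def _tiny_dataset(self):
        tube = TubeModel(radius=2.2)
        gt = generate_skeleton(50, (64, 64, 48), radius=tube.radius)
        img = render_image(gt, (64, 64, 48), tube, seed=51)
        from nrrs.synthetic import perturb

        pert = perturb(gt, "case3_shift", seed=52, magnitude=5.0)
        params = {"tube": {"background_level": tube.background_level, "peak_intensity": tube.peak_intensity}}
        return [SyntheticSample(gt, pert, img, "case3_shift", params)]

    def test_identity_ratios_are_100(self, tmp_path):
        ds = self._tiny_dataset()
        df = run_benchmark(ds, methods=("identity",), out_path=tmp_path)
        s = summarize(df)
        assert s["methods"]["identity"]["skeleton_deviation_ratio_pct"] == pytest.approx(100.0)
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "summary.json").exists()

    def test_ground_truth_as_test_scores_zero(self):
        ds = self._tiny_dataset()
        ds[0].perturbed = ds[0].ground_truth.copy()
        df = run_benchmark(ds, methods=("identity",))
        row = df[df.method == "identity"].iloc[0]
        assert row.skeleton_deviation == pytest.approx(0.0, abs=1e-9)
        assert row.info_extraction_rate == pytest.approx(1.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            run_benchmark(self._tiny_dataset(), methods=("identity", "magic"))

    def test_nrrs_beats_identity(self):
        ds = self._tiny_dataset()
        df = run_benchmark(ds, methods=("identity", "nrrs"))
        s = summarize(df)["methods"]
        assert s["nrrs"]["skeleton_deviation"] < s["identity"]["skeleton_deviation"]
        assert s["nrrs"]["bifurcation_deviation"] < s["identity"]["bifurcation_deviation"]
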