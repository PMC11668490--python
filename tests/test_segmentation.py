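"""Per-slice segmentation, z-linking, path length and admission filters."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from flsquant import SceneParams, generate_stack
from flsquant.segmentation import (
    FilterCriteria,
    FLSPath,
    SliceComponent,
    ThresholdConfig,
    detect_fls,
    filter_fls,
    link_components,
    path_length,
    segment_slice,
)
from flsquant.stack import VoxelStack

from conftest import make_stub_path

PS = 0.16  # µm, pixel size used by array-constructed stacks


def _stack_from_slices(slices, pixel_size=PS, z_spacing=1.0):
    arr = np.stack(slices)[None].astype(float)
    return VoxelStack(arr, pixel_size, z_spacing, ("actin",))


class TestSegmentSlice:
    def test_blank_slice_gives_no_components(self, fixed_threshold):
        stack = _stack_from_slices([np.zeros((40, 40))])
        assert segment_slice(stack, "actin", 0, fixed_threshold) == []

    def test_two_squares_pixel_arithmetic(self, fixed_threshold):
        img = np.zeros((40, 40))
        img[5:10, 5:10] = 1000.0
        img[25:30, 28:33] = 1000.0
        stack = _stack_from_slices([img])
        comps = segment_slice(stack, "actin", 0, fixed_threshold)
        assert len(comps) == 2
        for c in comps:
            assert c.area == pytest.approx(25 * PS**2)  # 0.64 µm²
            assert c.perimeter == pytest.approx(20 * PS)  # crack length
            assert c.circularity == pytest.approx(np.pi / 4)

    def test_noisy_single_fls_centroid_within_one_pixel(self, single_fls_scene):
        import dataclasses

        scene = dataclasses.replace(single_fls_scene, noise_sd=100.0, seed=8)
        stack, truth = generate_stack(scene)
        comps = segment_slice(stack, "actin", 5)  # default MAD threshold
        assert len(comps) == 1
        got = np.array(comps[0].centroid)
        want = truth.fls[["base_x_um", "base_y_um"]].to_numpy()[0]
        assert np.hypot(*(got - want)) <= scene.pixel_size_xy

    def test_unknown_channel_and_method_raise(self, single_fls):
        stack, _ = single_fls
        with pytest.raises(KeyError):
            segment_slice(stack, "nope", 0)
        with pytest.raises(ValueError):
            segment_slice(stack, "actin", 0, ThresholdConfig(method="magic"))


class TestLinking:
    def test_single_vertical_fls_one_path(self, single_fls, fixed_threshold):
        stack, truth = single_fls
        layers = [segment_slice(stack, "actin", z, fixed_threshold)
                  for z in range(stack.n_slices)]
        paths = link_components(layers, z_spacing=1.0)
        assert len(paths) == 1
        assert paths[0].n_slices == 11  # z = 0..10 for a 10 µm structure

    def test_two_parallel_fls_no_cross_linking(self):
        scene = SceneParams(n_fls=2, field_xy=26.0, min_separation=10.0,
                            tilt_max=0.0, noise_sd=0.0, z_depth=20.0, seed=12)
        stack, truth = generate_stack(scene)
        paths = detect_fls(stack, "actin",
                           ThresholdConfig(method="fixed", value=300.0,
                                           smooth_sigma_px=0.0))
        assert len(paths) == 2
        d = cdist(truth.fls[["base_x_um", "base_y_um"]].to_numpy(),
                  np.array([p.base_centroid for p in paths]))
        assert d.min(axis=1).max() <= scene.pixel_size_xy

    def test_equal_overlap_tie_goes_to_larger_top_component(self):
        def comp(z, pixels, area):
            return SliceComponent(z=z, centroid=(0.0, 0.0), area=area,
                                  perimeter=4.0, mean_intensity=1.0,
                                  pixels=np.asarray(pixels))

        big = comp(0, [0, 1, 2, 3, 10, 11], area=6.0)
        small = comp(0, [100, 101, 102, 110], area=4.0)
        # overlaps both tops by exactly 2 pixels
        straddler = comp(1, [10, 11, 100, 101], area=4.0)
        paths = link_components([[big, small], [straddler]], z_spacing=1.0)
        assert paths[0].n_slices == 2  # joined the larger top
        assert paths[1].n_slices == 1

    def test_missing_slice_terminates_path(self):
        def comp(z):
            return SliceComponent(z=z, centroid=(0.0, 0.0), area=1.0,
                                  perimeter=4.0, mean_intensity=1.0,
                                  pixels=np.arange(4))

        paths = link_components([[comp(0)], [], [comp(2)]], z_spacing=1.0)
        assert len(paths) == 1
        assert paths[0].n_slices == 1  # the z=2 component is discarded

    def test_agrees_with_exhaustive_max_overlap_oracle(self):
        # on small separable stacks greedy linking attains the maximum
        # total overlap an exhaustive per-layer assignment can reach
        from itertools import permutations

        def oracle_best(layers):
            def layer_gain(tops, comps):
                best = 0
                idx = list(range(len(tops)))
                for k in range(min(len(tops), len(comps)) + 1):
                    for perm in permutations(idx, k):
                        for sel in permutations(range(len(comps)), k):
                            gain = sum(
                                len(np.intersect1d(tops[p].pixels,
                                                   comps[c].pixels))
                                for p, c in zip(perm, sel)
                            )
                            best = max(best, gain)
                return best

            total = 0
            tops = layers[0]
            for layer in layers[1:]:
                total += layer_gain(tops, layer)
                tops = layer  # upper bound on continuation, fine for oracle
            return total

        rng = np.random.default_rng(0)
        for trial in range(5):
            img = np.zeros((8, 24, 24))
            n = rng.integers(1, 4)
            cols = rng.choice(np.arange(3, 21, 7), size=n, replace=False)
            for c in cols:
                h = rng.integers(3, 8)
                img[:h, 8:12, c:c + 3] = 1000.0
            stack = VoxelStack(img[None], PS, 1.0, ("actin",))
            cfg = ThresholdConfig(method="fixed", value=500.0,
                                  smooth_sigma_px=0.0, min_size_px=1)
            layers = [segment_slice(stack, "actin", z, cfg) for z in range(8)]
            paths = link_components(layers, z_spacing=1.0)
            greedy_total = sum(
                len(np.intersect1d(a.pixels, b.pixels))
                for p in paths
                for a, b in zip(p.components, p.components[1:])
            )
            assert greedy_total == oracle_best(layers)
            assert len(paths) == n


class TestPathLength:
    def _aligned_path(self, n, dx=0.0, z_spacing=1.0):
        comps = [
            SliceComponent(z=k, centroid=(k * dx, 0.0), area=1.0,
                           perimeter=4.0, mean_intensity=1.0)
            for k in range(n)
        ]
        return FLSPath(components=comps, z_spacing=z_spacing)

    def test_vertical_line(self):
        assert path_length(self._aligned_path(11)) == pytest.approx(10.0)

    def test_slanted_line_closed_form(self):
        # 0.5 µm lateral step per 1 µm slice: 10·sqrt(1.25)
        p = self._aligned_path(11, dx=0.5)
        assert path_length(p) == pytest.approx(10 * np.sqrt(1.25))

    def test_single_component_has_zero_length(self):
        assert path_length(self._aligned_path(1)) == 0.0

    def test_tilted_synthetic_recovery(self):
        scene = SceneParams(n_fls=1, field_xy=28.0, z_depth=25.0,
                            min_length=15.0, length_rate=1e6,
                            tilt_max=15.0, noise_sd=0.0, seed=21)
        stack, truth = generate_stack(scene)
        paths = detect_fls(stack, "actin",
                           ThresholdConfig(method="fixed", value=300.0,
                                           smooth_sigma_px=0.0))
        assert len(paths) == 1
        true_len = truth.fls["length_um"].iloc[0]
        assert abs(paths[0].path_length - true_len) <= max(1.0, 0.05 * true_len)


class TestFilters:
    def test_boundary_decisions(self):
        crit = FilterCriteria()
        assert filter_fls([make_stub_path(2.9)], crit) == []
        assert len(filter_fls([make_stub_path(3.0)], crit)) == 1
        assert filter_fls([make_stub_path(5.0, base_area=21.0)], crit) == []
        square = make_stub_path(5.0, base_circularity=np.pi / 4)
        assert len(filter_fls([square], crit)) == 1

    def test_monotone_in_criteria(self):
        rng = np.random.default_rng(1)
        paths = [
            make_stub_path(rng.uniform(1, 12), base_area=rng.uniform(1, 30),
                           base_circularity=rng.uniform(0.2, 1.0))
            for _ in range(60)
        ]
        counts = [
            len(filter_fls(paths, FilterCriteria(min_length=ml)))
            for ml in (2.0, 3.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts = [
            len(filter_fls(paths, FilterCriteria(max_base_area=a)))
            for a in (30.0, 20.0, 10.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_calibration_equivariance(self, small_field):
        # doubling linear calibration doubles lengths, quadruples areas,
        # and preserves decisions under correspondingly scaled criteria
        (stack, truth), scene = small_field
        cfg = ThresholdConfig()
        paths = detect_fls(stack, "actin", cfg, criteria=FilterCriteria(
            1e-6, np.inf, 1e-6))
        doubled = VoxelStack(stack.intensities.copy(), stack.pixel_size_xy * 2,
                             stack.z_spacing * 2, stack.channel_names)
        paths2 = detect_fls(doubled, "actin", cfg, criteria=FilterCriteria(
            1e-6, np.inf, 1e-6))
        assert len(paths) == len(paths2)
        for a, b in zip(paths, paths2):
            assert b.path_length == pytest.approx(2 * a.path_length)
            assert b.base_area == pytest.approx(4 * a.base_area)
        base = FilterCriteria()
        scaled = FilterCriteria(base.min_length * 2, base.max_base_area * 4,
                                base.min_circularity)
        kept = {round(p.base_centroid[0], 3) for p in filter_fls(paths, base)}
        kept2 = {round(p.base_centroid[0] / 2, 3)
                 for p in filter_fls(paths2, scaled)}
        assert kept == kept2
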