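"""Extent statistics, normalized z-profiles and per-FLS intensity profiles."""

import dataclasses

import numpy as np
import pytest

from flsquant import SceneParams, generate_stack
from flsquant.displacement import (
    ExtentProfile,
    actin_extent,
    area_profile,
    extent_ratio,
    fls_intensity_profile,
    normalized_z_profiles,
    probe_extent,
)
from flsquant.segmentation import ThresholdConfig, detect_fls
from flsquant.stack import VoxelStack


def _profile(areas_by_channel, fov_id=""):
    a = {k: np.asarray(v, dtype=float) for k, v in areas_by_channel.items()}
    return ExtentProfile(areas=a, actin_extent=0, probe_extent=0,
                         extent_ratio=1.0, actin_truncated=False,
                         probe_truncated=False, fov_id=fov_id)


class TestExtents:
    def test_actin_extent_first_zero_slice(self):
        assert actin_extent([5, 4, 3, 2, 1, 0, 0]) == (5, False)

    def test_actin_extent_degenerate_field(self):
        assert actin_extent([0, 0, 0]) == (0, False)

    def test_actin_extent_truncated_at_top(self):
        idx, truncated = actin_extent([3, 2, 1])
        assert (idx, truncated) == (3, True)

    def test_probe_extent_half_area_rule(self):
        assert probe_extent([10, 10, 10, 10], [10, 6, 5, 4]).index == 2

    def test_probe_equal_to_actin_reaches_first_zero(self):
        a = [10, 8, 6, 0, 0]
        assert probe_extent(a, a).index == actin_extent(a).index == 3

    def test_probe_never_exceeds_actin_on_noisy_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(3, 40)
            a = rng.uniform(0, 5, n) * (rng.random(n) > 0.2)
            p = rng.uniform(0, 5, n) * (rng.random(n) > 0.2)
            assert probe_extent(a, p).index <= actin_extent(a).index

    def test_area_profile_of_empty_channel(self, fixed_threshold):
        stack = VoxelStack(np.zeros((1, 5, 30, 30)), 0.16, 1.0, ("actin",))
        assert np.all(area_profile(stack, "actin", fixed_threshold) == 0)

    def test_area_profile_pixel_arithmetic(self, fixed_threshold):
        # 4-pixel column through 6 of 8 slices: 4·0.16² = 0.1024 µm²
        arr = np.zeros((1, 8, 30, 30))
        arr[0, :6, 10:12, 10:12] = 1000.0
        stack = VoxelStack(arr, 0.16, 1.0, ("actin",))
        cfg = dataclasses.replace(fixed_threshold, min_size_px=1)
        prof = area_profile(stack, "actin", cfg)
        assert np.allclose(prof[:6], 4 * 0.16**2)
        assert np.all(prof[6:] == 0)

    def test_identical_channels_give_unit_ratio(self, single_fls):
        stack, _ = single_fls
        cfg = ThresholdConfig(method="fixed", value=300.0, smooth_sigma_px=0.0)
        prof = extent_ratio(stack, cfg)
        assert prof.extent_ratio == pytest.approx(1.0)
        assert not prof.actin_truncated

    def test_zero_actin_extent_flagged_invalid(self):
        stack = VoxelStack(np.zeros((2, 4, 20, 20)), 0.16, 1.0,
                           ("actin", "probe"))
        with pytest.warns(UserWarning, match="zero actin extent"):
            prof = extent_ratio(stack, ThresholdConfig(method="fixed",
                                                       value=10.0,
                                                       smooth_sigma_px=0.0))
        assert not prof.valid

    def test_half_truncated_probe_recovers_half_ratio(self):
        # near-uniform 30 µm structures, probe on the lower half
        ratios = []
        for seed in (0, 1, 2):
            scene = SceneParams(n_fls=12, field_xy=40.0, min_length=30.0,
                                length_rate=5.0, z_depth=38.0,
                                probe_fraction=0.5, seed=seed)
            stack, _ = generate_stack(scene)
            ratios.append(extent_ratio(stack).extent_ratio)
        assert abs(np.mean(ratios) - 0.5) < 0.1


class TestNormalizedProfiles:
    def test_normalization_to_first_slice_above_base(self):
        prof = normalized_z_profiles(
            [_profile({"actin": [8, 4, 2, 1], "probe": [8, 4, 2, 1]})]
        )
        assert np.allclose(prof.mean["actin"], [2.0, 1.0, 0.5, 0.25])

    def test_single_field_zero_width_ci(self):
        prof = normalized_z_profiles([_profile({"actin": [4, 2, 1]})])
        assert prof.n_fields == 1
        assert np.allclose(prof.ci_low["actin"], prof.mean["actin"])

    def test_identical_fields_zero_variance_ci(self):
        fields = [_profile({"actin": [8, 4, 2, 1]}) for _ in range(8)]
        prof = normalized_z_profiles(fields)
        assert prof.n_fields == 8
        assert np.allclose(prof.ci_high["actin"] - prof.ci_low["actin"], 0.0)

    def test_zero_reference_field_excluded(self):
        good = _profile({"actin": [8, 4, 2, 1]})
        bad = _profile({"actin": [8, 0, 0, 0]}, fov_id="bad")
        with pytest.warns(UserWarning, match="excluded"):
            prof = normalized_z_profiles([good, bad])
        assert prof.n_fields == 1


class TestIntensityProfiles:
    def test_percentage_arithmetic(self):
        # raw [100, 80, 60] with background 20 -> [100%, 75%, 50%]
        arr = np.zeros((1, 3, 20, 20))
        for z, v in enumerate((100.0, 80.0, 60.0)):
            arr[0, z] = v
        stack = VoxelStack(arr, 0.16, 1.0, ("actin",))
        from conftest import make_stub_path
        from flsquant.segmentation import FLSPath, SliceComponent

        comps = [SliceComponent(z=z, centroid=(1.6, 1.6), area=1.0,
                                perimeter=4.0, mean_intensity=1.0)
                 for z in range(3)]
        path = FLSPath(components=comps, z_spacing=1.0)
        prof = fls_intensity_profile(stack, path, box=5,
                                     background={"actin": 20.0})
        assert np.allclose(prof.percent["actin"], [100.0, 75.0, 50.0])

    def test_constant_structure_flat_profile(self, single_fls):
        stack, _ = single_fls
        cfg = ThresholdConfig(method="fixed", value=300.0, smooth_sigma_px=0.0)
        path = detect_fls(stack, "actin", cfg)[0]
        prof = fls_intensity_profile(stack, path, box=3,
                                     background={"actin": 100.0,
                                                 "probe": 100.0})
        inner = prof.percent["actin"][1:-1]  # ends see axial PSF falloff
        assert np.all(np.abs(inner - 100.0) < 15.0)

    def test_probe_profile_drops_at_truncation_plane(self):
        scene = SceneParams(n_fls=1, field_xy=14.0, min_length=20.0,
                            length_rate=1e6, z_depth=24.0, tilt_max=0.0,
                            probe_fraction=0.5, noise_sd=0.0, seed=3)
        stack, truth = generate_stack(scene)
        cfg = ThresholdConfig(method="fixed", value=300.0, smooth_sigma_px=0.0)
        path = detect_fls(stack, "actin", cfg)[0]
        prof = fls_intensity_profile(stack, path, box=3,
                                     background={"actin": 100.0,
                                                 "probe": 100.0})
        cut = int(0.5 * truth.fls["length_um"].iloc[0])  # slices above base
        actin, probe = prof.percent["actin"], prof.percent["probe"]
        assert np.all(probe[cut + 2:] < 50.0)
        assert np.all(probe[: cut - 1] > 80.0)
        assert np.all(actin[: -2] > 80.0)

    def test_base_at_background_flagged(self):
        arr = np.full((1, 3, 20, 20), 50.0)
        stack = VoxelStack(arr, 0.16, 1.0, ("actin",))
        from flsquant.segmentation import FLSPath, SliceComponent

        comps = [SliceComponent(z=z, centroid=(1.6, 1.6), area=1.0,
                                perimeter=4.0, mean_intensity=1.0)
                 for z in range(3)]
        path = FLSPath(components=comps, z_spacing=1.0)
        with pytest.warns(UserWarning, match="invalid"):
            prof = fls_intensity_profile(stack, path,
                                         background={"actin": 50.0})
        assert not prof.valid
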