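"""Shared fixtures: small synthetic stacks and component builders."""

from __future__ import annotations

import numpy as np
import pytest

from flsquant import SceneParams, generate_stack
from flsquant.segmentation import FLSPath, SliceComponent, ThresholdConfig


@pytest.fixture(scope="session")
def fixed_threshold() -> ThresholdConfig:
    """Raw-pixel fixed threshold for arithmetic-exact assertions."""
    return ThresholdConfig(method="fixed", value=300.0, smooth_sigma_px=0.0)


@pytest.fixture(scope="session")
def single_fls_scene() -> SceneParams:
    """One vertical 10 µm structure, noise-free, fully probe-decorated."""
    return SceneParams(
        n_fls=1,
        min_length=10.0,
        length_rate=1e6,  # essentially exact 10 µm
        tilt_max=0.0,
        probe_fraction=1.0,
        noise_sd=0.0,
        background_level=100.0,
        field_xy=12.0,
        z_depth=12.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def single_fls(single_fls_scene):
    return generate_stack(single_fls_scene)


@pytest.fixture(scope="session")
def small_field():
    """A modest noisy field reused by segmentation/displacement tests."""
    scene = SceneParams(n_fls=8, field_xy=30.0, z_depth=25.0, seed=3)
    return generate_stack(scene), scene


def make_stub_path(
    length: float,
    base: tuple[float, float] = (0.0, 0.0),
    base_area: float = 3.0,
    base_circularity: float = 0.785,
    fov_id: str = "",
) -> FLSPath:
    """A two-component path with prescribed summary statistics.

    The two aligned components are ``length`` apart in z, so the path
    length, base area and base circularity take exactly the requested
    values — handy for exercising filters and tracking without imagery.
    """
    perimeter = float(np.sqrt(4 * np.pi * base_area / base_circularity))
    # counteract sqrt/square rounding so the stored circularity is not a
    # hair below the requested value at criterion boundaries
    for _ in range(4):
        if 4 * np.pi * base_area / perimeter**2 >= base_circularity:
            break
        perimeter = float(np.nextafter(perimeter, 0.0))
    comps = [
        SliceComponent(z=k, centroid=base, area=base_area, perimeter=perimeter,
                       mean_intensity=1.0)
        for k in (0, 1)
    ]
    return FLSPath(components=comps, z_spacing=length, fov_id=fov_id)
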