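"""FLS detection in calibrated z-stacks.

Detection works slice by slice from the base plane upward: each z-slice is
binarized, connected components are measured (8-connectivity in plane),
and components are linked across consecutive slices into candidate paths.
A path's length is the cumulative 3-D distance through its per-slice
centroids.  Candidates are then admitted as FLS by the standard criteria:
path length at least 3 µm, base area at most 20 µm², and base circularity
at least half that of a circle.

Circularity is 4πA/P² with the perimeter measured as pixel-boundary crack
length (the count of exposed pixel edges times the pixel size); a square
region scores π/4 ≈ 0.785.

Linking is greedy and gap-free: a component at z+1 joins the path whose
top component it overlaps most (falling back to the nearest top centroid
within ``max_step_xy``), ties going to the larger top component and then
to the earlier-seeded path; a slice with no admissible continuation
terminates the path.  Components above the base slice that never join a
path are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist
from skimage import filters, measure, morphology

from .stack import VoxelStack

__all__ = [
    "ThresholdConfig",
    "SliceComponent",
    "FLSPath",
    "FilterCriteria",
    "binarize_slice",
    "segment_slice",
    "link_components",
    "path_length",
    "filter_fls",
    "filter_report",
    "detect_fls",
    "paths_to_frame",
]


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdConfig:
    """How a slice is binarized before component analysis.

    ``mad``: background median + k robust standard deviations
    (1.4826 × median absolute deviation) — robust when structures occupy a
    small fraction of the slice.  ``otsu``: Otsu's threshold.  ``fixed``:
    an explicit intensity value.  Components smaller than ``min_size_px``
    pixels are discarded, which also removes isolated noise pixels from
    area profiles.

    ``smooth_sigma_px`` applies a light Gaussian filter to the slice
    before the threshold is computed and applied; it suppresses
    pixel-scale boundary jitter that would otherwise inflate crack-length
    perimeters.  Set to 0 to threshold the raw image.
    """

    method: str = "mad"
    k: float = 3.0
    value: float | None = None
    min_size_px: int = 4
    smooth_sigma_px: float = 0.7

    def validate(self) -> None:
        if self.method not in ("mad", "otsu", "fixed"):
            raise ValueError(
                f"unknown threshold method {self.method!r}; "
                "choose 'mad', 'otsu' or 'fixed'"
            )
        if self.method == "fixed" and self.value is None:
            raise ValueError("fixed thresholding needs an explicit value")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be at least 1")


def threshold_value(image: np.ndarray, cfg: ThresholdConfig) -> float:
    cfg.validate()
    if cfg.method == "fixed":
        return float(cfg.value)
    if cfg.method == "otsu":
        return float(filters.threshold_otsu(image))
    med = float(np.median(image))
    sigma = 1.4826 * float(np.median(np.abs(image - med)))
    return med + cfg.k * sigma


def binarize_slice(image: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Above-threshold mask with sub-minimum components removed."""
    if cfg.smooth_sigma_px > 0:
        image = gaussian_filter(np.asarray(image, dtype=float),
                                cfg.smooth_sigma_px)
    mask = image > threshold_value(image, cfg)
    if cfg.min_size_px > 1:
        # drop components with fewer than min_size_px pixels
        mask = morphology.remove_small_objects(
            mask, max_size=cfg.min_size_px - 1, connectivity=2
        )
    return mask


# ---------------------------------------------------------------------------
# components and paths
# ---------------------------------------------------------------------------


@dataclass
class SliceComponent:
    """One connected blob in one z-slice, geometry in µm."""

    z: int
    centroid: tuple[float, float]  # (x, y) µm
    area: float  # µm²
    perimeter: float  # µm, crack length
    mean_intensity: float
    pixels: np.ndarray | None = None  # sorted flat indices into the slice

    @property
    def circularity(self) -> float:
        return 4.0 * np.pi * self.area / self.perimeter**2


@dataclass
class FLSPath:
    """An ordered chain of components from the base slice upward."""

    components: list[SliceComponent]
    z_spacing: float  # µm
    fov_id: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a path needs at least one component")
        zs = [c.z for c in self.components]
        if any(b - a != 1 for a, b in zip(zs, zs[1:])):
            raise ValueError("component z indices must increase by exactly 1")

    @property
    def base(self) -> SliceComponent:
        return self.components[0]

    @property
    def base_area(self) -> float:
        return self.base.area

    @property
    def base_circularity(self) -> float:
        return self.base.circularity

    @property
    def base_centroid(self) -> tuple[float, float]:
        return self.base.centroid

    @property
    def n_slices(self) -> int:
        return len(self.components)

    @property
    def path_length(self) -> float:
        return path_length(self)


def _crack_perimeter(region_mask: np.ndarray) -> int:
    """Count of exposed pixel edges of a binary region."""
    padded = np.pad(region_mask, 1)
    edges = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        edges += int(np.sum(padded & ~np.roll(padded, shift, axis=(0, 1))))
    return edges


def segment_slice(
    stack: VoxelStack,
    channel: str | int,
    z: int,
    threshold_cfg: ThresholdConfig | None = None,
) -> list[SliceComponent]:
    """Connected components of the above-threshold pixels in one slice."""
    cfg = threshold_cfg or ThresholdConfig()
    image = stack.slice(channel, z).astype(np.float64)
    mask = binarize_slice(image, cfg)
    labels = measure.label(mask, connectivity=2)
    ps = stack.pixel_size_xy
    comps: list[SliceComponent] = []
    for rp in measure.regionprops(labels, intensity_image=image):
        cy, cx = rp.centroid  # (row, col) pixel units
        rows, cols = np.nonzero(rp.image)
        flat = np.sort(
            (rows + rp.bbox[0]) * image.shape[1] + (cols + rp.bbox[1])
        )
        comps.append(
            SliceComponent(
                z=z,
                centroid=(cx * ps, cy * ps),
                area=rp.area * ps**2,
                perimeter=_crack_perimeter(rp.image) * ps,
                mean_intensity=float(rp.intensity_mean),
                pixels=flat,
            )
        )
    return comps


def _overlap(a: SliceComponent, b: SliceComponent) -> int:
    if a.pixels is None or b.pixels is None:
        return 0
    return len(np.intersect1d(a.pixels, b.pixels, assume_unique=True))


def link_components(
    per_slice_components: list[list[SliceComponent]],
    z_spacing: float = 1.0,
    max_step_xy: float = 1.0,
    fov_id: str = "",
) -> list[FLSPath]:
    """Greedy upward linking of per-slice components into paths.

    ``per_slice_components[0]`` must hold the base-slice components; each
    of them seeds a path.  See the module docstring for the linking and
    tie-break rules.  ``max_step_xy`` (µm) bounds the centroid fallback
    when a candidate has no pixel overlap with any open path.
    """
    if not per_slice_components or not per_slice_components[0]:
        return []
    paths = [
        FLSPath(components=[c], z_spacing=z_spacing, fov_id=fov_id)
        for c in per_slice_components[0]
    ]
    active = list(range(len(paths)))

    for layer in per_slice_components[1:]:
        if not active or not layer:
            active = []
            break
        tops = {pi: paths[pi].components[-1] for pi in active}
        # candidate (component, path) pairs ranked by overlap
        cand = []
        for ci, comp in enumerate(layer):
            for pi in active:
                ov = _overlap(comp, tops[pi])
                if ov > 0:
                    cand.append((ov, tops[pi].area, pi, ci))
        # larger overlap first; ties -> larger top area, then earlier path
        cand.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
        assigned_comp: set[int] = set()
        extended: dict[int, int] = {}  # path index -> component index
        claimed = {pi: 0 for pi in active}
        for ov, _, pi, ci in cand:
            claimed[pi] += 1
            if ci in assigned_comp or pi in extended:
                continue
            extended[pi] = ci
            assigned_comp.add(ci)
        # fallback: nearest top centroid within max_step_xy
        open_paths = [pi for pi in active if pi not in extended]
        loose = [ci for ci in range(len(layer)) if ci not in assigned_comp]
        if open_paths and loose:
            pc = np.array([tops[pi].centroid for pi in open_paths])
            cc = np.array([layer[ci].centroid for ci in loose])
            dist = cdist(cc, pc)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                               dist.shape))[0]
            used_p: set[int] = set()
            used_c: set[int] = set()
            for ri, pj in order:
                if dist[ri, pj] > max_step_xy:
                    break
                ci, pi = loose[ri], open_paths[pj]
                if ci in used_c or pi in used_p:
                    continue
                extended[pi] = ci
                used_c.add(ci)
                used_p.add(pi)
        for pi, ci in extended.items():
            paths[pi].components.append(layer[ci])
            if claimed.get(pi, 0) > 1:
                paths[pi].flags.add("branch")
        active = sorted(extended)
    return paths


def path_length(path: FLSPath) -> float:
    """Cumulative 3-D distance through consecutive component centroids (µm).

    A single-component path has length 0.
    """
    total = 0.0
    for a, b in zip(path.components, path.components[1:]):
        dx = b.centroid[0] - a.centroid[0]
        dy = b.centroid[1] - a.centroid[1]
        total += float(np.sqrt(dx * dx + dy * dy + path.z_spacing**2))
    return total


# ---------------------------------------------------------------------------
# admission filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterCriteria:
    """Admission criteria defining what counts as an FLS."""

    min_length: float = 3.0  # µm
    max_base_area: float = 20.0  # µm²
    min_circularity: float = 0.5  # relative to a perfect circle

    def validate(self) -> None:
        if self.min_length <= 0 or self.max_base_area <= 0:
            raise ValueError("criteria must be positive")
        if not (0 < self.min_circularity <= 1):
            raise ValueError("min_circularity must be in (0, 1]")


def _reject_reason(path: FLSPath, criteria: FilterCriteria) -> str:
    reasons = []
    if path.path_length < criteria.min_length:
        reasons.append("short")
    if path.base_area > criteria.max_base_area:
        reasons.append("base_area")
    if path.base_circularity < criteria.min_circularity:
        reasons.append("circularity")
    return "+".join(reasons)


def filter_fls(
    paths: list[FLSPath], criteria: FilterCriteria | None = None
) -> list[FLSPath]:
    """Keep the paths that satisfy all admission criteria, in order."""
    crit = criteria or FilterCriteria()
    crit.validate()
    return [p for p in paths if not _reject_reason(p, crit)]


def filter_report(
    paths: list[FLSPath], criteria: FilterCriteria | None = None
):
    """Per-path accept/reject table (pandas DataFrame)."""
    import pandas as pd

    crit = criteria or FilterCriteria()
    crit.validate()
    rows = []
    for i, p in enumerate(paths):
        reason = _reject_reason(p, crit)
        rows.append(
            {
                "fov_id": p.fov_id,
                "fls_id": i,
                "base_x_um": p.base_centroid[0],
                "base_y_um": p.base_centroid[1],
                "length_um": p.path_length,
                "base_area_um2": p.base_area,
                "base_circularity": p.base_circularity,
                "n_slices": p.n_slices,
                "accepted": reason == "",
                "reject_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def paths_to_frame(paths: list[FLSPath]):
    """Accepted-path geometry as a tidy table."""
    return filter_report(paths, FilterCriteria(1e-9, np.inf, 1e-9)).drop(
        columns=["accepted", "reject_reason"]
    )


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------


def detect_fls(
    stack: VoxelStack,
    channel: str | int = "actin",
    threshold_cfg: ThresholdConfig | None = None,
    criteria: FilterCriteria | None = None,
    max_step_xy: float = 1.0,
    fov_id: str = "",
) -> list[FLSPath]:
    """Segment, link and filter FLS in one channel of a stack.

    Slices are processed from ``stack.base_slice`` to the top.  Pass
    ``criteria=None`` for the standard admission filters; pass a
    permissive :class:`FilterCriteria` to inspect raw candidates.
    """
    cfg = threshold_cfg or ThresholdConfig()
    layers = [
        segment_slice(stack, channel, z, cfg)
        for z in range(stack.base_slice, stack.n_slices)
    ]
    paths = link_components(
        layers, z_spacing=stack.z_spacing, max_step_xy=max_step_xy, fov_id=fov_id
    )
    return filter_fls(paths, criteria or FilterCriteria())
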