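"""Synthetic FLS fields with known ground truth.

Filopodia-like structures (FLS) are fascin-bundled parallel actin bundles
that grow upward from a supported lipid bilayer.  This module renders
fields of such structures as two-channel confocal z-stacks whose
statistical structure matches what the measurement pipeline assumes:

* FLS lengths follow a shifted exponential above the 3 µm detection
  threshold (the steady-state length law of unperturbed fields), with an
  optional two-component mixture emulating perturbations that inflate the
  long tail;
* the probe channel (e.g. GFP-UtrCH / LifeAct) shares each structure's
  geometry but is truncated at ``probe_fraction`` of its length, emulating
  displacement of the probe from the older part of the bundle;
* time-lapse sequences evolve each length by a two-state growth/shrinkage
  telegraph process at filopodial rates (~1–2 µm/min), with optional
  photobleaching that dims pre-existing material while newly added length
  renders at full intensity.

Image formation is deliberately simple: constant-intensity cylinders of
radius ``fls_radius`` blurred by a separable anisotropic Gaussian PSF, on
a uniform background with additive Gaussian noise (optionally Poisson
shot noise).  Every rendered structure has exactly one ground-truth
record, so recovery of counts, lengths, extents and rates can be tested
without real microscopy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import VoxelStack

__all__ = [
    "SceneParams",
    "DynamicsParams",
    "GroundTruth",
    "sample_lengths",
    "generate_stack",
    "simulate_trajectories",
    "generate_timelapse",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and noise of one synthetic field of view.

    Lengths and positions are in µm, intensities in arbitrary units.
    Defaults describe a separable steady-state field: ~50 structures in a
    60×60 µm field, shifted-exponential lengths with mean 3 + 1/0.25 =
    7 µm, imaged at 1 µm z-steps over a 30 µm stack with 0.16 µm pixels
    (16 µm camera pixel / 100× objective).  Structures render as
    constant-intensity tapered cylinders: a ``base_radius`` membrane
    attachment narrowing to the ``fls_radius`` shaft over ``base_taper``
    µm, so measured base areas fall on the µm² scale of real fields.
    """

    n_fls: int = 50
    poisson_n: bool = False  # draw the count as Poisson(n_fls)
    length_rate: float = 0.25  # 1/µm, exponential rate above min_length
    min_length: float = 3.0  # µm, detection threshold of the FLS definition
    heavy_tail_mix: float = 0.0  # fraction drawn from the secondary rate
    heavy_tail_rate: float = 0.05  # 1/µm, emulates the "lengthened" condition
    tilt_max: float = 8.0  # degrees from the z axis
    probe_fraction: float = 1.0  # fraction of each length carrying probe
    min_separation: float = 4.0  # µm between base points
    fls_radius: float = 0.35  # µm, rendered shaft radius
    base_radius: float = 1.5  # µm, rendered radius of the membrane attachment
    base_taper: float = 2.0  # µm over which the base flares into the shaft
    fls_intensity: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 100.0  # additive Gaussian, a.u.
    shot_noise: bool = False
    psf_sigma_xy: float = 0.1  # µm
    psf_sigma_z: float = 0.3  # µm
    field_xy: float = 60.0  # µm
    z_depth: float = 30.0  # µm
    pixel_size_xy: float = 0.16  # µm
    z_spacing: float = 1.0  # µm
    edge_margin: float = 3.0  # µm kept clear of the lateral field border
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.probe_fraction <= 1.0):
            raise ValueError("probe_fraction must be in (0, 1]")
        if self.length_rate <= 0 or self.heavy_tail_rate <= 0:
            raise ValueError("length rates must be positive")
        if self.min_length < 0:
            raise ValueError("min_length must be non-negative")
        if not (0.0 <= self.heavy_tail_mix <= 1.0):
            raise ValueError("heavy_tail_mix must be in [0, 1]")
        if min(self.field_xy, self.z_depth, self.pixel_size_xy, self.z_spacing) <= 0:
            raise ValueError("geometric parameters must be positive")
        if self.z_depth < self.min_length:
            raise ValueError(
                f"z_depth {self.z_depth} µm cannot hold structures of at least "
                f"{self.min_length} µm"
            )
        if not (0.0 <= self.tilt_max < 90.0):
            raise ValueError("tilt_max must be in [0, 90) degrees")
        if self.n_fls < 0:
            raise ValueError("n_fls must be non-negative")
        if self.fls_radius <= 0 or self.psf_sigma_xy < 0 or self.psf_sigma_z < 0:
            raise ValueError("rendering parameters out of range")
        if self.base_radius < self.fls_radius or self.base_taper < 0:
            raise ValueError("base_radius must be >= fls_radius and taper >= 0")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters out of range")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(Z, Y, X) voxel grid covering the field."""
        nxy = int(round(self.field_xy / self.pixel_size_xy))
        nz = int(round(self.z_depth / self.z_spacing)) + 1
        return nz, nxy, nxy


@dataclass(frozen=True)
class DynamicsParams:
    """Growth/shrinkage dynamics of a time-lapse sequence.

    Rates are per minute; ``frame_interval`` is in seconds (20 s default,
    matching a 10 min time course imaged every 20 s).  The length of each
    structure follows a telegraph process: it grows at ``growth_rate``
    until a catastrophe switches it to shrinking at ``shrink_rate``, until
    a rescue switches it back.  A structure whose length reaches zero
    disappears.  ``bleach_frame`` emulates photobleaching of the whole
    field: material present at that frame renders at ``bleach_survival``
    of its intensity thereafter, while newly added length is bright.
    """

    growth_rate: float = 1.5  # µm/min
    shrink_rate: float = 1.5  # µm/min
    catastrophe_rate: float = 0.0  # per min, growing -> shrinking
    rescue_rate: float = 0.0  # per min, shrinking -> growing
    nucleation_rate: float = 0.0  # new FLS per field per min
    frame_interval: float = 20.0  # s
    n_frames: int = 30
    bleach_frame: int | None = None
    bleach_survival: float = 0.1
    initial_length: float | None = None  # µm; None -> draw from the scene law

    def validate(self) -> None:
        for name in ("growth_rate", "shrink_rate", "catastrophe_rate",
                     "rescue_rate", "nucleation_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("a time lapse needs at least 2 frames")
        if not (0.0 <= self.bleach_survival < 1.0):
            raise ValueError("bleach_survival must be in [0, 1)")
        if self.bleach_frame is not None and not (
            0 <= self.bleach_frame < self.n_frames
        ):
            raise ValueError("bleach_frame outside the frame range")


@dataclass
class GroundTruth:
    """True per-structure geometry (and trajectories, for time lapses)."""

    fls: pd.DataFrame
    params: dict = field(default_factory=dict)
    trajectories: pd.DataFrame | None = None

    @property
    def n_fls(self) -> int:
        return len(self.fls)

    def to_csv(self, path) -> None:
        self.fls.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_lengths(
    rng: np.random.Generator,
    n: int,
    rate: float,
    min_length: float,
    heavy_tail_mix: float = 0.0,
    heavy_tail_rate: float = 0.05,
) -> np.ndarray:
    """Draw lengths from a (possibly two-component) shifted exponential.

    Each length is ``min_length + Exp(rate)``; with probability
    ``heavy_tail_mix`` the secondary, smaller rate is used instead, which
    fattens the tail the way length-perturbing treatments do.
    """
    scale = np.full(n, 1.0 / rate)
    if heavy_tail_mix > 0:
        heavy = rng.random(n) < heavy_tail_mix
        scale[heavy] = 1.0 / heavy_tail_rate
    return min_length + rng.exponential(scale)


def _sample_bases(
    rng: np.random.Generator,
    n: int,
    field_xy: float,
    margin: float,
    min_separation: float,
    existing: np.ndarray | None = None,
    max_attempts: int = 200_000,
) -> np.ndarray:
    """Dart-throwing placement of base points with a minimum separation."""
    lo, hi = margin, field_xy - margin
    if hi <= lo:
        raise ValueError("edge margin leaves no room for base points")
    placed: list[np.ndarray] = [] if existing is None else [p for p in existing]
    target = len(placed) + n
    attempts = 0
    while len(placed) < target:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} bases with separation {min_separation} µm "
                f"in a {field_xy} µm field"
            )
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= min_separation for p in placed):
            placed.append(cand)
    out = np.array(placed[-n:]) if n else np.empty((0, 2))
    return out


def _sample_directions(rng: np.random.Generator, n: int, tilt_max_deg: float):
    """Unit direction vectors tilted uniformly within tilt_max of +z."""
    tilt = np.deg2rad(rng.uniform(0.0, tilt_max_deg, n))
    azim = rng.uniform(0.0, 2 * np.pi, n)
    return (
        np.column_stack(
            [np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)]
        ),
        np.rad2deg(tilt),
        np.rad2deg(azim),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _radius_profile(params: SceneParams):
    """Bundle radius as a function of arc length from the base.

    The membrane attachment is rendered wider (``base_radius``) and
    tapers linearly into the shaft radius over ``base_taper`` µm, so the
    measured base areas are on the µm² scale seen in real fields.
    """
    r0, r1, taper = params.base_radius, params.fls_radius, params.base_taper

    def radius_at(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if taper <= 0:
            return np.where(t <= 0, r0, r1)
        frac = np.clip(t / taper, 0.0, 1.0)
        return r0 + (r1 - r0) * frac

    return radius_at


def _rasterize(
    shape_zyx: tuple[int, int, int],
    segments: list[tuple[float, float, np.ndarray, float, float]],
    pixel_size_xy: float,
    z_spacing: float,
    radius_fn,
) -> np.ndarray:
    """Boolean occupancy of tapered-cylinder segments.

    ``segments`` holds (base_x, base_y, direction, t0, t1) with t the arc
    length in µm along the direction vector.  Each sampled centreline
    point paints the in-plane disc of pixels whose centres lie within
    ``radius_fn(t)``; the nearest pixel is always painted so that thin
    structures never vanish.
    """
    occ = np.zeros(shape_zyx, dtype=bool)
    step = min(pixel_size_xy, z_spacing) / 3.0
    pts = []
    arcs = []
    for bx, by, d, t0, t1 in segments:
        if t1 <= t0:
            continue
        n = max(2, int(math.ceil((t1 - t0) / step)) + 1)
        t = np.linspace(t0, t1, n)
        pts.append(
            np.column_stack([t * d[2], by + t * d[1], bx + t * d[0]])
        )  # (z, y, x) µm
        arcs.append(t)
    if not pts:
        return occ
    pzyx = np.concatenate(pts)
    radius = np.asarray(radius_fn(np.concatenate(arcs)), dtype=float)
    zi = np.rint(pzyx[:, 0] / z_spacing).astype(np.int64)
    inz = (zi >= 0) & (zi < shape_zyx[0])
    pzyx, zi, radius = pzyx[inz], zi[inz], radius[inz]
    if not len(pzyx):
        return occ

    w = max(0, int(math.ceil(radius.max() / pixel_size_xy)))
    oy, ox = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    offs_y, offs_x = oy.ravel(), ox.ravel()

    ypix = pzyx[:, 1] / pixel_size_xy
    xpix = pzyx[:, 2] / pixel_size_xy
    cy = np.rint(ypix).astype(np.int64)[:, None] + offs_y[None, :]
    cx = np.rint(xpix).astype(np.int64)[:, None] + offs_x[None, :]
    dy = cy - ypix[:, None]
    dx = cx - xpix[:, None]
    within = (dy * dy + dx * dx) * pixel_size_xy**2 <= (radius**2)[:, None]
    within |= (offs_y == 0)[None, :] & (offs_x == 0)[None, :]  # nearest pixel
    inb = (cy >= 0) & (cy < shape_zyx[1]) & (cx >= 0) & (cx < shape_zyx[2])
    sel = within & inb
    zz = np.broadcast_to(zi[:, None], cy.shape)[sel]
    occ[zz, cy[sel], cx[sel]] = True
    return occ


def _render_channel(
    occ_full: np.ndarray,
    params: SceneParams,
    rng: np.random.Generator,
    occ_dim: np.ndarray | None = None,
    dim_scale: float = 1.0,
) -> np.ndarray:
    """PSF blur + background + noise on top of occupancy masks."""
    signal = occ_full.astype(np.float64)
    if occ_dim is not None:
        signal = np.maximum(signal, dim_scale * occ_dim)
    signal *= params.fls_intensity
    sigma = (
        params.psf_sigma_z / params.z_spacing,
        params.psf_sigma_xy / params.pixel_size_xy,
        params.psf_sigma_xy / params.pixel_size_xy,
    )
    if any(s > 0 for s in sigma):
        signal = gaussian_filter(signal, sigma=sigma, mode="constant")
    img = signal + params.background_level
    if params.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return img


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_stack(params: SceneParams) -> tuple[VoxelStack, GroundTruth]:
    """Render one two-channel (actin, probe) field with ground truth.

    The probe channel shares the actin geometry truncated at
    ``probe_fraction`` of each structure's length, measured from the base.
    Identical ``params`` (including the seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(rng.poisson(params.n_fls)) if params.poisson_n else params.n_fls

    bases = _sample_bases(
        rng, n, params.field_xy, params.edge_margin, params.min_separation
    )
    lengths = sample_lengths(
        rng,
        n,
        params.length_rate,
        params.min_length,
        params.heavy_tail_mix,
        params.heavy_tail_rate,
    )
    dirs, tilt_deg, azim_deg = _sample_directions(rng, n, params.tilt_max)

    truth = pd.DataFrame(
        {
            "fls_id": np.arange(n),
            "base_x_um": bases[:, 0] if n else np.array([]),
            "base_y_um": bases[:, 1] if n else np.array([]),
            "tilt_deg": tilt_deg,
            "azimuth_deg": azim_deg,
            "length_um": lengths,
            "probe_fraction": np.full(n, params.probe_fraction),
        }
    )

    shape = params.grid_shape
    actin_segs = [
        (bases[i, 0], bases[i, 1], dirs[i], 0.0, lengths[i]) for i in range(n)
    ]
    probe_segs = [
        (bases[i, 0], bases[i, 1], dirs[i], 0.0, params.probe_fraction * lengths[i])
        for i in range(n)
    ]
    radius_fn = _radius_profile(params)
    occ_actin = _rasterize(
        shape, actin_segs, params.pixel_size_xy, params.z_spacing, radius_fn
    )
    occ_probe = _rasterize(
        shape, probe_segs, params.pixel_size_xy, params.z_spacing, radius_fn
    )
    occ_probe &= occ_actin  # the probe decorates a prefix of each structure
    actin = _render_channel(occ_actin, params, rng)
    probe = _render_channel(occ_probe, params, rng)

    stack = VoxelStack(
        intensities=np.stack([actin, probe]),
        pixel_size_xy=params.pixel_size_xy,
        z_spacing=params.z_spacing,
        channel_names=("actin", "probe"),
        base_slice=0,
    )
    return stack, GroundTruth(fls=truth, params=asdict(params))


def simulate_trajectories(
    scene: SceneParams, dyn: DynamicsParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Telegraph-process length trajectories without rendering.

    Returns ``(fls, trajectories)``: one row per structure (base position,
    direction, birth/death frame) and one row per structure per frame it
    is alive (length, state, bleach boundary).  All structures start in
    the growing state; new ones nucleate at ``nucleation_rate`` per
    minute with length zero.
    """
    scene.validate()
    dyn.validate()
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    dt = dyn.frame_interval / 60.0  # minutes per frame
    p_cat = 1.0 - math.exp(-dyn.catastrophe_rate * dt)
    p_res = 1.0 - math.exp(-dyn.rescue_rate * dt)

    bases = _sample_bases(
        rng, scene.n_fls, scene.field_xy, scene.edge_margin, scene.min_separation
    )
    dirs, tilt_deg, azim_deg = _sample_directions(rng, scene.n_fls, scene.tilt_max)
    if dyn.initial_length is not None:
        lengths = np.full(scene.n_fls, float(dyn.initial_length))
    else:
        lengths = sample_lengths(
            rng,
            scene.n_fls,
            scene.length_rate,
            scene.min_length,
            scene.heavy_tail_mix,
            scene.heavy_tail_rate,
        )

    fls_rows = [
        {
            "fls_id": i,
            "base_x_um": bases[i, 0],
            "base_y_um": bases[i, 1],
            "tilt_deg": tilt_deg[i],
            "azimuth_deg": azim_deg[i],
            "birth_frame": 0,
            "death_frame": -1,  # -1: survives to the end
        }
        for i in range(scene.n_fls)
    ]
    alive = {i: {"length": lengths[i], "growing": True, "mark": None}
             for i in range(scene.n_fls)}
    next_id = scene.n_fls
    traj_rows: list[dict] = []

    for f in range(dyn.n_frames):
        if dyn.bleach_frame is not None and f == dyn.bleach_frame:
            for st in alive.values():
                st["mark"] = st["length"]
        for i, st in alive.items():
            if st["mark"] is not None:
                st["mark"] = min(st["mark"], st["length"])
            traj_rows.append(
                {
                    "fls_id": i,
                    "frame": f,
                    "time_s": f * dyn.frame_interval,
                    "length_um": st["length"],
                    "growing": st["growing"],
                    "bleach_mark_um": np.nan if st["mark"] is None else st["mark"],
                }
            )
        if f == dyn.n_frames - 1:
            break
        # evolve to the next frame: advance, then evaluate switching
        dead = []
        for i, st in alive.items():
            rate = dyn.growth_rate if st["growing"] else -dyn.shrink_rate
            st["length"] += rate * dt
            if st["length"] <= 0:
                dead.append(i)
                continue
            u = rng.random()
            if st["growing"] and u < p_cat:
                st["growing"] = False
            elif not st["growing"] and u < p_res:
                st["growing"] = True
        for i in dead:
            del alive[i]
            fls_rows[i]["death_frame"] = f + 1
        n_new = rng.poisson(dyn.nucleation_rate * dt) if dyn.nucleation_rate else 0
        if n_new:
            occupied = np.array(
                [[fls_rows[i]["base_x_um"], fls_rows[i]["base_y_um"]] for i in alive]
            )
            new_bases = _sample_bases(
                rng,
                n_new,
                scene.field_xy,
                scene.edge_margin,
                scene.min_separation,
                existing=occupied if len(occupied) else None,
            )
            new_dirs, new_tilt, new_azim = _sample_directions(
                rng, n_new, scene.tilt_max
            )
            for k in range(n_new):
                fls_rows.append(
                    {
                        "fls_id": next_id,
                        "base_x_um": new_bases[k, 0],
                        "base_y_um": new_bases[k, 1],
                        "tilt_deg": new_tilt[k],
                        "azimuth_deg": new_azim[k],
                        "birth_frame": f + 1,
                        "death_frame": -1,
                    }
                )
                alive[next_id] = {"length": 0.0, "growing": True, "mark": None}
                next_id += 1

    fls = pd.DataFrame(fls_rows)
    traj = pd.DataFrame(traj_rows)
    return fls, traj


def generate_timelapse(
    scene: SceneParams, dyn: DynamicsParams
) -> tuple[list[VoxelStack], GroundTruth]:
    """Render a time-lapse sequence of two-channel stacks with ground truth.

    Each frame is rendered from the trajectory state at that frame.  With
    a ``bleach_frame``, material below each structure's bleach boundary
    renders at ``bleach_survival`` of full intensity; the boundary only
    moves down (shrinkage consumes bleached material, regrowth is bright).
    """
    rng = np.random.default_rng(scene.seed)
    fls, traj = simulate_trajectories(scene, dyn, rng)
    geom = fls.set_index("fls_id")
    dirs = {
        i: np.array(
            [
                math.sin(math.radians(geom.loc[i, "tilt_deg"]))
                * math.cos(math.radians(geom.loc[i, "azimuth_deg"])),
                math.sin(math.radians(geom.loc[i, "tilt_deg"]))
                * math.sin(math.radians(geom.loc[i, "azimuth_deg"])),
                math.cos(math.radians(geom.loc[i, "tilt_deg"])),
            ]
        )
        for i in geom.index
    }
    shape = scene.grid_shape
    frames: list[VoxelStack] = []
    for f in range(dyn.n_frames):
        rows = traj[traj["frame"] == f]
        chans = []
        for frac in (1.0, scene.probe_fraction):  # actin, probe
            segs_full, segs_dim = [], []
            for _, r in rows.iterrows():
                i = int(r["fls_id"])
                bx, by = geom.loc[i, "base_x_um"], geom.loc[i, "base_y_um"]
                top = frac * r["length_um"]
                if top <= 0:
                    continue
                mark = r["bleach_mark_um"]
                if np.isnan(mark):
                    segs_full.append((bx, by, dirs[i], 0.0, top))
                else:
                    cut = min(mark, top)
                    segs_dim.append((bx, by, dirs[i], 0.0, cut))
                    if top > cut:
                        segs_full.append((bx, by, dirs[i], cut, top))
            radius_fn = _radius_profile(scene)
            occ_full = _rasterize(
                shape, segs_full, scene.pixel_size_xy, scene.z_spacing, radius_fn
            )
            occ_dim = _rasterize(
                shape, segs_dim, scene.pixel_size_xy, scene.z_spacing, radius_fn
            )
            chans.append(
                _render_channel(
                    occ_full, scene, rng, occ_dim=occ_dim,
                    dim_scale=dyn.bleach_survival,
                )
            )
        frames.append(
            VoxelStack(
                intensities=np.stack(chans),
                pixel_size_xy=scene.pixel_size_xy,
                z_spacing=scene.z_spacing,
                channel_names=("actin", "probe"),
                base_slice=0,
            )
        )
    truth = GroundTruth(
        fls=fls, params={"scene": asdict(scene), "dynamics": asdict(dyn)},
        trajectories=traj,
    )
    return frames, truth
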