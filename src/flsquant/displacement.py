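"""Two-channel extent statistics for actin-probe displacement.

Actin-binding probes (GFP-UtrCH, LifeAct) can be displaced from the older
part of a growing actin bundle, leaving probe signal only in a strip near
the base plane while the actin channel spans the full structure.  The
field-level summary of this displacement compares how far each channel
reaches in z:

* ``actin_extent`` — the first z-slice (counted from the base slice) with
  zero above-threshold actin area;
* ``probe_extent`` — the first z-slice where the probe area is at most
  half the actin area in that slice (a slice with zero actin area always
  qualifies, so the probe extent never exceeds the actin extent);
* ``extent_ratio`` — probe extent over actin extent: ~1 for full
  decoration, < 1 for displacement.

Per-slice areas use the same binarization as FLS detection.  When an
extent is never reached before the top of the stack the profile length is
returned and the result flagged as truncated rather than silently capped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import FLSPath, ThresholdConfig, binarize_slice
from .stack import VoxelStack

__all__ = [
    "ExtentResult",
    "ExtentProfile",
    "NormalizedProfile",
    "FLSIntensityProfile",
    "area_profile",
    "actin_extent",
    "probe_extent",
    "extent_ratio",
    "normalized_z_profiles",
    "fls_intensity_profile",
]


class ExtentResult(NamedTuple):
    index: int  # z-slices above the base slice
    truncated: bool  # condition never met before the top of the stack


@dataclass
class ExtentProfile:
    """Per-slice channel areas of one field plus the derived extents."""

    areas: dict[str, np.ndarray]  # channel -> µm² per slice, base upward
    actin_extent: int
    probe_extent: int
    extent_ratio: float  # NaN when actin extent is 0
    actin_truncated: bool
    probe_truncated: bool
    fov_id: str = ""

    @property
    def valid(self) -> bool:
        return np.isfinite(self.extent_ratio)


def area_profile(
    stack: VoxelStack,
    channel: str | int,
    threshold_cfg: ThresholdConfig | None = None,
) -> np.ndarray:
    """Total above-threshold area (µm²) per slice, base slice upward."""
    cfg = threshold_cfg or ThresholdConfig()
    data = stack.channel(channel)
    areas = np.empty(stack.n_slices - stack.base_slice)
    for i, z in enumerate(range(stack.base_slice, stack.n_slices)):
        mask = binarize_slice(data[z].astype(np.float64), cfg)
        areas[i] = mask.sum() * stack.pixel_size_xy**2
    return areas


def actin_extent(actin_areas: np.ndarray) -> ExtentResult:
    """First slice above the base with zero actin area."""
    areas = np.asarray(actin_areas)
    if areas.size == 0:
        raise ValueError("empty area profile")
    zero = np.flatnonzero(areas == 0)
    if zero.size:
        return ExtentResult(int(zero[0]), False)
    return ExtentResult(int(areas.size), True)


def probe_extent(actin_areas: np.ndarray, probe_areas: np.ndarray) -> ExtentResult:
    """First slice where probe area <= half the actin area in that slice.

    Slices with zero actin area qualify regardless of probe area, which
    guarantees probe extent <= actin extent for any pair of profiles.
    """
    a = np.asarray(actin_areas, dtype=float)
    p = np.asarray(probe_areas, dtype=float)
    if a.shape != p.shape:
        raise ValueError("profiles must have equal length")
    if a.size == 0:
        raise ValueError("empty area profile")
    ok = np.flatnonzero((a == 0) | (p <= 0.5 * a))
    if ok.size:
        return ExtentResult(int(ok[0]), False)
    return ExtentResult(int(a.size), True)


def extent_ratio(
    stack: VoxelStack,
    threshold_cfg: ThresholdConfig | None = None,
    actin_channel: str = "actin",
    probe_channel: str = "probe",
    fov_id: str = "",
) -> ExtentProfile:
    """Probe extent over actin extent for one two-channel field.

    A field whose actin extent is zero has no defined ratio; it is
    returned with ``extent_ratio = NaN`` and should be excluded from
    group means (``valid`` is False).
    """
    a = area_profile(stack, actin_channel, threshold_cfg)
    p = area_profile(stack, probe_channel, threshold_cfg)
    ae = actin_extent(a)
    pe = probe_extent(a, p)
    if ae.index == 0:
        warnings.warn(f"field {fov_id!r}: zero actin extent, ratio undefined")
        ratio = float("nan")
    else:
        ratio = pe.index / ae.index
    return ExtentProfile(
        areas={actin_channel: a, probe_channel: p},
        actin_extent=ae.index,
        probe_extent=pe.index,
        extent_ratio=ratio,
        actin_truncated=ae.truncated,
        probe_truncated=pe.truncated,
        fov_id=fov_id,
    )


@dataclass
class NormalizedProfile:
    """Group-averaged per-slice areas, normalized per field and channel.

    Each field's profile is divided by that channel's area in the first
    slice above the base slice, so every field contributes 1.0 there.
    ``mean`` and the t-based 95% CI are taken across fields per slice.
    """

    channels: tuple[str, ...]
    mean: dict[str, np.ndarray]
    ci_low: dict[str, np.ndarray]
    ci_high: dict[str, np.ndarray]
    n_fields: int
    reference_index: int = 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.channels:
            for z, (m, lo, hi) in enumerate(
                zip(self.mean[ch], self.ci_low[ch], self.ci_high[ch])
            ):
                rows.append(
                    {"channel": ch, "z_above_base": z, "mean_norm_area": m,
                     "ci_low": lo, "ci_high": hi, "n_fields": self.n_fields}
                )
        return pd.DataFrame(rows)


def normalized_z_profiles(
    fields: list[ExtentProfile], confidence: float = 0.95
) -> NormalizedProfile:
    """Average normalized z-profiles over fields, with t-based CIs.

    Fields whose reference-slice area is zero in any channel are excluded
    with a warning.  Profiles are compared over the slices common to all
    fields.  With a single field the CI half-width is reported as zero.
    """
    if not fields:
        raise ValueError("at least one field required")
    channels = tuple(fields[0].areas)
    ref = 1  # first slice above the base slice
    usable = []
    for fp in fields:
        if any(fp.areas[ch].size <= ref or fp.areas[ch][ref] == 0 for ch in channels):
            warnings.warn(
                f"field {fp.fov_id!r}: zero reference area, excluded from profile"
            )
            continue
        usable.append(fp)
    if not usable:
        raise ValueError("no field has a positive reference-slice area")
    nz = min(fp.areas[ch].size for fp in usable for ch in channels)
    n = len(usable)
    mean, lo, hi = {}, {}, {}
    for ch in channels:
        mat = np.stack([fp.areas[ch][:nz] / fp.areas[ch][ref] for fp in usable])
        m = mat.mean(axis=0)
        if n > 1:
            sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
            half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * sem
        else:
            half = np.zeros(nz)
        mean[ch], lo[ch], hi[ch] = m, m - half, m + half
    return NormalizedProfile(
        channels=channels, mean=mean, ci_low=lo, ci_high=hi, n_fields=n,
        reference_index=ref,
    )


@dataclass
class FLSIntensityProfile:
    """Background-subtracted intensity along one FLS, % of the base slice."""

    percent: dict[str, np.ndarray]  # channel -> % per slice from the base
    background: dict[str, float]
    box: int
    valid: bool = True
    fov_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch, vals in self.percent.items():
            for z, v in enumerate(vals):
                rows.append({"channel": ch, "z_above_base": z,
                             "intensity_pct_of_base": v})
        return pd.DataFrame(rows)


def fls_intensity_profile(
    stack: VoxelStack,
    path: FLSPath,
    box: int = 5,
    background: dict[str, float] | tuple[slice, slice] | None = None,
) -> FLSIntensityProfile:
    """Mean intensity in a box×box pixel window along one FLS.

    At each z-plane of the path (from the base slice) the window is
    centred on the nearest pixel to that slice's component centroid; the
    channel background is subtracted and the value expressed as a
    percentage of the base-slice value.  ``background`` is either a
    per-channel value, a pixel-space ROI ``(rows, cols)`` averaged over
    all slices (it must not contain FLS signal), or ``None`` for zero
    background.  A base-slice value at or below background flags the
    profile invalid.
    """
    if box < 1 or box % 2 == 0:
        raise ValueError("box must be a positive odd number of pixels")
    ps = stack.pixel_size_xy
    half = box // 2
    bg: dict[str, float] = {}
    for ch in stack.channel_names:
        if background is None:
            bg[ch] = 0.0
        elif isinstance(background, dict):
            bg[ch] = float(background[ch])
        else:
            rows, cols = background
            bg[ch] = float(stack.channel(ch)[:, rows, cols].mean())

    raw: dict[str, list[float]] = {ch: [] for ch in stack.channel_names}
    ny, nx = stack.shape[2], stack.shape[3]
    for comp in path.components:
        col = int(round(comp.centroid[0] / ps))
        row = int(round(comp.centroid[1] / ps))
        r0, r1 = max(0, row - half), min(ny, row + half + 1)
        c0, c1 = max(0, col - half), min(nx, col + half + 1)
        z = comp.z  # component z indices are stack slice indices
        for ch in stack.channel_names:
            raw[ch].append(float(stack.channel(ch)[z, r0:r1, c0:c1].mean()))

    percent: dict[str, np.ndarray] = {}
    valid = True
    for ch, vals in raw.items():
        corrected = np.asarray(vals) - bg[ch]
        if corrected[0] <= 0:
            warnings.warn(
                f"channel {ch!r}: base-slice intensity not above background; "
                "profile flagged invalid"
            )
            valid = False
            percent[ch] = np.full(len(corrected), np.nan)
        else:
            percent[ch] = 100.0 * corrected / corrected[0]
    return FLSIntensityProfile(
        percent=percent, background=bg, box=box, valid=valid, fov_id=path.fov_id
    )
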