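"""Geometric model of the 24-well microfluidic worm-trap chip.

The chip has 24 wells, each feeding 40 parallel tapering channels (960
channels total) that trap and laterally orient single *C. elegans* for
brightfield imaging.  Two designs are modelled: ``D1`` (adult-sized, tapering
from 98 x 102 um at the entrance to 24 x 40 um at the exit) and ``L4``
(narrowing further to 10 x 17 um, trapping smaller larvae).

This module owns three things:

* the channel taper profile (piecewise-linear width/height vs axial position),
  from which the volume integrator downstream derives per-pixel channel
  heights;
* the channel layout relative to the per-well fiduciary marker, used to crop
  individual channels out of a field of view (FOV);
* acquisition-plan accounting: how many FOVs cover a well and how many images
  a whole-chip experiment produces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ChannelGeometry",
    "ChipMap",
    "ImagingPlan",
    "ChannelBox",
    "height_profile_at",
    "fovs_required",
    "channel_boxes",
    "plan_image_count",
    "d1_geometry",
    "l4_geometry",
    "default_chip_map",
    "minimal_plan",
    "full_plan",
    "load_chip",
    "load_plan",
    "save_chip",
    "save_plan",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Tapered trapping-channel profile.

    ``control_points`` is an ordered list of ``(axial_position_um, width_um,
    height_um)`` with the first point at the channel entrance (axial position
    0) and the last at ``channel_length``.  Width and height are interpolated
    piecewise-linearly between control points and must taper (be
    non-increasing) along the axis.
    """

    design_name: str
    control_points: tuple[tuple[float, float, float], ...]
    channel_length: float

    def __post_init__(self) -> None:
        cps = tuple((float(s), float(w), float(h)) for s, w, h in self.control_points)
        object.__setattr__(self, "control_points", cps)
        if len(cps) < 2:
            raise ValueError("need at least two control points")
        s = np.array([p[0] for p in cps])
        w = np.array([p[1] for p in cps])
        h = np.array([p[2] for p in cps])
        if s[0] != 0.0:
            raise ValueError("first control point must be at axial position 0")
        if not np.all(np.diff(s) > 0):
            raise ValueError("axial positions must be strictly increasing")
        if s[-1] != self.channel_length:
            raise ValueError("last control point must sit at channel_length")
        if np.any(w <= 0) or np.any(h <= 0):
            raise ValueError("channel dimensions must be positive")
        if np.any(np.diff(w) > 0) or np.any(np.diff(h) > 0):
            raise ValueError("channel must taper: width/height non-increasing")


@dataclass(frozen=True)
class ChipMap:
    """Layout of channels and wells relative to the fiduciary markers."""

    n_wells: int = 24
    channels_per_well: int = 40
    channel_pitch: float = 150.0  # um between adjacent channel centerlines
    well_pitch_mm: float = 9.0
    fiduciary_offset: tuple[float, float] = (0.0, 0.0)  # um, fiduciary -> channel 0 center
    channel_axis: str = "y"  # image axis along which channels run

    def __post_init__(self) -> None:
        if self.n_wells <= 0 or self.channels_per_well <= 0:
            raise ValueError("counts must be positive")
        if self.channel_pitch <= 0 or self.well_pitch_mm <= 0:
            raise ValueError("pitch must be positive")
        if self.channel_axis not in ("x", "y"):
            raise ValueError("channel_axis must be 'x' or 'y'")

    @property
    def total_channels(self) -> int:
        return self.n_wells * self.channels_per_well


@dataclass(frozen=True)
class ImagingPlan:
    """Volumetric brightfield acquisition plan for one chip run."""

    objective: tuple[float, float] = (10.0, 0.4)  # magnification, NA
    fov_size: tuple[float, float] = (1300.0, 2200.0)  # um (width across channels, height)
    fovs_per_well: int = 5
    z_slices: int = 18
    z_step: float = 6.0  # um
    volumes_per_fov: int = 1  # static (+ timelapse) volumes per FOV
    fiduciary_frames_per_well: int = 1
    wells: int = 24
    pixel_size: float = 0.425  # um/px at the 10x objective

    def __post_init__(self) -> None:
        for name in ("fovs_per_well", "z_slices", "volumes_per_fov",
                     "fiduciary_frames_per_well", "wells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.z_step <= 0:
            raise ValueError("z_step must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class ChannelBox:
    """Axis-aligned crop box for one channel (um, 0-based, half-open)."""

    channel_index: int
    x0: float
    y0: float
    x1: float
    y1: float
    truncated: bool = False

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


# ---------------------------------------------------------------------------
# operations


def height_profile_at(
    geometry: ChannelGeometry, s: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Channel (width, height) in um at axial position ``s`` um from the entrance.

    Piecewise-linear interpolation between the geometry's control points;
    exact at the control points.  ``s`` may be a scalar or an array.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0) or np.any(s_arr > geometry.channel_length):
        raise ValueError(
            f"axial position outside [0, {geometry.channel_length}] um"
        )
    pts = np.array(geometry.control_points)
    w = np.interp(s_arr, pts[:, 0], pts[:, 1])
    h = np.interp(s_arr, pts[:, 0], pts[:, 2])
    if np.isscalar(s) or s_arr.ndim == 0:
        return float(w), float(h)
    return w, h


def fovs_required(n_channels: int, channel_pitch: float, fov_width: float) -> int:
    """Number of FOVs needed to cover ``n_channels`` at the given pitch.

    A FOV of width ``fov_width`` um covers ``floor(fov_width / channel_pitch)``
    channels; e.g. 8 channels at 150 um pitch fit in a 1.3 mm FOV, so a
    40-channel well needs 5 FOVs.
    """
    if n_channels <= 0 or channel_pitch <= 0 or fov_width <= 0:
        raise ValueError("all inputs must be positive")
    per_fov = math.floor(fov_width / channel_pitch)
    if per_fov < 1:
        raise ValueError("FOV narrower than channel pitch: no channel fits")
    return math.ceil(n_channels / per_fov)


def channel_boxes(
    chip: ChipMap,
    fiduciary_xy: tuple[float, float],
    crop_size: tuple[float, float],
    image_size: tuple[float, float] | None = None,
) -> list[ChannelBox]:
    """Per-channel crop boxes for one well, positioned off the fiduciary marker.

    Boxes are spaced at ``chip.channel_pitch`` along the axis perpendicular to
    the channel axis, ordered by channel index, and non-overlapping as long as
    the crop width does not exceed the pitch.  If ``image_size`` (width,
    height in um) is given, boxes extending outside the image are flagged
    ``truncated`` (never silently clipped).
    """
    fx, fy = fiduciary_xy
    ox, oy = chip.fiduciary_offset
    cw, ch = crop_size
    if cw <= 0 or ch <= 0:
        raise ValueError("crop size must be positive")
    boxes = []
    for i in range(chip.channels_per_well):
        if chip.channel_axis == "y":
            cx = fx + ox + i * chip.channel_pitch
            cy = fy + oy
        else:
            cx = fx + ox
            cy = fy + oy + i * chip.channel_pitch
        x0, x1 = cx - cw / 2.0, cx + cw / 2.0
        y0, y1 = cy - ch / 2.0, cy + ch / 2.0
        truncated = False
        if image_size is not None:
            iw, ih = image_size
            truncated = x0 < 0 or y0 < 0 or x1 > iw or y1 > ih
        boxes.append(ChannelBox(i, x0, y0, x1, y1, truncated))
    return boxes


def plan_image_count(plan: ImagingPlan) -> int:
    """Total 2D images produced by an acquisition plan.

    wells x (fiduciary frames + FOVs x z-slices x volumes).  The default
    minimal plan (1 volume) gives 2,184 images for a 24-well chip; the full
    plan (1 static + 5 timelapse volumes) gives 12,984.
    """
    per_well = plan.fiduciary_frames_per_well + (
        plan.fovs_per_well * plan.z_slices * plan.volumes_per_fov
    )
    return plan.wells * per_well


# ---------------------------------------------------------------------------
# shipped defaults


def d1_geometry() -> ChannelGeometry:
    """Adult-trapping design: 98 x 102 um entrance tapering to 24 x 40 um exit."""
    return ChannelGeometry(
        design_name="D1",
        control_points=((0.0, 98.0, 102.0), (3000.0, 24.0, 40.0)),
        channel_length=3000.0,
    )


def l4_geometry() -> ChannelGeometry:
    """Larva-trapping design narrowing to 10 x 17 um at the narrowest region.

    Only the entrance and narrowest dimensions are fixed by the chip
    description; the intermediate control point is a configurable default.
    """
    return ChannelGeometry(
        design_name="L4",
        control_points=(
            (0.0, 98.0, 102.0),
            (2400.0, 24.0, 40.0),
            (3000.0, 10.0, 17.0),
        ),
        channel_length=3000.0,
    )


def default_chip_map() -> ChipMap:
    return ChipMap()


def minimal_plan() -> ImagingPlan:
    """Single-timepoint plan: 18 z-slices, 5 FOVs/well -> 2,184 images/chip."""
    return ImagingPlan(volumes_per_fov=1)


def full_plan() -> ImagingPlan:
    """Static + 5-frame timelapse plan -> 12,984 images/chip."""
    return ImagingPlan(volumes_per_fov=6)


# ---------------------------------------------------------------------------
# structured text config I/O (YAML)


def _geometry_to_dict(g: ChannelGeometry) -> dict:
    return {
        "design_name": g.design_name,
        "channel_length_um": g.channel_length,
        "control_points": [
            {"s_um": s, "width_um": w, "height_um": h} for s, w, h in g.control_points
        ],
    }


def _geometry_from_dict(d: dict) -> ChannelGeometry:
    return ChannelGeometry(
        design_name=d["design_name"],
        control_points=tuple(
            (p["s_um"], p["width_um"], p["height_um"]) for p in d["control_points"]
        ),
        channel_length=d["channel_length_um"],
    )


def _plan_to_dict(p: ImagingPlan) -> dict:
    return {
        "objective": {"magnification": p.objective[0], "na": p.objective[1]},
        "fov_size_um": list(p.fov_size),
        "fovs_per_well": p.fovs_per_well,
        "z_slices": p.z_slices,
        "z_step_um": p.z_step,
        "volumes_per_fov": p.volumes_per_fov,
        "fiduciary_frames_per_well": p.fiduciary_frames_per_well,
        "wells": p.wells,
        "pixel_size_um": p.pixel_size,
    }


def _plan_from_dict(d: dict) -> ImagingPlan:
    return ImagingPlan(
        objective=(d["objective"]["magnification"], d["objective"]["na"]),
        fov_size=tuple(d["fov_size_um"]),
        fovs_per_well=d["fovs_per_well"],
        z_slices=d["z_slices"],
        z_step=d["z_step_um"],
        volumes_per_fov=d["volumes_per_fov"],
        fiduciary_frames_per_well=d["fiduciary_frames_per_well"],
        wells=d["wells"],
        pixel_size=d.get("pixel_size_um", 0.425),
    )


def save_chip(geometry: ChannelGeometry, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_geometry_to_dict(geometry), sort_keys=False))


def save_plan(plan: ImagingPlan, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_plan_to_dict(plan), sort_keys=False))


def _shipped(name: str) -> Path:
    return resources.files("wormdart").joinpath("data", name)  # type: ignore[return-value]


def load_chip(name_or_path: str | Path) -> ChannelGeometry:
    """Load a channel geometry from a config file or a shipped name (``d1.chip``)."""
    p = Path(name_or_path)
    if not p.exists():
        shipped = _shipped(str(name_or_path))
        if shipped.is_file():
            return _geometry_from_dict(yaml.safe_load(shipped.read_text()))
        raise FileNotFoundError(name_or_path)
    return _geometry_from_dict(yaml.safe_load(p.read_text()))


def load_plan(name_or_path: str | Path) -> ImagingPlan:
    """Load an imaging plan from a config file or a shipped name (``minimal.plan``)."""
    p = Path(name_or_path)
    if not p.exists():
        shipped = _shipped(str(name_or_path))
        if shipped.is_file():
            return _plan_from_dict(yaml.safe_load(shipped.read_text()))
        raise FileNotFoundError(name_or_path)
    return _plan_from_dict(yaml.safe_load(p.read_text()))
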