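"""Ground-truthed synthetic data standing in for unavailable raw assay data.

Three generator families:

* **Rendered channel z-stacks** — a curved worm body squeezed into a tapered
  trapping channel, imaged as an 18-slice brightfield stack whose sharpness
  peaks at a known best-focus plane, with in-utero embryos rendered early
  (granular ellipse) or late (ellipse containing a dark curled-larva motif).
  Every stack ships with a :class:`GroundTruth` (mask, body dimensions,
  embryo records) enabling oracle tests without any downloaded data.

* **Tabular well-plate phenotype simulations** — hierarchical sampling
  (biological-replicate effect x well effect x worm-level noise) around the
  assay's six endpoints, with baseline means matching a healthy day-1 adult
  population (length 1,522 um; area 75.9e3 um2; volume 2.96e6 um3; 30.7
  early / 14.0 late / 44.7 total in-utero embryos).

* **Concentration-response simulations** — well values drawn around a true
  four-parameter logistic (4PL) curve, for fit-recovery and coverage tests.

Body model.  The worm is a tube of radius ``r(s)`` along an arc-length
parameterised sinusoidal centerline.  A trapped day-1 adult is pressed into
full dorsoventral contact with the channel ceiling and floor, so the
generator renders the squeezed cross-section as an equivalent-area rectangle
of height ``h(s)`` (the local channel height) and half-width
``a(s) = pi r(s)^2 / (2 h(s))``.  In this regime the downstream estimator
"mask area integrated with channel heights" recovers the true tube volume
``pi * integral r(s)^2 ds`` exactly (up to pixelation), which is what makes
the fixtures usable as morphometric oracles.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .chip import ChannelGeometry, ChipMap, ImagingPlan, height_profile_at
from .imaging import ZStack, cross_template
from .stats import fourpl

__all__ = [
    "EmbryoSpec",
    "SyntheticWormSpec",
    "GroundTruth",
    "PhenotypeSimConfig",
    "ConcResponseSimConfig",
    "GeometryError",
    "render_channel_stack",
    "render_empty_channel",
    "render_well_image",
    "render_motility_frames",
    "simulate_well_plate",
    "simulate_dose_plate",
    "simulate_conc_response",
    "plant_outliers",
    "annotations_from_truth",
    "annotations_from_counts",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_truth_json",
]


class GeometryError(ValueError):
    """Worm does not fit the channel at its trap position."""


@dataclass(frozen=True)
class EmbryoSpec:
    """One in-utero embryo: position along/across the body, stage, eggshell axes."""

    arc_pos_um: float  # arc position of the embryo center along the body
    lateral_offset_um: float = 0.0
    stage: str = "early"  # early (<= 2-fold) or late (> 2-fold)
    major_um: float = 50.0
    minor_um: float = 30.0

    def __post_init__(self) -> None:
        if self.stage not in ("early", "late"):
            raise ValueError("stage must be 'early' or 'late'")


@dataclass(frozen=True)
class SyntheticWormSpec:
    """Parametric trapped-worm description (free-body dimensions).

    ``max_radius`` is the undeformed mid-body radius; the rendered squeezed
    half-width follows from the local channel height (module docstring).
    ``axial_offset`` is the channel-axis position (um from the entrance) of
    the tail tip of the body.
    """

    body_length: float = 1200.0  # um along the centerline
    max_radius: float = 32.0  # um, mid-body
    tip_radius_fraction: float = 0.25
    taper_fraction: float = 0.12  # fraction of body length tapered at each end
    amplitude: float = 8.0  # um, sinusoidal centerline amplitude
    wavelength: float = 600.0  # um
    phase: float = 0.0
    axial_offset: float = 200.0  # um, trap position of the tail tip
    embryos: tuple[EmbryoSpec, ...] = ()
    background: float = 0.85
    worm_contrast: float = 0.5  # worm interior intensity / background
    noise_sd: float = 0.02  # additive noise, fraction of background
    best_focus_z: int | None = None  # defaults to the middle slice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_length <= 0 or self.max_radius <= 0:
            raise ValueError("body dimensions must be positive")
        if not (0 < self.taper_fraction < 0.5):
            raise ValueError("taper_fraction must be in (0, 0.5)")
        if not (0 <= self.tip_radius_fraction < 1):
            raise ValueError("tip_radius_fraction must be in [0, 1)")

    def radius_at(self, u: float | np.ndarray) -> np.ndarray:
        """Body radius (um) at arc fraction ``u`` in [0, 1]: blunt-tapered tube."""
        u = np.asarray(u, dtype=float)
        t, f0 = self.taper_fraction, self.tip_radius_fraction
        g = np.ones_like(u)
        lo = u < t
        hi = u > 1 - t
        g[lo] = f0 + (1 - f0) * np.sin(0.5 * np.pi * u[lo] / t)
        g[hi] = f0 + (1 - f0) * np.sin(0.5 * np.pi * (1 - u[hi]) / t)
        return self.max_radius * g


@dataclass
class GroundTruth:
    """Truth channel for oracle tests: what the generator actually drew."""

    mask: np.ndarray
    true_length: float
    true_area: float
    true_volume: float
    true_best_focus: int
    embryo_records: list  # (x_um, y_um, z_index, stage)
    channel_id: str
    classification: str = "full"
    axial_origin: float = 0.0

    @property
    def n_early(self) -> int:
        return sum(1 for r in self.embryo_records if r[3] == "early")

    @property
    def n_late(self) -> int:
        return sum(1 for r in self.embryo_records if r[3] == "late")

    @property
    def n_total(self) -> int:
        return self.n_early + self.n_late


# ---------------------------------------------------------------------------
# channel-stack rendering


def _centerline(spec: SyntheticWormSpec, n: int = 8192):
    """Arc-length parameterisation of the sinusoidal centerline.

    Returns (s_axial, lateral, arc, cos_theta) sampled on a fine axial grid
    starting at the tail tip; ``arc`` is cumulative arc length (um).
    """
    # generous axial span; the body ends where arc == body_length
    span = spec.body_length * 1.5 + 10.0
    s = np.linspace(0.0, span, n) + spec.axial_offset
    lat = spec.amplitude * np.sin(2 * np.pi * (s - spec.axial_offset) / spec.wavelength + spec.phase)
    dlat = np.gradient(lat, s)
    cos_t = 1.0 / np.sqrt(1.0 + dlat**2)
    darc = np.sqrt(1.0 + dlat**2) * np.gradient(s)
    arc = np.cumsum(darc) - darc[0]
    return s, lat, arc, cos_t


def _true_volume(spec: SyntheticWormSpec, n: int = 20001) -> float:
    """Closed-tube volume pi * integral r(u)^2 dl by fine trapezoid quadrature."""
    u = np.linspace(0.0, 1.0, n)
    r = spec.radius_at(u)
    return float(np.pi * np.trapezoid(r**2, u * spec.body_length))


def _draw_ellipse_embryo(
    img: np.ndarray,
    mask: np.ndarray,
    center_rc: tuple[float, float],
    major_px: float,
    minor_px: float,
    stage: str,
    background: float,
    rng: np.random.Generator,
) -> None:
    """Render one embryo: early = granular ellipse, late = dark curled tube."""
    r0, c0 = center_rc
    rr = int(math.ceil(major_px / 2)) + 2
    cc = int(math.ceil(minor_px / 2)) + 2
    r_lo, r_hi = max(0, int(r0) - rr), min(img.shape[0], int(r0) + rr + 1)
    c_lo, c_hi = max(0, int(c0) - cc), min(img.shape[1], int(c0) + cc + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    yy, xx = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    # major axis along the channel axis (rows)
    e = ((yy - r0) / (major_px / 2)) ** 2 + ((xx - c0) / (minor_px / 2)) ** 2
    inside = (e <= 1.0) & mask[r_lo:r_hi, c_lo:c_hi]
    region = img[r_lo:r_hi, c_lo:c_hi]
    shell = (e <= 1.0) & (e > 0.78) & mask[r_lo:r_hi, c_lo:c_hi]
    if stage == "early":
        # uniform granular texture inside the eggshell
        tex = 0.62 * background * (1.0 + 0.22 * rng.uniform(-1, 1, size=region.shape))
        region[inside] = tex[inside]
    else:
        region[inside] = 0.68 * background
        # curled-larva motif: a dark spiral band inside the eggshell
        t = np.linspace(0.0, 1.0, 80)
        rho = (0.15 + 0.55 * t)
        ang = 3.0 * np.pi * t
        sy = r0 + rho * np.cos(ang) * (major_px / 2) * 0.8
        sx = c0 + rho * np.sin(ang) * (minor_px / 2) * 0.8
        for py, px_ in zip(sy, sx):
            ry, rx = int(round(py)), int(round(px_))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    qy, qx = ry + dy, rx + dx
                    if r_lo <= qy < r_hi and c_lo <= qx < c_hi and mask[qy, qx]:
                        img[qy, qx] = 0.38 * background
    region[shell] = np.minimum(region[shell], 0.5 * background)


def render_channel_stack(
    spec: SyntheticWormSpec,
    geometry: ChannelGeometry,
    plan: ImagingPlan,
    channel_id: str = "c00",
    margin_um: float = 60.0,
    crop_axial_range: tuple[float, float] | None = None,
    defocus_px_per_slice: float = 2.0,
    wall_clearance_um: float = 2.0,
) -> tuple[ZStack, GroundTruth]:
    """Render a trapped worm as a calibrated brightfield z-stack + truth.

    Slice sharpness peaks at the true best-focus plane and degrades with
    Gaussian blur of sigma ``defocus_px_per_slice * |z - best|``.  Passing
    ``crop_axial_range`` that clips the body produces a ``partial`` fixture.
    Raises :class:`GeometryError` when the squeezed body (plus clearance)
    exceeds the local channel width.
    """
    if plan.z_slices < 1:
        raise ValueError("plan must have >= 1 z slice")
    px = plan.pixel_size
    rng = np.random.default_rng(spec.seed)

    s_f, lat_f, arc_f, cos_f = _centerline(spec)
    if arc_f[-1] < spec.body_length:
        raise GeometryError("centerline span too short for body length")
    # axial extent of the body: arc length from 0 to body_length
    s_head = float(np.interp(spec.body_length, arc_f, s_f))
    if crop_axial_range is None:
        crop_start = max(0.0, spec.axial_offset - margin_um)
        crop_end = s_head + margin_um
    else:
        crop_start, crop_end = crop_axial_range
    if crop_start < 0 or crop_end > geometry.channel_length:
        raise GeometryError("crop outside the channel span")
    n_rows = int(math.ceil((crop_end - crop_start) / px))
    s_rows = crop_start + (np.arange(n_rows) + 0.5) * px
    w_rows, h_rows = height_profile_at(geometry, s_rows)
    width_um = float(np.max(w_rows)) + 20.0
    n_cols = int(math.ceil(width_um / px))
    center_col = n_cols / 2.0

    bg = spec.background
    sharp = np.full((n_rows, n_cols), bg, dtype=np.float64)

    # channel walls: dark lines at +/- w(s)/2 around the channel centerline
    cols = np.arange(n_cols)
    for sign in (-1.0, 1.0):
        wall_col = center_col + sign * (w_rows / 2.0) / px
        for i in range(n_rows):
            c = int(round(wall_col[i]))
            if 0 <= c < n_cols:
                sharp[i, max(0, c - 1) : min(n_cols, c + 1)] = 0.55 * bg

    # body mask, row by row along the channel axis
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    in_body = (s_rows >= spec.axial_offset) & (s_rows <= s_head)
    arc_rows = np.interp(s_rows, s_f, arc_f)
    lat_rows = np.interp(s_rows, s_f, lat_f)
    cos_rows = np.interp(s_rows, s_f, cos_f)
    u_rows = np.clip(arc_rows / spec.body_length, 0.0, 1.0)
    r_rows = spec.radius_at(u_rows)
    a_rows = np.pi * r_rows**2 / (2.0 * h_rows)  # squeezed half-width, um
    body_clipped = False
    for i in np.where(in_body)[0]:
        a_um = a_rows[i]
        if 2 * a_um + 2 * abs(lat_rows[i]) + wall_clearance_um > w_rows[i]:
            raise GeometryError(
                f"worm wider than channel at s={s_rows[i]:.0f} um "
                f"(needs {2 * a_um + 2 * abs(lat_rows[i]):.1f}, width {w_rows[i]:.1f})"
            )
        half_px = a_um / (cos_rows[i] * px)
        if half_px < 0.5:
            continue
        c0 = center_col + lat_rows[i] / px
        lo = int(round(c0 - half_px))
        hi = int(round(c0 + half_px))
        lo_c, hi_c = max(0, lo), min(n_cols, hi)
        if lo_c < hi_c:
            mask[i, lo_c:hi_c] = True
    if (in_body.any() and (s_rows[0] > spec.axial_offset or s_rows[-1] < s_head)):
        body_clipped = True

    # worm interior: dark with mild smooth texture
    interior = spec.worm_contrast * bg
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=sharp.shape), 4.0)
    tex = 0.06 * bg * tex / max(tex.std(), 1e-12)
    sharp[mask] = interior + tex[mask]

    z_slices = plan.z_slices
    best = spec.best_focus_z if spec.best_focus_z is not None else z_slices // 2
    if not (0 <= best < z_slices):
        raise ValueError("best_focus_z outside the stack")

    # embryos: placed by arc position, centered on the centerline row
    embryo_records = []
    for emb in spec.embryos:
        if not (0 < emb.arc_pos_um < spec.body_length):
            raise GeometryError("embryo outside the body span")
        s_e = float(np.interp(emb.arc_pos_um, arc_f, s_f))
        i_row = (s_e - crop_start) / px - 0.5
        if not (0 <= i_row < n_rows):
            continue
        idx = int(round(i_row))
        a_here = a_rows[idx]
        if abs(emb.lateral_offset_um) >= max(a_here, 1e-9):
            raise GeometryError("embryo center outside the body")
        c_e = center_col + (lat_rows[idx] + emb.lateral_offset_um) / px
        _draw_ellipse_embryo(
            sharp, mask, (i_row, c_e), emb.major_um / px, emb.minor_um / px,
            emb.stage, bg, rng,
        )
        z_e = int(np.clip(best + rng.integers(-1, 2), 0, z_slices - 1))
        embryo_records.append((float(c_e * px), float(i_row * px), z_e, emb.stage))

    sharp = ndimage.gaussian_filter(sharp, 0.8)

    stack = np.empty((z_slices, n_rows, n_cols), dtype=np.float32)
    for k in range(z_slices):
        sigma = defocus_px_per_slice * abs(k - best)
        sl = ndimage.gaussian_filter(sharp, sigma) if sigma > 0 else sharp
        noise = rng.normal(0.0, spec.noise_sd * bg, size=sharp.shape)
        stack[k] = (sl + noise).astype(np.float32)

    classification = "partial" if body_clipped else "full"
    truth = GroundTruth(
        mask=mask,
        true_length=spec.body_length,
        true_area=float(mask.sum()) * px**2,
        true_volume=_true_volume(spec),
        true_best_focus=best,
        embryo_records=embryo_records,
        channel_id=channel_id,
        classification=classification,
        axial_origin=crop_start,
    )
    zs = ZStack(
        stack, pixel_size=px, z_step=plan.z_step,
        metadata={"channel_id": channel_id, "axial_origin": crop_start},
    )
    return zs, truth


def render_empty_channel(
    geometry: ChannelGeometry,
    plan: ImagingPlan,
    axial_origin: float = 200.0,
    length_um: float = 1300.0,
    background: float = 0.85,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> ZStack:
    """A worm-free channel crop (walls + noise only), for ``none`` fixtures."""
    px = plan.pixel_size
    rng = np.random.default_rng(seed)
    n_rows = int(math.ceil(length_um / px))
    s_rows = axial_origin + (np.arange(n_rows) + 0.5) * px
    w_rows, _ = height_profile_at(geometry, s_rows)
    n_cols = int(math.ceil((float(np.max(w_rows)) + 20.0) / px))
    center_col = n_cols / 2.0
    sharp = np.full((n_rows, n_cols), background, dtype=np.float64)
    for sign in (-1.0, 1.0):
        wall_col = center_col + sign * (w_rows / 2.0) / px
        for i in range(n_rows):
            c = int(round(wall_col[i]))
            if 0 <= c < n_cols:
                sharp[i, max(0, c - 1) : min(n_cols, c + 1)] = 0.55 * background
    best = plan.z_slices // 2
    stack = np.empty((plan.z_slices, n_rows, n_cols), dtype=np.float32)
    for k in range(plan.z_slices):
        sigma = 2.0 * abs(k - best)
        sl = ndimage.gaussian_filter(sharp, sigma) if sigma > 0 else sharp
        stack[k] = (sl + rng.normal(0.0, noise_sd * background, sharp.shape)).astype(np.float32)
    return ZStack(stack, pixel_size=px, z_step=plan.z_step,
                  metadata={"axial_origin": axial_origin})


def render_well_image(
    chip: ChipMap,
    fiduciary_xy_um: tuple[float, float] = (400.0, 400.0),
    pixel_size: float = 2.0,
    image_size_um: tuple[float, float] = (7000.0, 1200.0),
    stripe_width_um: float = 60.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Low-magnification view of one well: fiduciary cross + channel stripes.

    Returns ``(image, truth)`` with the painted fiduciary position and true
    channel center x-coordinates (um), for testing marker detection and
    chip-map channel localisation end to end.
    """
    rng = np.random.default_rng(seed)
    w_px = int(image_size_um[0] / pixel_size)
    h_px = int(image_size_um[1] / pixel_size)
    img = np.full((h_px, w_px), 0.85, dtype=np.float64)
    tmpl = cross_template(size=31, arm_width=5, contrast=0.6) * 0.85
    fx_px = int(round(fiduciary_xy_um[0] / pixel_size))
    fy_px = int(round(fiduciary_xy_um[1] / pixel_size))
    img[fy_px : fy_px + tmpl.shape[0], fx_px : fx_px + tmpl.shape[1]] = tmpl
    centers = []
    ox, oy = chip.fiduciary_offset
    for i in range(chip.channels_per_well):
        cx_um = fiduciary_xy_um[0] + ox + i * chip.channel_pitch
        centers.append(cx_um)
        c0 = int(round((cx_um - stripe_width_um / 2) / pixel_size))
        c1 = int(round((cx_um + stripe_width_um / 2) / pixel_size))
        y0 = int(round((fiduciary_xy_um[1] + oy + 100.0) / pixel_size))
        img[y0:, max(0, c0) : min(w_px, c1)] = 0.6
    img += rng.normal(0.0, 0.01, img.shape)
    truth = {"fiduciary_xy_um": fiduciary_xy_um, "channel_centers_x_um": centers}
    return img, truth


def render_motility_frames(
    n_blobs: int = 10,
    n_moving: int = 4,
    shift_px: float = 6.0,
    n_frames: int = 3,
    shape: tuple[int, int] = (240, 320),
    blob_radius_px: int = 5,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Timelapse frames of dark worm-scale blobs; the first ``n_moving`` blobs
    displace by ``shift_px`` per frame.  Returns (frames, moving_truth)."""
    rng = np.random.default_rng(seed)
    margin = 25
    pos = np.column_stack([
        rng.uniform(margin, shape[0] - margin - (n_frames * shift_px), n_blobs),
        rng.uniform(margin, shape[1] - margin, n_blobs),
    ])
    # enforce spacing so nearest-neighbour matching is unambiguous
    for _ in range(200):
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1) + np.eye(n_blobs) * 1e9
        bad = np.where(d.min(axis=1) < 6 * blob_radius_px)[0]
        if len(bad) == 0:
            break
        pos[bad] = np.column_stack([
            rng.uniform(margin, shape[0] - margin - (n_frames * shift_px), len(bad)),
            rng.uniform(margin, shape[1] - margin, len(bad)),
        ])
    moving = np.zeros(n_blobs, dtype=bool)
    moving[:n_moving] = True
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    frames = []
    for f in range(n_frames):
        img = np.full(shape, 0.85, dtype=np.float64)
        for b in range(n_blobs):
            py, px_ = pos[b]
            if moving[b]:
                py = py + f * shift_px
            blob = (yy - py) ** 2 + (xx - px_) ** 2 <= blob_radius_px**2
            img[blob] = 0.3
        img += rng.normal(0.0, 0.01, shape)
        frames.append(img)
    return frames, moving


# ---------------------------------------------------------------------------
# tabular simulations


@dataclass(frozen=True)
class PhenotypeSimConfig:
    """Hierarchical well-plate phenotype simulation.

    Baseline means are a healthy day-1 adult population; worm-level spread,
    well effects and biological-replicate effects are multiplicative
    lognormal (CV-parameterised, strictly positive).  Worm-level embryo
    totals are rounded lognormal, split early/late by a Beta fraction.
    """

    length_mean: float = 1522.0
    length_sd: float = 60.0
    area_mean: float = 75.9e3
    area_sd: float = 5.5e3
    volume_mean: float = 2.96e6
    volume_sd: float = 0.30e6
    early_mean: float = 30.7
    late_mean: float = 14.0
    embryo_cv: float = 0.18  # worm-level CV of the total embryo count
    early_fraction_kappa: float = 60.0  # Beta concentration of the early fraction
    between_replicate_cv: float = 0.04
    between_well_cv: float = 0.015
    worms_per_well: int = 40
    wells_per_condition: int = 6
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embryo_cv", "between_replicate_cv", "between_well_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.worms_per_well > 40:
            warnings.warn("worms_per_well exceeds the 40-channel chip capacity")

    @property
    def total_mean(self) -> float:
        return self.early_mean + self.late_mean


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative lognormal effect with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def _sample_worms(
    rng: np.random.Generator,
    cfg: PhenotypeSimConfig,
    n: int,
    rep_f: dict,
    well_f: dict,
    mean_scale: dict | None = None,
) -> dict:
    """Worm-level endpoint draws for one well given replicate/well effects."""
    scale = mean_scale or {}
    out = {}
    for key, mean, sd in (
        ("length_um", cfg.length_mean, cfg.length_sd),
        ("area_um2", cfg.area_mean, cfg.area_sd),
        ("volume_um3", cfg.volume_mean, cfg.volume_sd),
    ):
        mu = mean * scale.get(key, 1.0) * rep_f[key] * well_f[key]
        out[key] = np.maximum(rng.normal(mu, sd, n) if sd > 0 else np.full(n, mu), 1e-9)
    e_mean = cfg.early_mean * scale.get("early_count", 1.0)
    l_mean = cfg.late_mean * scale.get("late_count", 1.0)
    t_mean = (e_mean + l_mean) * rep_f["embryo"] * well_f["embryo"]
    if cfg.embryo_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.embryo_cv**2))
        totals = rng.lognormal(math.log(max(t_mean, 1e-9)) - 0.5 * sigma**2, sigma, n)
    else:
        totals = np.full(n, t_mean)
    totals = np.maximum(np.round(totals), 0).astype(int)
    p = e_mean / max(e_mean + l_mean, 1e-9)
    if math.isinf(cfg.early_fraction_kappa):
        frac = np.full(n, p)
    else:
        k = cfg.early_fraction_kappa
        frac = rng.beta(max(k * p, 1e-9), max(k * (1 - p), 1e-9), n)
    early = np.round(frac * totals).astype(int)
    out["early_count"] = early
    out["late_count"] = totals - early
    out["total_count"] = totals
    return out


def simulate_well_plate(
    config: PhenotypeSimConfig,
    condition: str = "control",
    concentration_uM: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a worm-level phenotype table and plate map for one condition.

    Hierarchy: biological-replicate effect x well effect x worm-level noise,
    with independent lognormal effects per endpoint family (length, area,
    volume, embryo production).  ``total_count == early_count + late_count``
    by construction.  Deterministic given the config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    fams = ("length_um", "area_um2", "volume_um3", "embryo")
    rows = []
    for rep in range(1, config.n_replicates + 1):
        rep_f = {f: _lognormal_factor(rng, config.between_replicate_cv) for f in fams}
        for w in range(1, config.wells_per_condition + 1):
            well_f = {f: _lognormal_factor(rng, config.between_well_cv) for f in fams}
            draws = _sample_worms(rng, config, config.worms_per_well, rep_f, well_f)
            for i in range(config.worms_per_well):
                rows.append({
                    "experiment": f"exp{rep}",
                    "replicate": rep,
                    "well": f"{condition}-W{w:02d}",
                    "channel": i + 1,
                    "worm_id": f"exp{rep}-{condition}-W{w:02d}-c{i + 1:02d}",
                    "classification": "full",
                    "length_um": draws["length_um"][i],
                    "area_um2": draws["area_um2"][i],
                    "volume_um3": draws["volume_um3"][i],
                    "early_count": draws["early_count"][i],
                    "late_count": draws["late_count"][i],
                    "total_count": draws["total_count"][i],
                })
    worms = pd.DataFrame(rows)
    plate = pd.DataFrame([
        {
            "well": f"{condition}-W{w:02d}",
            "condition": condition,
            "concentration_uM": concentration_uM,
            "chemical": condition,
            "solvent": "1% DMSO",
        }
        for w in range(1, config.wells_per_condition + 1)
    ])
    return worms, plate


def simulate_dose_plate(
    config: PhenotypeSimConfig,
    concentrations: Sequence[float],
    ec50: dict[str, float],
    hill: dict[str, float] | float = 2.0,
    bottom: dict[str, float] | None = None,
    chemical: str = "toxicant",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentration series: per-endpoint means follow a true 4PL curve.

    ``ec50``/``hill``/``bottom`` are per-endpoint (keys among length_um,
    area_um2, volume_um3, early_count, late_count); endpoints not listed stay
    at baseline.  Each concentration gets ``wells_per_condition`` wells per
    replicate.  Returns (worm table, plate map).
    """
    if any(c < 0 for c in concentrations):
        raise ValueError("negative concentrations")
    if isinstance(hill, (int, float)):
        hill = {k: float(hill) for k in ec50}
    bottom = bottom or {}
    baselines = {
        "length_um": config.length_mean,
        "area_um2": config.area_mean,
        "volume_um3": config.volume_mean,
        "early_count": config.early_mean,
        "late_count": config.late_mean,
    }
    fams = ("length_um", "area_um2", "volume_um3", "embryo")
    rng = np.random.default_rng(config.seed)
    rows, plate_rows = [], []
    for ci, conc in enumerate(concentrations):
        scale = {}
        for ep, e50 in ec50.items():
            top = baselines[ep]
            bot = bottom.get(ep, 0.0)
            scale[ep] = fourpl(conc, top, bot, e50, hill[ep]) / top
        cond = f"{chemical}-{ci:02d}"
        for rep in range(1, config.n_replicates + 1):
            rep_f = {f: _lognormal_factor(rng, config.between_replicate_cv) for f in fams}
            for w in range(1, config.wells_per_condition + 1):
                well_f = {f: _lognormal_factor(rng, config.between_well_cv) for f in fams}
                draws = _sample_worms(rng, config, config.worms_per_well, rep_f, well_f, scale)
                for i in range(config.worms_per_well):
                    rows.append({
                        "experiment": f"exp{rep}",
                        "replicate": rep,
                        "well": f"{cond}-W{w:02d}",
                        "channel": i + 1,
                        "worm_id": f"exp{rep}-{cond}-W{w:02d}-c{i + 1:02d}",
                        "classification": "full",
                        "length_um": draws["length_um"][i],
                        "area_um2": draws["area_um2"][i],
                        "volume_um3": draws["volume_um3"][i],
                        "early_count": draws["early_count"][i],
                        "late_count": draws["late_count"][i],
                        "total_count": draws["total_count"][i],
                    })
        for w in range(1, config.wells_per_condition + 1):
            plate_rows.append({
                "well": f"{cond}-W{w:02d}",
                "condition": cond,
                "concentration_uM": conc,
                "chemical": chemical,
                "solvent": "1% DMSO",
            })
    return pd.DataFrame(rows), pd.DataFrame(plate_rows)


@dataclass(frozen=True)
class ConcResponseSimConfig:
    """Well-level concentration-response draws around a true 4PL curve."""

    top: float = 45.0
    bottom: float = 0.0
    hill: float = 2.0
    ec50: float = 1.5
    concentrations: tuple[float, ...] = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    noise_cv: float = 0.05
    replicates: int = 3
    endpoint: str = "value"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hill <= 0:
            raise ValueError("hill must be > 0 (decreasing response)")
        if self.bottom > self.top:
            raise ValueError("bottom must be <= top")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("negative concentrations")
        if len(set(self.concentrations)) < 5:
            raise ValueError("need >= 5 distinct concentrations")


def simulate_conc_response(config: ConcResponseSimConfig) -> pd.DataFrame:
    """Tidy (concentration, replicate, value) table; value = 4PL(c) * (1 + noise).

    At c = 0 the expected value is Top exactly (the 4PL power term vanishes
    for positive Hill slope).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for c in config.concentrations:
        mu = fourpl(c, config.top, config.bottom, config.ec50, config.hill)
        for r in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0
            rows.append({"concentration": c, "replicate": r, "value": mu * (1.0 + eps)})
    return pd.DataFrame(rows)


def plant_outliers(
    table: pd.DataFrame,
    fraction: float,
    displacement: float = 10.0,
    seed: int = 0,
    endpoints: tuple[str, ...] = ("volume_um3", "total_count"),
    group_cols: tuple[str, ...] = ("experiment", "well"),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Displace a random fraction of worms by ``displacement`` x group IQR.

    Emulates debris (shed cuticle, egg clumps) inflating body-volume and
    embryo-count readings.  Displacement is upward so planted counts stay
    valid non-negative integers; the embryo-count invariant
    ``total = early + late`` is preserved by adding the excess to the late
    count.  Returns (table, truth labels).  Deterministic given the seed;
    ``fraction == 0`` returns the table unchanged.
    """
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must be in [0, 0.5)")
    out = table.copy(deep=True)
    labels = np.zeros(len(out), dtype=bool)
    if fraction == 0 or len(out) == 0:
        return out, labels
    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(out)))
    idx = rng.choice(len(out), size=n_plant, replace=False)
    labels[idx] = True
    grouped = out.groupby(list(group_cols))
    iqr = {}
    for ep in endpoints:
        q = grouped[ep].quantile([0.25, 0.75]).unstack()
        iqr[ep] = (q[0.75] - q[0.25]).to_dict()
    for i in idx:
        row = out.iloc[i]
        key = tuple(row[c] for c in group_cols)
        key = key[0] if len(key) == 1 else key
        which = rng.integers(0, 3)  # 0: first endpoint, 1: second, 2: both
        chosen = [endpoints[0]] if which == 0 else [endpoints[1]] if which == 1 else list(endpoints)
        for ep in chosen:
            delta = displacement * iqr[ep][key]
            if ep.endswith("_count"):
                delta = int(round(delta))
                out.iat[i, out.columns.get_loc(ep)] = row[ep] + delta
                if ep == "total_count" and "late_count" in out.columns:
                    out.iat[i, out.columns.get_loc("late_count")] = row["late_count"] + delta
            else:
                out.iat[i, out.columns.get_loc(ep)] = row[ep] + delta
    return out, labels


# ---------------------------------------------------------------------------
# annotation fixtures and file I/O


ANNOTATION_COLUMNS = [
    "experiment", "well", "channel", "worm_id", "x_um", "y_um", "z_index",
    "stage", "scorer_id", "timestamp", "unscorable", "reason",
]


def annotations_from_truth(
    truths: Iterable[GroundTruth],
    experiment: str = "exp1",
    well: str = "W01",
    scorer_id: str = "synthetic",
) -> pd.DataFrame:
    """Embryo-marker table reproducing each GroundTruth's records exactly."""
    rows = []
    for truth in truths:
        for j, (x, y, z, stage) in enumerate(truth.embryo_records):
            rows.append({
                "experiment": experiment, "well": well, "channel": truth.channel_id,
                "worm_id": f"{experiment}-{well}-{truth.channel_id}",
                "x_um": x, "y_um": y, "z_index": z, "stage": stage,
                "scorer_id": scorer_id, "timestamp": "2025-01-01T00:00:00",
                "unscorable": False, "reason": "",
            })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def annotations_from_counts(worms: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic marker table matching a worm table's early/late counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, w in worms.iterrows():
        for stage, n in (("early", int(w["early_count"])), ("late", int(w["late_count"]))):
            for j in range(n):
                rows.append({
                    "experiment": w["experiment"], "well": w["well"],
                    "channel": w["channel"], "worm_id": w["worm_id"],
                    "x_um": float(rng.uniform(0, 100)),
                    "y_um": float(rng.uniform(0, 1500)),
                    "z_index": int(rng.integers(0, 18)),
                    "stage": stage, "scorer_id": "synthetic",
                    "timestamp": "2025-01-01T00:00:00",
                    "unscorable": False, "reason": "",
                })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_stack_tiff(stack: ZStack, path: str | Path) -> None:
    """Multi-page TIFF with pixel-size resolution tags and z-step metadata."""
    res = 1.0 / stack.pixel_size  # pixels per um
    tifffile.imwrite(
        str(path), stack.data, resolution=(res, res),
        metadata={"spacing": stack.z_step, "unit": "um", **stack.metadata},
    )


def read_stack_tiff(path: str | Path, pixel_size: float = 0.425, z_step: float = 6.0) -> ZStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return ZStack(data, pixel_size=pixel_size, z_step=z_step, metadata={"path": str(path)})


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """Ground-truth sidecar (mask excluded; summary + embryo records)."""
    payload = {
        "channel_id": truth.channel_id,
        "classification": truth.classification,
        "true_length_um": truth.true_length,
        "true_area_um2": truth.true_area,
        "true_volume_um3": truth.true_volume,
        "true_best_focus": truth.true_best_focus,
        "axial_origin_um": truth.axial_origin,
        "n_early": truth.n_early,
        "n_late": truth.n_late,
        "n_total": truth.n_total,
        "embryo_records": [
            {"x_um": x, "y_um": y, "z_index": z, "stage": st}
            for x, y, z, st in truth.embryo_records
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
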