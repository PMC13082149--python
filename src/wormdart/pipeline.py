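"""End-to-end orchestration of the 3-day DART assay analysis.

``run_pipeline`` ties the stages together — body-measurement ingestion (or
image analysis), embryo-count ingestion, merging, outlier filtering, well
aggregation, repeatability, SSMD, concentration-response fitting and
endpoint ranking — writing wells.csv, repeatability.csv, fits.json,
comparison.json and report.md into the output directory.  Runs are
deterministic given (config, seed), every stage logs row counts in/out, and
the row-conservation audit reconciles exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip as chipmod
from . import embryos as embmod
from . import imaging as immod
from . import stats as statsmod

log = logging.getLogger("wormdart")

__all__ = ["RunConfig", "run_pipeline", "plan_report", "analyze_images", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class RunConfig:
    """Validated run configuration (paths, filtering and fitting parameters)."""

    plate_map: str
    out_dir: str
    body_table: str | None = None
    annotations: str | None = None
    worm_table: str | None = None  # pre-merged six-endpoint table (skips merge)
    images_dir: str | None = None
    chip: str = "d1.chip"
    plan: str = "minimal.plan"
    filter_k: float = 1.5
    filter_endpoints: tuple[str, ...] = ("volume_um3", "total_count")
    bottoms: dict = field(default_factory=statsmod.l1_bottom_constraints)
    f_values: tuple[float, ...] = (10.0, 25.0, 50.0)
    positive_control_uM: float | None = None
    combo_k: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.plate_map).exists():
            raise FileNotFoundError(f"plate map not found: {self.plate_map}")
        if self.worm_table is None and (self.body_table is None or self.annotations is None) \
                and self.images_dir is None:
            raise ValueError(
                "config must provide worm_table, or body_table + annotations"
            )
        for name in ("body_table", "annotations", "worm_table", "images_dir"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} not found: {p}")
        missing = [e for e in statsmod.ENDPOINTS if e not in self.bottoms]
        if missing:
            raise ValueError(f"bottom constraints missing for: {missing}")


def plan_report(plan: chipmod.ImagingPlan) -> dict:
    """Human-readable acquisition accounting for an imaging plan."""
    per_well = plan.fiduciary_frames_per_well + (
        plan.fovs_per_well * plan.z_slices * plan.volumes_per_fov
    )
    total = chipmod.plan_image_count(plan)
    lines = [
        f"wells: {plan.wells}",
        f"FOVs per well: {plan.fovs_per_well}",
        f"z-slices per FOV: {plan.z_slices} at {plan.z_step} um step",
        f"volumes per FOV: {plan.volumes_per_fov}",
        f"fiduciary frames per well: {plan.fiduciary_frames_per_well}",
        f"images per well: {per_well}",
        f"total images: {total}",
    ]
    return {"images_per_well": per_well, "total_images": total,
            "text": "\n".join(lines)}


def analyze_images(
    images_dir: str | Path,
    geometry: chipmod.ChannelGeometry,
    plan: chipmod.ImagingPlan | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Measure every channel stack in a directory into a body table.

    Stacks are multi-page TIFFs named ``{experiment}_{well}_{channel}.tif``
    with an optional ``*.meta.json`` sidecar carrying the crop's axial
    origin (um from the channel entrance, known from the chip map at
    acquisition time).  Per channel: best focus, full/partial/none
    classification, segmentation, and the three body endpoints.
    """
    from .synthetic import read_stack_tiff  # local import to avoid a cycle

    plan = plan or chipmod.minimal_plan()
    rows = []
    paths = sorted(Path(images_dir).glob("*.tif*"))
    if not paths:
        raise FileNotFoundError(f"no TIFF stacks in {images_dir}")
    for p in paths:
        parts = p.stem.split("_")
        if len(parts) < 3:
            log.warning("skipping %s: expected {experiment}_{well}_{channel}", p.name)
            continue
        experiment, well, channel = parts[0], parts[1], parts[2]
        meta_path = p.with_suffix("").with_suffix(".meta.json") \
            if p.suffix else p
        meta_path = p.parent / (p.stem + ".meta.json")
        axial_origin = 0.0
        if meta_path.exists():
            axial_origin = float(json.loads(meta_path.read_text()).get("axial_origin_um", 0.0))
        stack = read_stack_tiff(p, pixel_size=plan.pixel_size, z_step=plan.z_step)
        crop = immod.ChannelCrop(stack, channel, axial_origin, geometry)
        row = {"experiment": experiment, "well": well, "channel": channel,
               "worm_id": f"{experiment}-{well}-{channel}",
               "segmentation_failed": False}
        try:
            bf = immod.best_focus_index(stack)
        except immod.FocusError:
            row.update(classification="none", best_focus_z=None)
            rows.append(row)
            continue
        label, flags = immod.classify_channel(crop, best_focus=bf)
        row.update(classification=label, best_focus_z=bf, **{
            f"flag_{k}": v for k, v in flags.items()})
        if label == immod.FULL:
            mask, seg_flags = immod.segment_worm(crop, bf)
            if seg_flags.get("segmentation_failed"):
                row["segmentation_failed"] = True
            else:
                length, area, volume = immod.measure_body(
                    mask, geometry, axial_origin, stack.pixel_size)
                row.update(length_um=length, area_um2=area, volume_um3=volume)
        rows.append(row)
    out = pd.DataFrame(rows)
    log.info("analyzed %d channels: %s", len(out),
             out["classification"].value_counts().to_dict())
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis flow; returns the artifact bundle.

    Stages: load -> merge -> filter -> aggregate -> repeatability -> SSMD ->
    ANOVA -> 4PL fits + EC table -> endpoint ranking -> report.  Any stage
    failure aborts with a stage-attributed :class:`StageError`; artifacts
    already written are retained.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    # ----- load & merge -------------------------------------------------
    name = stage("load")
    try:
        plate = pd.read_csv(config.plate_map)
        if config.worm_table is not None:
            worms = pd.read_csv(config.worm_table)
            audit = {"input_rows": len(worms), "output_rows": len(worms),
                     "partial_or_none": 0, "segmentation_failed": 0,
                     "unscorable": 0, "unscored": 0}
            if "condition" not in worms.columns:
                worms = worms.merge(plate, on="well", how="left")
        else:
            if config.images_dir is not None and config.body_table is None:
                geometry = chipmod.load_chip(config.chip)
                plan = chipmod.load_plan(config.plan)
                body = analyze_images(config.images_dir, geometry, plan)
            else:
                body = pd.read_csv(config.body_table)
            ann = embmod.ingest_annotations(config.annotations)
            counts = embmod.counts_per_worm(ann)
            worms, audit = embmod.merge_phenotypes(body, counts, plate)
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e
    artifacts["audit"] = audit
    log.info("merge audit: %s", audit)

    # ----- filter & aggregate -------------------------------------------
    name = stage("filter")
    try:
        kept, excluded = statsmod.tukey_filter(
            worms, endpoints=config.filter_endpoints, k=config.filter_k)
        n_before = worms.groupby(["experiment", "well"]).size()
        wells = statsmod.well_means(kept, n_before=n_before)
        wells = wells.sort_values(["experiment", "well"]).reset_index(drop=True)
        wells.to_csv(out_dir / "wells.csv", index=False, float_format="%.6g")
        audit["filtered_out"] = len(excluded)
        audit["worms_kept"] = len(kept)
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e
    artifacts["wells"] = wells
    artifacts["excluded"] = excluded
    log.info("filtered %d/%d worms", len(excluded), len(worms))

    # ----- repeatability -------------------------------------------------
    name = stage("repeatability")
    try:
        n_reps = wells.groupby("well")["experiment"].nunique()
        repeat_rows = []
        if (n_reps >= config.combo_k).all() and wells["experiment"].nunique() >= config.combo_k:
            results = statsmod.combo_cv_analysis(wells, k=config.combo_k)
            for r in results:
                repeat_rows.append({
                    "endpoint": r.endpoint, "condition": r.condition,
                    "mean_cv_pct": r.mean_cv, "sem_cv_pct": r.sem_cv,
                    "n_combinations": len(r.cvs), "k": r.k,
                    "n_replicates": r.n_replicates,
                })
        repeatability = pd.DataFrame(repeat_rows)
        repeatability.to_csv(out_dir / "repeatability.csv", index=False,
                             float_format="%.6g")
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e
    artifacts["repeatability"] = repeatability

    # ----- SSMD vs positive control --------------------------------------
    name = stage("ssmd")
    ssmd_rows = []
    try:
        if config.positive_control_uM is not None:
            ctrl = wells[wells["concentration_uM"] == 0]
            pos = wells[wells["concentration_uM"] == config.positive_control_uM]
            if len(ctrl) >= 2 and len(pos) >= 2:
                for ep in statsmod.ENDPOINTS:
                    if ep not in wells.columns:
                        continue
                    r = statsmod.ssmd(ctrl[ep].dropna(), pos[ep].dropna())
                    ssmd_rows.append({"endpoint": ep, "ssmd": r.value,
                                      "quality": r.quality})
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e
    artifacts["ssmd"] = pd.DataFrame(ssmd_rows)

    # ----- ANOVA across solvent conditions -------------------------------
    name = stage("anova")
    anova_rows = []
    try:
        if "condition" in wells.columns:
            ctrl_wells = wells[wells["concentration_uM"] == 0]
            conds = ctrl_wells["condition"].unique()
            if len(conds) >= 2:
                for ep in statsmod.ENDPOINTS:
                    if ep not in wells.columns:
                        continue
                    groups = [
                        ctrl_wells[ctrl_wells["condition"] == c][ep].dropna()
                        for c in conds
                    ]
                    groups = [g for g in groups if len(g) >= 2]
                    if len(groups) >= 2:
                        F, p = statsmod.oneway_anova(groups)
                        anova_rows.append({"endpoint": ep, "F": F, "p": p,
                                           "stars": statsmod.p_stars(p)})
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e
    artifacts["anova"] = pd.DataFrame(anova_rows)

    # ----- concentration-response fits ------------------------------------
    name = stage("fit")
    fits: dict = {}
    fit_json: dict = {}
    try:
        if "concentration_uM" in wells.columns and \
                wells["concentration_uM"].nunique() >= 5:
            for ep in statsmod.ENDPOINTS:
                if ep not in wells.columns:
                    continue
                sub = wells.dropna(subset=[ep])
                try:
                    fit = statsmod.fit_4pl(
                        sub["concentration_uM"], sub[ep],
                        bottom=config.bottoms[ep])
                except (statsmod.UnidentifiableFitError, ValueError) as err:
                    fit_json[ep] = {"error": str(err)}
                    continue
                fits[ep] = fit
                ecs = {}
                for F in config.f_values:
                    est = statsmod.ec_f(fit, F)
                    ecs[f"EC{F:g}"] = {"value": est.value, "ci95": [est.ci_low, est.ci_high]}
                fit_json[ep] = {
                    "top": fit.top, "bottom": fit.bottom,
                    "ec50_uM": fit.ec50, "hill": fit.hill,
                    "ssr": fit.ssr, "dof": fit.dof, "ec": ecs,
                }
        _write_json(fit_json, out_dir / "fits.json")
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e
    artifacts["fits"] = fits

    # ----- endpoint ordering ----------------------------------------------
    name = stage("rank")
    try:
        comparison: dict = {}
        if len(fits) >= 2:
            ranking = statsmod.normalize_and_rank(fits, F=10.0)
            comparison["ec10_ordering"] = ranking[
                ["endpoint", "ec_f", "ci_low", "ci_high", "ci_overlaps_next"]
            ].to_dict(orient="records")
            artifacts["ranking"] = ranking
        _write_json(comparison, out_dir / "comparison.json")
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e

    # ----- report ----------------------------------------------------------
    name = stage("report")
    try:
        lines = ["# DART assay report", ""]
        lines += ["## Row-conservation audit", ""]
        for k in sorted(audit):
            lines.append(f"- {k}: {audit[k]}")
        recon = (audit["input_rows"]
                 == audit["output_rows"] + audit["partial_or_none"]
                 + audit["segmentation_failed"] + audit["unscorable"]
                 + audit["unscored"])
        lines.append(f"- reconciles: {recon}")
        lines += ["", "## Well summaries", "",
                  f"{len(wells)} wells; see wells.csv", ""]
        if len(repeatability):
            lines += ["## Repeatability (CV% over replicate combinations)", ""]
            for _, r in repeatability.iterrows():
                sem = f" +/- {r['sem_cv_pct']:.2f}" if pd.notna(r["sem_cv_pct"]) else ""
                lines.append(
                    f"- {r['condition']} / {r['endpoint']}: "
                    f"{r['mean_cv_pct']:.2f}%{sem} "
                    f"({int(r['n_combinations'])} combinations)")
            lines.append("")
        if ssmd_rows:
            lines += ["## SSMD vs positive control", ""]
            for r in ssmd_rows:
                lines.append(f"- {r['endpoint']}: {r['ssmd']:.2f} ({r['quality']})")
            lines.append("")
        if anova_rows:
            lines += ["## One-way ANOVA across solvent conditions", ""]
            for r in anova_rows:
                lines.append(f"- {r['endpoint']}: F = {r['F']:.3g}, "
                             f"p = {r['p']:.3g} {r['stars']}")
            lines.append("")
        if fit_json:
            lines += ["## Concentration-response (4PL)", ""]
            for ep in sorted(fit_json):
                d = fit_json[ep]
                if "error" in d:
                    lines.append(f"- {ep}: fit failed ({d['error']})")
                    continue
                ec50 = d["ec50_uM"]
                lines.append(f"- {ep}: EC50 = {ec50:.3g} uM, hill = {d['hill']:.3g}")
                for name_, e in d["ec"].items():
                    lines.append(
                        f"    - {name_} = {e['value']:.3g} uM "
                        f"(95% CI {e['ci95'][0]:.3g}-{e['ci95'][1]:.3g})")
            lines.append("")
        if "ranking" in artifacts:
            lines += ["## Endpoint sensitivity (ascending EC10)", ""]
            for _, r in artifacts["ranking"].iterrows():
                flag = " (CI overlaps next)" if r["ci_overlaps_next"] else ""
                lines.append(f"- {r['endpoint']}: EC10 = {r['ec_f']:.3g} uM{flag}")
            lines.append("")
        (out_dir / "report.md").write_text("\n".join(lines))
    except Exception as e:  # noqa: BLE001
        raise StageError(name, e) from e

    artifacts["out_dir"] = out_dir
    return artifacts
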