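"""File-based embryo scoring: annotation validation, per-worm counts, and the
merge into the worm-level DART table.

In-utero embryos are marked manually (one marker per embryo, classified
early or late relative to the 2-fold elongation stage) and stored as CSV.
This module validates those annotation files, aggregates them into per-worm
early/late/total counts, and joins them with the body-measurement table and
plate map to produce the six-endpoint worm-level table the statistics layer
consumes.  ``total = early + late`` holds for every output row, and the
merge is lossless modulo explicitly counted drops (failed segmentation,
unscorable worms, partial/absent worms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ANNOTATION_SCHEMA",
    "AnnotationError",
    "ingest_annotations",
    "counts_per_worm",
    "merge_phenotypes",
    "WORM_KEY",
]

ANNOTATION_SCHEMA = [
    "experiment", "well", "channel", "worm_id", "x_um", "y_um", "z_index",
    "stage", "scorer_id", "timestamp", "unscorable", "reason",
]
WORM_KEY = ["experiment", "well", "channel"]
STAGES = ("early", "late")


class AnnotationError(ValueError):
    """Annotation file failed validation; ``errors`` lists line-numbered messages."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors[:10]) + ("" if len(errors) <= 10 else " ..."))


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, np.integer, float)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")


def ingest_annotations(path: str | Path, z_max: int | None = None) -> pd.DataFrame:
    """Read and validate an embryo-annotation CSV.

    Every record is checked for schema completeness, stage vocabulary,
    numeric coordinates and z range; all violations are collected and raised
    together as :class:`AnnotationError` with 1-based file line numbers
    (line 1 is the header).  Exact duplicate markers (same worm and x, y, z)
    are deduplicated with a warning; the same marker carrying two different
    stages is an error.  An empty file with a valid header yields an empty
    table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_SCHEMA if c not in df.columns]
    if missing:
        raise AnnotationError([f"header missing columns: {', '.join(missing)}"])
    errors: list[str] = []
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        unscorable = _as_bool(row["unscorable"])
        rec = {c: row[c] for c in ANNOTATION_SCHEMA}
        rec["unscorable"] = unscorable
        for key in WORM_KEY + ["worm_id"]:
            if str(row[key]).strip() == "":
                errors.append(f"line {line}: missing {key}")
        if unscorable:
            records.append(rec)
            continue
        if row["stage"] not in STAGES:
            errors.append(f"line {line}: unknown stage {row['stage']!r}")
        for coord in ("x_um", "y_um"):
            try:
                rec[coord] = float(row[coord])
            except ValueError:
                errors.append(f"line {line}: non-numeric {coord} {row[coord]!r}")
        try:
            z = int(float(row["z_index"]))
            rec["z_index"] = z
            if z < 0 or (z_max is not None and z >= z_max):
                errors.append(f"line {line}: z_index {z} outside stack range")
        except ValueError:
            errors.append(f"line {line}: non-numeric z_index {row['z_index']!r}")
        records.append(rec)
    if errors:
        raise AnnotationError(errors)
    out = pd.DataFrame(records, columns=ANNOTATION_SCHEMA)
    if len(out):
        marker_key = WORM_KEY + ["worm_id", "x_um", "y_um", "z_index"]
        scored = out[~out["unscorable"]]
        dup = scored.duplicated(subset=marker_key, keep=False)
        if dup.any():
            conflicting = (
                scored[dup].groupby(marker_key)["stage"].nunique()
            )
            if (conflicting > 1).any():
                raise AnnotationError(
                    ["duplicate marker with conflicting stages "
                     f"({int((conflicting > 1).sum())} marker position(s))"]
            )
            n_dropped = int(scored.duplicated(subset=marker_key).sum())
            warnings.warn(f"deduplicated {n_dropped} exact duplicate marker(s)")
            out = pd.concat([
                scored.drop_duplicates(subset=marker_key),
                out[out["unscorable"]],
            ]).sort_index()
    return out.reset_index(drop=True)


def counts_per_worm(
    records: pd.DataFrame,
    scored_worms: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate validated markers into per-worm early/late/total counts.

    Worms flagged unscorable (e.g. intestinal obstruction of the uterus)
    are excluded from counting but returned with ``unscorable = True`` and
    the reason propagated, so downstream merging can attribute the drop.
    ``total = early + late`` for every scored worm.

    ``scored_worms`` (optional; columns ``experiment, well, channel`` and
    optionally ``worm_id``) lists worms a scorer actually reviewed: any of
    them without a marker gets explicit zero counts instead of being treated
    as unscored.
    """
    if scored_worms is not None:
        base = counts_per_worm(records, None)
        extra = scored_worms.copy()
        for c in WORM_KEY:
            extra[c] = extra[c].astype(str)
        have = set(map(tuple, base[WORM_KEY].astype(str).to_numpy())) if len(base) else set()
        rows = []
        for _, w in extra.iterrows():
            key = tuple(w[c] for c in WORM_KEY)
            if key in have:
                continue
            rows.append(dict(zip(WORM_KEY, key),
                             worm_id=w.get("worm_id", "-".join(key)),
                             early_count=0, late_count=0, total_count=0,
                             unscorable=False, reason=""))
        if rows:
            base = pd.concat([base, pd.DataFrame(rows, columns=base.columns)],
                             ignore_index=True)
        return base
    if len(records) == 0:
        return pd.DataFrame(columns=WORM_KEY + [
            "worm_id", "early_count", "late_count", "total_count",
            "unscorable", "reason"])
    unscorable_keys = (
        records[records["unscorable"]]
        .groupby(WORM_KEY)
        .agg(worm_id=("worm_id", "first"), reason=("reason", "first"))
        .reset_index()
    )
    scored = records[~records["unscorable"]]
    # a worm flagged unscorable by any marker carries no counts downstream
    if len(unscorable_keys):
        flagged = unscorable_keys[WORM_KEY].apply(tuple, axis=1)
        keys = scored[WORM_KEY].apply(tuple, axis=1)
        scored = scored[~keys.isin(set(flagged))]
    rows = []
    if len(scored):
        for key, grp in scored.groupby(WORM_KEY, sort=False):
            early = int((grp["stage"] == "early").sum())
            late = int((grp["stage"] == "late").sum())
            rows.append(dict(zip(WORM_KEY, key), worm_id=grp["worm_id"].iloc[0],
                             early_count=early, late_count=late,
                             total_count=early + late, unscorable=False, reason=""))
    out = pd.DataFrame(rows, columns=WORM_KEY + [
        "worm_id", "early_count", "late_count", "total_count", "unscorable", "reason"])
    if len(unscorable_keys):
        un = unscorable_keys.assign(
            early_count=pd.NA, late_count=pd.NA, total_count=pd.NA,
            unscorable=True)
        out = pd.concat([out, un[out.columns]], ignore_index=True)
    return out


def merge_phenotypes(
    body: pd.DataFrame,
    embryo_counts: pd.DataFrame,
    plate_map: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join body measurements, embryo counts and the plate map per worm.

    Keeps only worms classified ``full`` with a valid segmentation mask and
    scored embryos; every dropped row is attributed in the returned audit
    dict (``partial_or_none``, ``segmentation_failed``, ``unscorable``,
    ``unscored``) so that input rows = output rows + drops.  Raises when a
    well present in the data is missing from the plate map.
    """
    audit = {"input_rows": len(body)}
    body = body.copy()
    embryo_counts = embryo_counts.copy()
    plate_map = plate_map.copy()
    for col in WORM_KEY:  # merge keys may arrive as int or str depending on source
        body[col] = body[col].astype(str)
        embryo_counts[col] = embryo_counts[col].astype(str)
    plate_map["well"] = plate_map["well"].astype(str)
    data_wells = set(body["well"].unique())
    map_wells = set(plate_map["well"].unique())
    unmapped = data_wells - map_wells
    if unmapped:
        raise ValueError(f"wells absent from plate map: {sorted(unmapped)}")

    is_full = body["classification"] == "full"
    audit["partial_or_none"] = int((~is_full).sum())
    kept = body[is_full]
    if "segmentation_failed" in kept.columns:
        failed = kept["segmentation_failed"].map(_as_bool)
        audit["segmentation_failed"] = int(failed.sum())
        kept = kept[~failed]
    else:
        audit["segmentation_failed"] = 0

    emb = embryo_counts.copy()
    unscorable = emb[emb["unscorable"]]
    audit["unscorable"] = int(
        kept.merge(unscorable[WORM_KEY], on=WORM_KEY, how="inner").shape[0]
    )
    emb = emb[~emb["unscorable"]]
    emb_cols = WORM_KEY + ["early_count", "late_count", "total_count"]
    merged = kept.merge(emb[emb_cols], on=WORM_KEY, how="inner",
                        suffixes=("_body", ""))
    audit["unscored"] = len(kept) - audit["unscorable"] - len(merged)
    merged = merged.merge(plate_map, on="well", how="left")
    audit["output_rows"] = len(merged)
    assert (merged["total_count"] == merged["early_count"] + merged["late_count"]).all(), \
        "embryo count invariant violated: total != early + late"
    return merged.reset_index(drop=True), audit
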