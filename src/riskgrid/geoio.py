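"""Reading, validating and writing the vector + tabular layers of the pipeline.

All geometry is planar, in an equal-area coordinate frame in metres. Real
data must be pre-projected; this module never reprojects. GeoJSON files may
declare their frame in a top-level ``crs_note`` member, which is compared
across files when ``crs_check`` is on but otherwise treated as free text.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from shapely import make_valid, unary_union
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

GROUPS = (
    "birds",
    "mammals",
    "reptiles",
    "amphibians",
    "arthropods",
    "molluscs",
    "vascular_plants",
    "mosses",
    "lichens",
)
NATIONAL_STATUSES = ("special_concern", "threatened", "endangered", "none")
GLOBAL_STATUSES = ("vulnerable", "endangered_g", "critically_endangered", "none")

TAXA_TABLE_COLUMNS = (
    "taxon_id",
    "name",
    "group",
    "national_status",
    "global_status",
    "assessment_year",
)


class ValidationError(ValueError):
    """Attribute/geometry consistency violation in the input bundle."""


@dataclass
class Taxon:
    """One assessed unit (species, subspecies or population).

    A taxon listed both nationally and globally is a single record with both
    statuses set; at least one status must differ from ``none``. Ranges are
    polygons/multipolygons in the shared planar frame; ``hemisphere_range``
    may be absent (such taxa are skipped by peripherality analyses).
    """

    taxon_id: str
    name: str
    group: str
    national_status: str = "none"
    global_status: str = "none"
    assessment_year: int | None = None
    focal_range: BaseGeometry | None = None
    hemisphere_range: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"taxon {self.taxon_id!r}: unknown group {self.group!r}")
        if self.national_status not in NATIONAL_STATUSES:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown national_status {self.national_status!r}"
            )
        if self.global_status not in GLOBAL_STATUSES:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown global_status {self.global_status!r}"
            )
        if self.national_status == "none" and self.global_status == "none":
            raise ValidationError(
                f"taxon {self.taxon_id!r}: both national and global status are 'none'"
            )

    @property
    def nationally_at_risk(self) -> bool:
        return self.national_status != "none"

    @property
    def globally_at_risk(self) -> bool:
        return self.global_status != "none"


@dataclass
class StudyLayers:
    """The full spatial bundle: focal region, hemisphere mask, protected
    areas (clipped to the focal region on load) and the taxa set."""

    focal_region: BaseGeometry
    hemisphere_mask: BaseGeometry
    protected_areas: list[BaseGeometry] = field(default_factory=list)
    taxa: list[Taxon] = field(default_factory=list)
    crs_note: str | None = None

    @property
    def protected_union(self) -> BaseGeometry:
        return unary_union(self.protected_areas) if self.protected_areas else shape(
            {"type": "MultiPolygon", "coordinates": []}
        )


def repair_geometry(geom: BaseGeometry) -> BaseGeometry:
    """Repair an invalid polygon, preserving total enclosed area.

    Digitized range maps routinely contain bowties and slivers. Repair uses
    make_valid rather than the zero-width-buffer trick: buffer(0) silently
    discards lobes whose ring winding is reversed (a bowtie would lose half
    its area), whereas make_valid splits the figure into valid parts keeping
    every enclosed region. Repairs are logged so cleaning can be audited.
    """
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    logger.info("repaired invalid geometry (area %.6g -> %.6g)", geom.area, fixed.area)
    return fixed


def union_ranges(parts: Sequence[BaseGeometry]) -> BaseGeometry:
    """Merge several (e.g. seasonal) range polygons into one footprint.

    The union's area is at most the sum of part areas, with equality for
    pairwise-disjoint parts.
    """
    if len(parts) == 0:
        raise ValueError("union_ranges requires a non-empty list of polygons")
    return unary_union([repair_geometry(p) for p in parts])


# ---------------------------------------------------------------------------
# GeoJSON helpers (planar coordinates; RFC 7946 geometry objects)

def read_geojson(path: str | Path) -> tuple[list[tuple[dict, BaseGeometry]], str | None]:
    """Read a GeoJSON file, returning (properties, geometry) pairs and the
    file's crs_note (if declared)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    crs_note = doc.get("crs_note")
    feats: list[tuple[dict, BaseGeometry]] = []
    if doc.get("type") == "FeatureCollection":
        for f in doc.get("features", []):
            feats.append((f.get("properties") or {}, shape(f["geometry"])))
    elif doc.get("type") == "Feature":
        feats.append((doc.get("properties") or {}, shape(doc["geometry"])))
    else:  # bare geometry
        feats.append(({}, shape(doc)))
    return feats, crs_note


def write_geojson(
    path: str | Path,
    features: Iterable[tuple[Mapping, BaseGeometry]],
    crs_note: str | None = None,
) -> int:
    """Write (properties, geometry) pairs as a FeatureCollection; returns the
    feature count. Output is deterministic (sorted keys, fixed separators)."""
    feats = [
        {"type": "Feature", "properties": dict(props), "geometry": mapping(geom)}
        for props, geom in features
    ]
    doc: dict = {"type": "FeatureCollection", "features": feats}
    if crs_note is not None:
        doc["crs_note"] = crs_note
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
    return len(feats)


def read_taxa_table(path: str | Path) -> list[dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"taxa table not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames or ()) != TAXA_TABLE_COLUMNS:
            raise ValidationError(
                f"taxa table header must be {','.join(TAXA_TABLE_COLUMNS)}; "
                f"got {reader.fieldnames}"
            )
        return list(reader)


# ---------------------------------------------------------------------------

def load_layers(
    paths: Mapping[str, str | Path],
    crs_check: bool = True,
    on_missing: str = "error",
) -> StudyLayers:
    """Load and validate a full input bundle.

    ``paths`` keys: ``focal_region``, ``hemisphere_mask``, ``protected_areas``,
    ``focal_ranges``, ``hemisphere_ranges`` (optional), ``taxa_table``.
    Range files are FeatureCollections keyed by a ``taxon_id`` property.

    ``on_missing`` controls taxa present in the table but lacking a focal
    range geometry: ``"error"`` raises a ValidationError listing the ids;
    ``"drop"`` removes them with a logged count (the attrition that occurs
    when source maps cannot be digitized).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")

    repairs = 0

    def load_union(key: str) -> tuple[BaseGeometry, str | None]:
        nonlocal repairs
        feats, note = read_geojson(paths[key])
        geoms = []
        for _, g in feats:
            if not g.is_valid:
                repairs += 1
            geoms.append(repair_geometry(g))
        return unary_union(geoms), note

    focal_region, note_f = load_union("focal_region")
    hemisphere_mask, note_h = load_union("hemisphere_mask")

    prot_feats, note_p = read_geojson(paths["protected_areas"])
    protected: list[BaseGeometry] = []
    for _, g in prot_feats:
        if not g.is_valid:
            repairs += 1
        clipped = repair_geometry(g).intersection(focal_region)
        if clipped.area > 0:
            protected.append(clipped)

    def load_ranges(key: str) -> tuple[dict[str, BaseGeometry], str | None]:
        nonlocal repairs
        if key not in paths:
            return {}, None
        feats, note = read_geojson(paths[key])
        out: dict[str, BaseGeometry] = {}
        for props, g in feats:
            tid = props.get("taxon_id")
            if tid is None:
                raise ValidationError(f"{key}: feature without taxon_id property")
            if not g.is_valid:
                repairs += 1
            g = repair_geometry(g)
            out[tid] = unary_union([out[tid], g]) if tid in out else g
        return out, note

    focal_ranges, note_rf = load_ranges("focal_ranges")
    hemi_ranges, note_rh = load_ranges("hemisphere_ranges")

    notes = {n for n in (note_f, note_h, note_p, note_rf, note_rh) if n is not None}
    if crs_check and len(notes) > 1:
        raise ValidationError(f"mixed coordinate-frame declarations: {sorted(notes)}")
    crs_note = next(iter(notes)) if notes else None

    rows = read_taxa_table(paths["taxa_table"])
    table_ids = {r["taxon_id"] for r in rows}
    orphans = sorted(set(focal_ranges) - table_ids)
    if orphans:
        raise ValidationError(f"range geometries without a table row: {orphans}")
    missing = sorted(table_ids - set(focal_ranges))
    if missing and on_missing == "error":
        raise ValidationError(f"table rows without a focal range geometry: {missing}")
    if missing:
        logger.info("dropping %d taxa lacking a focal range: %s", len(missing), missing)

    if hemisphere_mask.intersection(focal_region).area < focal_region.area * 0.999:
        raise ValidationError("focal_region is not contained in hemisphere_mask")

    taxa: list[Taxon] = []
    for r in rows:
        tid = r["taxon_id"]
        if tid not in focal_ranges:
            continue
        year = r["assessment_year"].strip()
        taxa.append(
            Taxon(
                taxon_id=tid,
                name=r["name"],
                group=r["group"],
                national_status=r["national_status"],
                global_status=r["global_status"],
                assessment_year=int(year) if year else None,
                focal_range=focal_ranges[tid],
                hemisphere_range=hemi_ranges.get(tid),
            )
        )
    for t in taxa:
        if t.focal_range.area <= 0:
            raise ValidationError(f"taxon {t.taxon_id!r}: focal range has zero area")

    if repairs:
        logger.info("repaired %d invalid geometries on load", repairs)

    return StudyLayers(
        focal_region=focal_region,
        hemisphere_mask=hemisphere_mask,
        protected_areas=protected,
        taxa=taxa,
        crs_note=crs_note,
    )


def write_taxa_table(path: str | Path, taxa: Sequence[Taxon]) -> int:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TAXA_TABLE_COLUMNS)
        for t in taxa:
            w.writerow(
                [
                    t.taxon_id,
                    t.name,
                    t.group,
                    t.national_status,
                    t.global_status,
                    "" if t.assessment_year is None else t.assessment_year,
                ]
            )
    return len(taxa)


def write_layers(layers: StudyLayers, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a StudyLayers bundle to the load_layers input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "focal_region": out / "focal_region.geojson",
        "hemisphere_mask": out / "hemisphere_mask.geojson",
        "protected_areas": out / "protected_areas.geojson",
        "focal_ranges": out / "focal_ranges.geojson",
        "hemisphere_ranges": out / "hemisphere_ranges.geojson",
        "taxa_table": out / "taxa.csv",
    }
    note = layers.crs_note
    write_geojson(paths["focal_region"], [({}, layers.focal_region)], note)
    write_geojson(paths["hemisphere_mask"], [({}, layers.hemisphere_mask)], note)
    write_geojson(
        paths["protected_areas"],
        [({"pa_id": i}, g) for i, g in enumerate(layers.protected_areas)],
        note,
    )
    write_geojson(
        paths["focal_ranges"],
        [({"taxon_id": t.taxon_id}, t.focal_range) for t in layers.taxa],
        note,
    )
    write_geojson(
        paths["hemisphere_ranges"],
        [
            ({"taxon_id": t.taxon_id}, t.hemisphere_range)
            for t in layers.taxa
            if t.hemisphere_range is not None
        ],
        note,
    )
    write_taxa_table(paths["taxa_table"], layers.taxa)
    return paths


# ---------------------------------------------------------------------------
# Pipeline output bundle

_FLOAT_FMT = "%.10g"


def _write_csv(df, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return len(df)


def write_outputs(result, out_dir: str | Path, seed: int | None = None) -> dict:
    """Write every pipeline product to ``out_dir`` and return the manifest.

    CSV for tabular products, GeoJSON for spatial ones, a plain-text run
    report, and a manifest listing each file with its row/feature count.
    Outputs are byte-identical across re-runs with the same inputs and seed.
    """
    from .hotspots import display_percent  # local import avoids a cycle

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    manifest: dict[str, dict] = {}

    def record(name: str, count: int) -> None:
        manifest[name] = {"rows_or_features": count}

    grid = result.grid
    record(
        "grid.geojson",
        write_geojson(
            out / "grid.geojson",
            [
                (
                    {
                        "cell_id": c.cell_id,
                        "row": c.row,
                        "col": c.col,
                        "land_area": c.land_area,
                        "protected_area": c.protected_area,
                    },
                    c.polygon,
                )
                for c in grid.cells
            ],
        ),
    )
    record("presence_matrix.csv", _write_csv(result.presence.to_frame(), out / "presence_matrix.csv"))
    record("taxon_metrics.csv", _write_csv(result.metrics, out / "taxon_metrics.csv"))
    record("peripherality_summary.csv", _write_csv(result.periph_summary, out / "peripherality_summary.csv"))
    record("cell_protection.csv", _write_csv(result.cell_protection.table, out / "cell_protection.csv"))

    cell_lookup = {c.cell_id: c for c in grid.cells}
    hs_rows = []
    for label, hs in result.hotspot_sets.items():
        fname = f"hotspots_{label}.geojson"
        record(
            fname,
            write_geojson(
                out / fname,
                [
                    (
                        {"cell_id": cid, "label": label, "threshold": hs.threshold},
                        cell_lookup[cid].polygon,
                    )
                    for cid in sorted(hs.cell_ids)
                ],
            ),
        )
        hs_rows.append(
            {
                "label": label,
                "threshold": -1 if hs.threshold is None else hs.threshold,
                "cap": hs.cap,
                "n_cells": len(hs.cell_ids),
            }
        )
    import pandas as pd

    record("hotspot_sets.csv", _write_csv(pd.DataFrame(hs_rows), out / "hotspot_sets.csv"))
    ov = result.overlap.to_frame().reset_index().rename(columns={"index": "label"})
    record("overlap_matrix.csv", _write_csv(ov, out / "overlap_matrix.csv"))

    coef_frames, lrt_rows, contrast_frames, ls_frames = [], [], [], []
    report_lines = [
        "riskgrid run report",
        f"seed: {seed}",
        f"cells: {grid.n_cells}; taxa: {len(result.layers.taxa)}",
        "assumptions: Smithson-Verkuilen squeeze for 0/1 responses; "
        "constant precision phi (no precision covariates)",
        "",
        f"mean off-diagonal hotspot overlap: "
        f"{display_percent(result.overlap.mean_offdiagonal)}%",
        "",
    ]
    for mid, mr in result.models.items():
        cf = mr.coefficient_frame()
        cf.insert(0, "model", mid)
        coef_frames.append(cf)
        report_lines.append(f"model {mid} (n={mr.n}): {'; '.join(mr.notes)}")
        for term, lr in mr.lrts.items():
            lrt_rows.append(
                {"model": mid, "term": term, "chi2": lr.chi2, "df": lr.df, "p": lr.p}
            )
            report_lines.append(
                f"  LRT {term}: chi2({lr.df}) = {lr.chi2:.2f}, p = {lr.p:.4f}"
            )
        for fac, ct in mr.contrasts.items():
            c = ct.contrasts.copy()
            c.insert(0, "factor", fac)
            c.insert(0, "model", mid)
            contrast_frames.append(c)
            ls = ct.lsmeans.copy()
            ls["letters"] = [ct.letters[lv] for lv in ls["level"]]
            ls.insert(0, "factor", fac)
            ls.insert(0, "model", mid)
            ls_frames.append(ls)
            report_lines.append(
                f"  letters [{fac}]: "
                + ", ".join(f"{lv}={ct.letters[lv]}" for lv in ct.letters)
            )
    for mid, err in result.model_errors.items():
        report_lines.append(f"model {mid} FAILED: {err}")
    if coef_frames:
        record("model_coefficients.csv", _write_csv(pd.concat(coef_frames, ignore_index=True), out / "model_coefficients.csv"))
    if lrt_rows:
        record("model_lrts.csv", _write_csv(pd.DataFrame(lrt_rows), out / "model_lrts.csv"))
    if contrast_frames:
        record("model_contrasts.csv", _write_csv(pd.concat(contrast_frames, ignore_index=True), out / "model_contrasts.csv"))
    if ls_frames:
        record("model_lsmeans.csv", _write_csv(pd.concat(ls_frames, ignore_index=True), out / "model_lsmeans.csv"))

    if result.ground_truth is not None:
        record("ground_truth.csv", _write_csv(result.ground_truth.taxa, out / "ground_truth.csv"))

    report = "\n".join(report_lines) + "\n"
    (out / "run_report.txt").write_text(report)
    record("run_report.txt", len(report_lines))

    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": seed, "files": manifest}, fh, sort_keys=True, indent=1)
    return manifest
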