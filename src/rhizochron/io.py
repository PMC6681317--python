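"""Readers and writers for traced-root measurements and trait tables.

Two input dialects are supported:

* **Measurement table (CSV)** — the direct transcription of manual tracing:
  one row per measured length, with ``record_type`` distinguishing PR
  inter-branch segments (``PR_SEG``), the unbranched PR tip (``PR_TIP``,
  exactly one per plant) and lateral roots (``LR``), ordered shoot-to-tip by
  ``order_index``.  Columns: ``plant_id, accession, day, treatment,
  record_type, order_index, length_mm``.

* **RSML (XML)** — the Root System Markup Language interchange format.  Only
  ``rootsystem/scene/plant/root`` elements with ``geometry/polyline/point``
  coordinates and nested first-order child ``root`` elements are consumed;
  deeper branching orders are ignored with a warning.  Each lateral root's
  insertion point (the first vertex of its polyline) is projected onto the
  primary-root polyline and converted to an arc-length position, from which
  the inter-branch segment decomposition is recovered.

All lengths are read and written in millimetres; files are UTF-8, comma
separated, "." decimal separator.  Lines starting with ``#`` are treated as
comments in the CSV dialects (simulation outputs record their seed there).
"""

from __future__ import annotations

import csv
import math
import warnings
import xml.etree.ElementTree as ET
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .core import RootSystem, RSMLFormatError, SchemaError, TraitRecord

MEASUREMENT_COLUMNS = (
    "plant_id", "accession", "day", "treatment", "record_type", "order_index", "length_mm",
)
_RECORD_TYPES = {"PR_SEG", "PR_TIP", "LR"}

#: significant digits used when rendering lengths; round trips are lossless
#: at this precision
_FLOAT_FMT = "{:.12g}"


def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    return _FLOAT_FMT.format(value)


# ---------------------------------------------------------------------------
# measurement table (CSV)
# ---------------------------------------------------------------------------

def read_measurement_table(source: str | IO[str]) -> list[RootSystem]:
    """Parse a measurement-table CSV into one :class:`RootSystem` per plant.

    Plants appear in order of first occurrence.  Raises
    :class:`~rhizochron.core.SchemaError` for structural violations (missing
    ``PR_TIP``, duplicated ``(plant_id, record_type, order_index)``, a
    segment/LR count mismatch, unknown record types) and ``ValueError`` for
    negative lengths.
    """
    df = pd.read_csv(source, comment="#", dtype={"plant_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns and c != "treatment"]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    if "treatment" not in df.columns:
        df["treatment"] = ""
    df["treatment"] = df["treatment"].fillna("").astype(str)
    df["accession"] = df["accession"].fillna("").astype(str)

    bad_types = set(df["record_type"].unique()) - _RECORD_TYPES
    if bad_types:
        raise SchemaError(f"unknown record_type values: {sorted(bad_types)}")
    if (df["length_mm"] < 0).any():
        plants = df.loc[df["length_mm"] < 0, "plant_id"].unique().tolist()
        raise ValueError(f"negative length_mm for plants: {plants}")

    dupes = df.duplicated(subset=["plant_id", "record_type", "order_index"], keep=False)
    if dupes.any():
        keys = (
            df.loc[dupes, ["plant_id", "record_type", "order_index"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise SchemaError(f"duplicate (plant_id, record_type, order_index) rows: {sorted(keys)}")

    roots: list[RootSystem] = []
    for plant_id, grp in df.groupby("plant_id", sort=False):
        tips = grp[grp["record_type"] == "PR_TIP"]
        if len(tips) != 1:
            raise SchemaError(
                f"plant {plant_id!r}: expected exactly one PR_TIP row, found {len(tips)}"
            )
        segs = grp[grp["record_type"] == "PR_SEG"].sort_values("order_index")
        lrs = grp[grp["record_type"] == "LR"].sort_values("order_index")
        if len(segs) != len(lrs):
            raise SchemaError(
                f"plant {plant_id!r}: {len(segs)} PR_SEG rows but {len(lrs)} LR rows"
            )
        meta = grp.iloc[0]
        roots.append(
            RootSystem(
                plant_id=str(plant_id),
                accession=str(meta["accession"]),
                day=int(meta["day"]),
                treatment=str(meta["treatment"]),
                pr_segments=tuple(segs["length_mm"].astype(float)),
                pr_tip=float(tips["length_mm"].iloc[0]),
                lr_lengths=tuple(lrs["length_mm"].astype(float)),
            )
        )
    return roots


def write_measurement_table(
    roots: Iterable[RootSystem], sink: str | IO[str], seed: int | None = None
) -> int:
    """Write root systems in the measurement-table dialect; returns row count."""

    def _write(fh: IO[str]) -> int:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MEASUREMENT_COLUMNS)
        n = 0
        for root in roots:
            meta = [root.plant_id, root.accession, root.day, root.treatment]
            for k, seg in enumerate(root.pr_segments, start=1):
                writer.writerow(meta + ["PR_SEG", k, _fmt(seg)])
                n += 1
            writer.writerow(meta + ["PR_TIP", 1, _fmt(root.pr_tip)])
            n += 1
            for k, lr in enumerate(root.lr_lengths, start=1):
                writer.writerow(meta + ["LR", k, _fmt(lr)])
                n += 1
        return n

    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            return _write(fh)
    return _write(sink)


# ---------------------------------------------------------------------------
# RSML (XML)
# ---------------------------------------------------------------------------

def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]

def _find_children(elem: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in elem if _localname(c.tag) == name]

def _find_descendant(elem: ET.Element, path: tuple[str, ...]) -> ET.Element | None:
    cur = [elem]
    for name in path:
        nxt: list[ET.Element] = []
        for e in cur:
            nxt.extend(_find_children(e, name))
        if not nxt:
            return None
        cur = nxt
    return cur[0]

def _polyline(root_elem: ET.Element, what: str) -> np.ndarray:
    poly = _find_descendant(root_elem, ("geometry", "polyline"))
    if poly is None:
        raise RSMLFormatError(f"{what}: root element has no geometry/polyline")
    pts = []
    for pt in _find_children(poly, "point"):
        try:
            pts.append([float(pt.get("x")), float(pt.get("y")), float(pt.get("z") or 0.0)])
        except (TypeError, ValueError) as exc:
            raise RSMLFormatError(f"{what}: polyline point lacks numeric x/y") from exc
    if len(pts) < 2:
        raise RSMLFormatError(f"{what}: polyline needs at least two points")
    return np.asarray(pts, dtype=float)

def _arc_lengths(poly: np.ndarray) -> np.ndarray:
    steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])

def _project_to_polyline(point: np.ndarray, poly: np.ndarray, arcs: np.ndarray) -> tuple[float, float]:
    """Arc-length position and residual distance of a point projected onto a polyline."""
    best_s, best_d = 0.0, math.inf
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0.0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        proj = a + t * ab
        d = float(np.linalg.norm(point - proj))
        if d < best_d:
            best_d = d
            best_s = float(arcs[i]) + t * math.sqrt(denom)
    return best_s, best_d


def read_rsml(
    source: str | IO[str] | IO[bytes], projection_tol: float = 0.5
) -> list[RootSystem]:
    """Parse an RSML document into one :class:`RootSystem` per primary root.

    Every top-level ``root`` element under ``scene/plant`` is one plant's
    primary root; its direct child ``root`` elements are the lateral roots.
    A lateral's insertion point (first polyline vertex) is projected onto the
    primary-root polyline; if the residual distance exceeds
    ``projection_tol`` (mm) — e.g. a child placed beyond the PR apex — a
    :class:`~rhizochron.core.RSMLFormatError` is raised.  Laterals whose
    document order disagrees with their projected arc-length order are
    sorted, with a warning.  Second-order laterals are ignored with a
    warning.  ``plant_id``/``accession`` come from ``id``/``label``
    attributes when present.
    """
    tree = ET.parse(source)
    doc = tree.getroot()
    scenes = _find_children(doc, "scene") if _localname(doc.tag) == "rsml" else [doc]
    top_roots: list[tuple[ET.Element, ET.Element | None]] = []
    for scene in scenes:
        for plant in _find_children(scene, "plant"):
            for r in _find_children(plant, "root"):
                top_roots.append((r, plant))
    if not top_roots:
        raise RSMLFormatError("no top-level root element found under scene/plant")

    systems: list[RootSystem] = []
    for idx, (pr_elem, plant) in enumerate(top_roots, start=1):
        plant_id = (
            pr_elem.get("id")
            or (plant.get("id") if plant is not None else None)
            or f"plant{idx}"
        )
        accession = (
            (plant.get("label") if plant is not None else None)
            or pr_elem.get("label")
            or ""
        )
        pr_poly = _polyline(pr_elem, f"plant {plant_id!r} primary root")
        arcs = _arc_lengths(pr_poly)
        pr_total = float(arcs[-1])

        laterals: list[tuple[float, float]] = []  # (insertion arc pos, LR length)
        for child in _find_children(pr_elem, "root"):
            if _find_children(child, "root"):
                warnings.warn(
                    f"plant {plant_id!r}: second-order lateral roots present; ignored",
                    stacklevel=2,
                )
            lr_poly = _polyline(child, f"plant {plant_id!r} lateral root")
            s, resid = _project_to_polyline(lr_poly[0], pr_poly, arcs)
            if resid > projection_tol:
                raise RSMLFormatError(
                    f"plant {plant_id!r}: lateral-root insertion point lies "
                    f"{resid:.3g} mm off the primary root (tolerance {projection_tol} mm)"
                )
            laterals.append((s, float(_arc_lengths(lr_poly)[-1])))

        if laterals != sorted(laterals, key=lambda t: t[0]):
            warnings.warn(
                f"plant {plant_id!r}: lateral-root document order is not monotone in "
                "insertion position; sorting by arc length",
                stacklevel=2,
            )
            laterals.sort(key=lambda t: t[0])
        positions = [s for s, _ in laterals]
        segments = tuple(np.diff(positions, prepend=0.0)) if positions else ()
        pr_tip = pr_total - positions[-1] if positions else pr_total
        systems.append(
            RootSystem(
                plant_id=str(plant_id),
                accession=str(accession),
                pr_segments=segments,
                pr_tip=pr_tip,
                lr_lengths=tuple(length for _, length in laterals),
            )
        )
    return systems


# ---------------------------------------------------------------------------
# trait table (CSV)
# ---------------------------------------------------------------------------

def write_trait_table(
    records: Iterable[TraitRecord], sink: str | IO[str], seed: int | None = None
) -> int:
    """Write one CSV row per plant; returns the number of data rows.

    Missing values (undefined RD, coefficients of discarded fits) are empty
    fields.  Floats are rendered with 12 significant digits, which makes a
    write-then-read round trip lossless at that precision.
    """

    def _write(fh: IO[str]) -> int:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TraitRecord.COLUMNS)
        n = 0
        for rec in records:
            row = []
            for col in TraitRecord.COLUMNS:
                val = getattr(rec, col)
                row.append(val if col in ("plant_id", "accession", "treatment", "discard_reason") else _fmt(val))
            writer.writerow(row)
            n += 1
        return n

    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            return _write(fh)
    return _write(sink)


def read_trait_table(source: str | IO[str]) -> list[TraitRecord]:
    """Read a trait-table CSV written by :func:`write_trait_table`."""
    df = pd.read_csv(source, comment="#", dtype={"plant_id": str})
    missing = [c for c in TraitRecord.COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trait table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        def opt(col: str) -> float | None:
            v = row[col]
            return None if pd.isna(v) else float(v)

        records.append(
            TraitRecord(
                plant_id=str(row["plant_id"]),
                accession="" if pd.isna(row["accession"]) else str(row["accession"]),
                day=int(row["day"]),
                treatment="" if pd.isna(row["treatment"]) else str(row["treatment"]),
                TRL=float(row["TRL"]),
                PRL=float(row["PRL"]),
                TLRL=float(row["TLRL"]),
                RD=opt("RD"),
                TLr=float(row["TLr"]),
                PLr=float(row["PLr"]),
                BZ=float(row["BZ"]),
                preBZ=float(row["preBZ"]),
                postBZ=float(row["postBZ"]),
                n_lr=int(row["n_lr"]),
                m=opt("m"),
                b=opt("b"),
                r2=opt("r2"),
                discarded=str(row["discarded"]).strip().lower() == "true",
                discard_reason="" if pd.isna(row["discard_reason"]) else str(row["discard_reason"]),
            )
        )
    return records


def write_discard_log(log, sink: str | IO[str]) -> int:
    """Write a discard log as CSV (plant_id, accession, day, treatment, reason)."""

    def _write(fh: IO[str]) -> int:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("plant_id", "accession", "day", "treatment", "reason"))
        n = 0
        for e in log:
            writer.writerow((e.plant_id, e.accession, e.day, e.treatment, e.reason))
            n += 1
        return n

    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            return _write(fh)
    return _write(sink)


__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurement_table",
    "write_measurement_table",
    "read_rsml",
    "write_trait_table",
    "read_trait_table",
    "write_discard_log",
]
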