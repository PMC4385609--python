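"""Readers and writers for every on-disk artifact.

Conventions
-----------
* Segmented TSVs (wide and long) use **1-based inclusive** coordinates on
  disk, UCSC-browser style; they are converted to the internal 0-based
  half-open representation on read and back on write.
* Annotation tracks are BED4+ and therefore already 0-based half-open.
* All files are tab-delimited UTF-8; lines starting with ``#`` are ignored.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np

from .core import AnnotationRecord, GroupLabels, Segment, SegmentMatrix, SegmentedProfile

__all__ = [
    "read_segment_matrix",
    "write_segment_matrix",
    "read_segmented_long",
    "write_segmented_long",
    "read_labels",
    "write_labels",
    "read_track",
    "write_track",
    "write_newick",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping comments and blank lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_coords(chrom: str, start_s: str, end_s: str, path, lineno: int) -> tuple[int, int]:
    """Disk (1-based inclusive) -> internal (0-based half-open)."""
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    start, end = start1 - 1, end1
    if end <= start:
        raise FormatError(
            f"{path}:{lineno}: segment end {end1} <= start {start1} on {chrom}"
        )
    return start, end


# ---------------------------------------------------------------------------
# Segmented wide TSV (common grid x samples)

def read_segment_matrix(path: str | Path) -> SegmentMatrix:
    """Read a wide segmented TSV: ``chrom  start  end  <sample1> ... <sampleN>``.

    Empty cells become missing entries.  Rows are sorted by (chrom, start)
    after parsing; duplicate intervals are an error.
    """
    lines = _data_lines(path)
    try:
        header_lineno, header = next(iter(lines))
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    if header[:3] != ["chrom", "start", "end"] or len(header) < 4:
        raise FormatError(
            f"{path}:{header_lineno}: expected header 'chrom\\tstart\\tend\\t<samples...>'"
        )
    samples = header[3:]
    segments: list[Segment] = []
    rows_v: list[list[float]] = []
    rows_m: list[list[bool]] = []
    seen: set[tuple[str, int, int]] = set()
    for lineno, fields in lines:
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        chrom = fields[0]
        start, end = _parse_coords(chrom, fields[1], fields[2], path, lineno)
        key = (chrom, start, end)
        if key in seen:
            raise FormatError(f"{path}:{lineno}: duplicate segment {chrom}:{fields[1]}-{fields[2]}")
        seen.add(key)
        vals, miss = [], []
        for col, cell in zip(samples, fields[3:]):
            if cell == "":
                vals.append(math.nan)
                miss.append(True)
            else:
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} for sample {col!r}"
                    ) from exc
                if not math.isfinite(v):
                    raise FormatError(f"{path}:{lineno}: non-finite value for sample {col!r}")
                vals.append(v)
                miss.append(False)
        segments.append(Segment(chrom, start, end))
        rows_v.append(vals)
        rows_m.append(miss)
    if not segments:
        raise FormatError(f"{path}: no data rows")
    mat = SegmentMatrix(segments, samples, np.array(rows_v), np.array(rows_m))
    return mat.sorted_by_position()


def write_segment_matrix(mat: SegmentMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(mat.samples) + "\n")
        for i, seg in enumerate(mat.segments):
            cells = [
                "" if mat.missing[i, j] else repr(float(mat.values[i, j]))
                for j in range(mat.n_samples)
            ]
            fh.write(f"{seg.chrom}\t{seg.start + 1}\t{seg.end}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Segmented long TSV (per-sample segments)

def read_segmented_long(path: str | Path) -> list[SegmentedProfile]:
    """Read a long segmented TSV: ``sample  chrom  start  end  value``.

    Returns one profile per distinct sample (order of first appearance),
    segments sorted; within-sample overlap is an error.
    """
    lines = _data_lines(path)
    try:
        header_lineno, header = next(iter(lines))
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    if header != ["sample", "chrom", "start", "end", "value"]:
        raise FormatError(
            f"{path}:{header_lineno}: expected header 'sample\\tchrom\\tstart\\tend\\tvalue'"
        )
    by_sample: dict[str, list[Segment]] = {}
    for lineno, fields in lines:
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        sample, chrom = fields[0], fields[1]
        start, end = _parse_coords(chrom, fields[2], fields[3], path, lineno)
        try:
            value = float(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value {fields[4]!r}") from exc
        if not math.isfinite(value):
            raise FormatError(f"{path}:{lineno}: non-finite value")
        by_sample.setdefault(sample, []).append(Segment(chrom, start, end, value))
    profiles = []
    for sample, segs in by_sample.items():
        try:
            profiles.append(SegmentedProfile(sample, segs))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return profiles


def write_segmented_long(profiles: Sequence[SegmentedProfile], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample\tchrom\tstart\tend\tvalue\n")
        for prof in profiles:
            for seg in prof.segments:
                fh.write(
                    f"{prof.sample_id}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}\t"
                    f"{float(seg.value)!r}\n"
                )


# ---------------------------------------------------------------------------
# Group labels

def read_labels(path: str | Path) -> GroupLabels:
    """Read ``sample  group`` TSV into a GroupLabels mapping."""
    lines = _data_lines(path)
    try:
        header_lineno, header = next(iter(lines))
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    if header != ["sample", "group"]:
        raise FormatError(f"{path}:{header_lineno}: expected header 'sample\\tgroup'")
    labels = GroupLabels()
    for lineno, fields in lines:
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        sample, group = fields
        if sample in labels:
            raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
        labels[sample] = group
    return labels


def write_labels(labels: GroupLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in labels.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# BED4+ annotation tracks

def read_track(path: str | Path, kind: str) -> list[AnnotationRecord]:
    """Read a BED4+ track as annotation records of the given kind.

    Column 4 becomes payload key ``name``; columns 5+ of the form
    ``key=value`` become further payload attributes.
    """
    records: list[AnnotationRecord] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED row needs >=3 fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
        payload: dict[str, str] = {}
        if len(fields) >= 4 and fields[3] != "":
            payload["name"] = fields[3]
        for extra in fields[4:]:
            if "=" in extra:
                k, _, v = extra.partition("=")
                payload[k] = v
            elif extra:
                raise FormatError(
                    f"{path}:{lineno}: extra column {extra!r} is not 'key=value'"
                )
        try:
            records.append(AnnotationRecord(chrom, start, end, kind, payload))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_track(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for rec in records:
            payload = dict(rec.payload)
            name = payload.pop("name", ".")
            extras = [f"{k}={v}" for k, v in sorted(payload.items())]
            row = [rec.chrom, str(rec.start), str(rec.end), name, *extras]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path: str | Path) -> None:
    """Serialize a ClusterTree to Newick; branch length = parent height - child height."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Reports (TSV / JSON)

def _as_rows(report: Any) -> list[dict]:
    if hasattr(report, "to_dict") and hasattr(report, "columns"):  # DataFrame
        return report.to_dict(orient="records")
    rows = []
    for item in report:
        if hasattr(item, "to_dict"):
            rows.append(item.to_dict())
        elif isinstance(item, dict):
            rows.append(item)
        else:
            raise TypeError(f"cannot serialize report row of type {type(item)!r}")
    return rows


def write_report(report: Any, path: str | Path, format: str = "tsv") -> None:
    """Write a report (sequence of dicts / objects with to_dict, or DataFrame)."""
    rows = _as_rows(report)
    if format == "json":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            json.dump(rows, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        cols: list[str] = []
        for row in rows:
            for k in row:
                if k not in cols:
                    cols.append(k)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=cols, delimiter="\t", lineterminator="\n"
            )
            writer.writeheader()
            for row in rows:
                writer.writerow(
                    {
                        k: (json.dumps(v, sort_keys=True) if isinstance(v, (list, dict)) else v)
                        for k, v in row.items()
                    }
                )
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'tsv' or 'json')")


def read_report(path: str | Path, format: str = "json") -> list[dict]:
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    raise ValueError("only JSON reports can be read back")
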