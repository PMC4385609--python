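"""Region annotation reports, CNV masking, and expert-annotation retention.

This realizes a retrieve/reuse/retain cycle deterministically from local
flat-file tracks: *retrieve* the gene, variant, and note records
overlapping each tested region; *reuse* them into a per-region report that
carries everything an expert reviewer needs (test outcome, genes with
their cross-references, disease texts, CNV overlaps); and *retain* expert
annotations back into the local note track so later runs see them.  The
revision step itself is human work and stays outside the package.

Regions largely explained by catalogued copy-number variants (CNVs found
in healthy populations) are flagged: an aberration that coincides with a
common CNV is usually not pathogenic and is dropped from the default
selected set, though its statistics are kept for review.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .association import AssociationResult
from .core import AnnotationRecord, Segment
from .io import read_track, write_track
from .regions import build_interval_index, query_overlaps

__all__ = ["RegionReport", "annotate_regions", "mask_cnv", "retain_annotation"]

_TRACK_KINDS = {"gene", "cnv", "note", "variant"}


def _union_covered_length(region: Segment, records: Sequence[AnnotationRecord]) -> int:
    """Total length of region covered by the union of the records' overlaps."""
    clipped = sorted(
        (max(r.start, region.start), min(r.end, region.end)) for r in records
    )
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in clipped:
        if s >= e:
            continue
        if cur_start is None or s > cur_end:
            if cur_start is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_start is not None:
        covered += cur_end - cur_start
    return covered


@dataclass
class RegionReport:
    """Everything retrieved for one tested region, ready for expert review."""

    region: Segment
    pathology: str
    p_value: float
    p_adjusted: float
    test_used: str
    selected: bool
    genes: list[dict] = field(default_factory=list)
    diseases: list[str] = field(default_factory=list)
    cnv_overlaps: list[dict] = field(default_factory=list)
    notes: list[dict] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)
    cnv_masked: bool = False

    def to_dict(self) -> dict:
        return {
            "chrom": self.region.chrom,
            "start": self.region.start,
            "end": self.region.end,
            "pathology": self.pathology,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "test_used": self.test_used,
            "selected": self.selected,
            "genes": self.genes,
            "diseases": self.diseases,
            "cnv_overlaps": self.cnv_overlaps,
            "notes": self.notes,
            "variants": self.variants,
            "cnv_masked": self.cnv_masked,
        }


def annotate_regions(
    results: Sequence[AssociationResult],
    tracks: Mapping[str, Sequence[AnnotationRecord]],
) -> list[RegionReport]:
    """Join association results with all overlapping track records.

    ``tracks`` maps kind ('gene', 'cnv', 'note', 'variant') to records.
    Payloads pass through verbatim; record order within a report is
    deterministic (genomic position, then payload).  Pure function: same
    inputs give identical reports.
    """
    unknown = set(tracks) - _TRACK_KINDS
    if unknown:
        raise ValueError(f"unknown track kinds: {sorted(unknown)}")
    indexes = {kind: build_interval_index(list(recs)) for kind, recs in tracks.items()}

    def hits(kind: str, region: Segment) -> list[AnnotationRecord]:
        if kind not in indexes:
            return []
        return query_overlaps(indexes[kind], region.chrom, region.start, region.end)

    reports = []
    for res in results:
        region = res.region
        genes = [dict(r.payload) for r in hits("gene", region)]
        diseases = sorted({g["disease"] for g in genes if "disease" in g})
        cnv_hits = hits("cnv", region)
        cnv_overlaps = [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                **dict(r.payload),
                "overlap_fraction": (min(r.end, region.end) - max(r.start, region.start))
                / region.length,
            }
            for r in cnv_hits
        ]
        reports.append(
            RegionReport(
                region=region,
                pathology=res.pathology,
                p_value=res.p_value,
                p_adjusted=res.p_adjusted,
                test_used=res.test_used,
                selected=res.selected,
                genes=genes,
                diseases=diseases,
                cnv_overlaps=cnv_overlaps,
                notes=[dict(r.payload) for r in hits("note", region)],
                variants=[dict(r.payload) for r in hits("variant", region)],
                cnv_masked=res.cnv_masked,
            )
        )
    return reports


def mask_cnv(
    results: Sequence[AssociationResult],
    cnv_track: Sequence[AnnotationRecord],
    min_fraction: float = 0.5,
) -> list[AssociationResult]:
    """Flag results whose region is mostly explained by catalogued CNVs.

    A region is masked when the fraction of its length covered by the
    union of overlapping CNV records is >= ``min_fraction``.  Masked
    regions keep their statistics but are removed from the selected set.
    Masking is monotone: lowering the threshold never unmasks a region.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    index = build_interval_index(list(cnv_track))
    for res in results:
        region = res.region
        hits = query_overlaps(index, region.chrom, region.start, region.end)
        covered = _union_covered_length(region, hits)
        res.cnv_overlaps = [
            (h, (min(h.end, region.end) - max(h.start, region.start)) / region.length)
            for h in hits
        ]
        res.cnv_masked = covered / region.length >= min_fraction
        if res.cnv_masked:
            res.selected = False
    return list(results)


def retain_annotation(store_path: str | Path, record: AnnotationRecord) -> None:
    """Append an expert note to the local annotation store (deduplicated).

    Only ``kind='note'`` records may be retained; the store is a BED4+
    track that subsequent annotation runs read back.
    """
    if record.kind != "note":
        raise ValueError(f"only kind='note' records may be retained, got {record.kind!r}")
    store_path = Path(store_path)
    existing: list[AnnotationRecord] = []
    if store_path.exists() and os.path.getsize(store_path) > 0:
        existing = read_track(store_path, "note")
    if record not in existing:
        existing.append(record)
    write_track(existing, store_path)
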