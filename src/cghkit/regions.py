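"""Harmonizing per-sample segmentations onto minimal common regions.

Oligo-style arrays segment every sample at its own breakpoints, so the
samples are not directly comparable.  Pooling all breakpoints and cutting
every profile at the pooled set yields the *minimal common regions*: the
finest grid on which every sample is constant, so each (region, sample)
cell inherits the unique covering segment's value unchanged.  BAC-style
input (identical breakpoints everywhere) is a fixed point of this
operation.

Also provides the accumulated gain/loss view over a ternary call matrix
and genomic interval overlap queries backed by an interval tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import AnnotationRecord, Segment, SegmentMatrix, SegmentedProfile

__all__ = [
    "union_breakpoints",
    "MinimalCommonRegionGrid",
    "minimal_common_regions",
    "harmonize",
    "accumulate",
    "build_interval_index",
    "query_overlaps",
]


def union_breakpoints(profiles: list[SegmentedProfile], chrom: str) -> list[int]:
    """Sorted, deduplicated union of all segment start/end positions on chrom."""
    if not profiles:
        raise ValueError("need at least one profile")
    points: set[int] = set()
    for prof in profiles:
        for seg in prof.segments:
            if seg.chrom == chrom:
                points.add(seg.start)
                points.add(seg.end)
    return sorted(points)


@dataclass
class MinimalCommonRegionGrid:
    """The common grid plus, per (region, sample), the source segment index.

    ``provenance[i, j]`` is the index into ``profiles[j].segments`` of the
    segment covering region ``i``, or -1 where sample ``j`` is uncovered.
    """

    regions: list[Segment]
    samples: list[str]
    provenance: np.ndarray


def minimal_common_regions(profiles: list[SegmentedProfile]) -> MinimalCommonRegionGrid:
    if not profiles:
        raise ValueError("need at least one profile")
    chroms = sorted({seg.chrom for prof in profiles for seg in prof.segments})
    regions: list[Segment] = []
    prov_rows: list[list[int]] = []
    for chrom in chroms:
        bps = union_breakpoints(profiles, chrom)
        # per-sample covering-segment lookup on this chromosome
        per_sample: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for prof in profiles:
            idx = [k for k, s in enumerate(prof.segments) if s.chrom == chrom]
            starts = np.array([prof.segments[k].start for k in idx])
            ends = np.array([prof.segments[k].end for k in idx])
            per_sample.append((starts, ends, np.array(idx, dtype=int)))
        for a, b in zip(bps[:-1], bps[1:]):
            row = []
            for starts, ends, idx in per_sample:
                pos = np.searchsorted(starts, a, side="right") - 1
                if pos >= 0 and ends[pos] >= b:  # segment [start,end) covers [a,b)
                    row.append(int(idx[pos]))
                else:
                    row.append(-1)
            if any(k >= 0 for k in row):  # drop regions covered by no sample
                regions.append(Segment(chrom, a, b))
                prov_rows.append(row)
    samples = [p.sample_id for p in profiles]
    prov = np.array(prov_rows, dtype=int).reshape(len(regions), len(samples))
    return MinimalCommonRegionGrid(regions, samples, prov)


def harmonize(profiles: list[SegmentedProfile]) -> SegmentMatrix:
    """Resegment heterogeneous profiles onto the minimal common region grid.

    The value of each (region, sample) cell is the value of the sample's
    unique covering segment; cells where the sample has no coverage are
    missing.  Values are conserved: at every genomic position a sample
    covers, the harmonized value equals the original segment value.
    """
    grid = minimal_common_regions(profiles)
    n_r, n_s = grid.provenance.shape
    values = np.full((n_r, n_s), np.nan)
    for j, prof in enumerate(profiles):
        seg_values = np.array([s.value for s in prof.segments])
        covered = grid.provenance[:, j] >= 0
        values[covered, j] = seg_values[grid.provenance[covered, j]]
    return SegmentMatrix(grid.regions, grid.samples, values, ~(grid.provenance >= 0))


def accumulate(calls: SegmentMatrix) -> pd.DataFrame:
    """Accumulated gain/loss view: per-region counts across samples.

    Returns a DataFrame with columns chrom, start, end, gain_count,
    loss_count, n_informative.  Looking at totals rather than individual
    patients makes recurrently aberrant regions stand out.
    """
    v = np.where(calls.missing, np.nan, calls.values)
    gain = np.nansum(v == 1, axis=1).astype(int)
    loss = np.nansum(v == -1, axis=1).astype(int)
    n_inf = (~calls.missing).sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in calls.segments],
            "start": [s.start for s in calls.segments],
            "end": [s.end for s in calls.segments],
            "gain_count": gain,
            "loss_count": loss,
            "n_informative": n_inf,
        }
    )


def build_interval_index(records: list[AnnotationRecord]) -> dict[str, IntervalTree]:
    """Index annotation records per chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, rec)
    return trees


def query_overlaps(
    index: dict[str, IntervalTree], chrom: str, start: int, end: int
) -> list[AnnotationRecord]:
    """Records intersecting [start, end) by >= 1 bp on chrom, ordered by (start, end).

    Half-open arithmetic: abutting intervals do not overlap.
    """
    if end <= start:
        raise ValueError("query end must exceed start")
    tree = index.get(chrom)
    if tree is None:
        return []
    hits = [iv.data for iv in tree.overlap(start, end)]
    hits.sort(key=lambda r: (r.start, r.end, r.kind, tuple(sorted(r.payload.items()))))
    return hits
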