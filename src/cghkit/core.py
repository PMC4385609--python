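"""Core in-memory containers for segmented aCGH data.

All genomic intervals are held internally as 0-based, half-open
``[start, end)`` coordinates on an opaque chromosome name.  On-disk
conventions (1-based inclusive for segmented TSVs, BED for tracks) are
handled by :mod:`cghkit.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Segment",
    "SegmentedProfile",
    "SegmentMatrix",
    "GroupLabels",
    "AnnotationRecord",
    "ANNOTATION_KINDS",
]

ANNOTATION_KINDS = frozenset({"gene", "cnv", "note", "variant"})


@dataclass(frozen=True, order=True)
class Segment:
    """A genomic interval carrying one segmented log-ratio.

    Parameters
    ----------
    chrom : str
        Chromosome name, treated as an opaque string (no "chr" handling).
    start, end : int
        0-based half-open bounds, ``end > start``.
    value : float
        Segmented copy-number log-ratio (dimensionless).  NaN marks an
        interval used purely as a grid cell.
    """

    chrom: str
    start: int
    end: int
    value: float = math.nan

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Segment.chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"Segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if math.isinf(self.value):
            raise ValueError("Segment value must be finite or NaN")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SegmentedProfile:
    """One sample's ordered, non-overlapping segments."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"sample {self.sample_id!r}: overlapping segments "
                    f"{prev.chrom}:{prev.start}-{prev.end} and "
                    f"{seg.chrom}:{seg.start}-{seg.end}"
                )
            prev = seg

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chrom, None)
        return list(seen)

    def value_at(self, chrom: str, pos: int) -> float | None:
        """Segment value covering ``pos`` (0-based), or None if uncovered."""
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos < seg.end:
                return seg.value
        return None


class SegmentMatrix:
    """A common segment grid by sample matrix of log-ratios (or ternary calls).

    ``values[i, j]`` is the value of grid segment ``i`` in sample ``j``;
    ``missing[i, j]`` is True where sample ``j`` has no measurement on
    segment ``i`` (the value there is undefined and stored as NaN).
    """

    def __init__(
        self,
        segments: Iterable[Segment],
        samples: Iterable[str],
        values: np.ndarray,
        missing: np.ndarray | None = None,
    ) -> None:
        self.segments: list[Segment] = list(segments)
        self.samples: list[str] = list(samples)
        values = np.asarray(values, dtype=float)
        if missing is None:
            missing = np.isnan(values)
        missing = np.asarray(missing, dtype=bool)
        shape = (len(self.segments), len(self.samples))
        if values.shape != shape:
            raise ValueError(f"values shape {values.shape} != {shape}")
        if missing.shape != shape:
            raise ValueError(f"missing shape {missing.shape} != {shape}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        intervals = [s.interval() for s in self.segments]
        if len(set(intervals)) != len(intervals):
            raise ValueError("duplicate grid segments")
        values = values.copy()
        values[missing] = np.nan
        if not np.all(np.isfinite(values[~missing])):
            raise ValueError("non-missing values must be finite")
        self.values = values
        self.missing = missing

    @property
    def n_regions(self) -> int:
        return len(self.segments)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_regions, self.n_samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def copy(self) -> "SegmentMatrix":
        return SegmentMatrix(
            list(self.segments),
            list(self.samples),
            self.values.copy(),
            self.missing.copy(),
        )

    def sorted_by_position(self) -> "SegmentMatrix":
        order = sorted(
            range(self.n_regions),
            key=lambda i: (self.segments[i].chrom, self.segments[i].start),
        )
        return SegmentMatrix(
            [self.segments[i] for i in order],
            list(self.samples),
            self.values[order],
            self.missing[order],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentMatrix):
            return NotImplemented
        return (
            [s.interval() for s in self.segments]
            == [s.interval() for s in other.segments]
            and self.samples == other.samples
            and np.array_equal(self.missing, other.missing)
            and np.allclose(
                self.values[~self.missing], other.values[~other.missing]
            )
        )

    def __repr__(self) -> str:
        return f"<SegmentMatrix {self.n_regions} regions x {self.n_samples} samples>"


class GroupLabels(dict):
    """Mapping from sample_id to pathology-group name."""

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.values():
            seen.setdefault(g, None)
        return list(seen)

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.items() if g == group]

    def validate_against(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if len(self.group_names) < 1:
            raise ValueError("at least one pathology group required")


@dataclass(frozen=True)
class AnnotationRecord:
    """A BED-style annotation: genes, catalogued CNVs, expert notes, variants."""

    chrom: str
    start: int
    end: int
    kind: str
    payload: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"annotation end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(
                f"unknown annotation kind {self.kind!r}; expected one of {sorted(ANNOTATION_KINDS)}"
            )
        object.__setattr__(self, "payload", dict(self.payload))

    def key(self) -> tuple:
        return (
            self.chrom,
            self.start,
            self.end,
            self.kind,
            tuple(sorted(self.payload.items())),
        )

    def __hash__(self) -> int:
        return hash(self.key())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationRecord):
            return NotImplemented
        return self.key() == other.key()
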