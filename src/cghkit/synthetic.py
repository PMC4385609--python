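"""Synthetic segmented aCGH cohorts with planted gain/loss regions.

The generator emulates the structure of a small clinical aCGH cohort:
pathology groups of patients whose segmented log-ratio profiles are flat
(copy-neutral) except for (a) *planted* recurrent aberrations — regions
where carriers of the affected pathology, drawn with a given penetrance,
gain or lose one copy-change worth of signal — (b) sporadic *background*
aberrations appearing in any sample at a low rate, and (c) Gaussian
segment-level measurement noise.

Two array styles are produced.  BAC mode puts every sample on one shared
segment grid (equal-width clones per chromosome).  Oligo mode draws each
sample's private breakpoints as a Poisson process along the chromosome
(plus forced breakpoints at planted-region edges for carriers), so every
sample has its own segmentation, exercising the minimal-common-region
harmonization.

Every draw flows from the single ``seed`` in the spec through one
numpy Generator; the same spec reproduces byte-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import AnnotationRecord, GroupLabels, Segment, SegmentMatrix, SegmentedProfile

__all__ = ["PlantedRegion", "SimulationSpec", "simulate_bac", "simulate_oligo", "make_tracks"]


@dataclass(frozen=True)
class PlantedRegion:
    """A recurrent aberration planted in one pathology group."""

    chrom: str
    start: int
    end: int
    group: str
    direction: str  # 'gain' | 'loss'
    penetrance: float = 0.9
    effect: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be 'gain' or 'loss', got {self.direction!r}")
        if not (0 <= self.penetrance <= 1):
            raise ValueError(f"penetrance must be in [0, 1], got {self.penetrance}")
        if not (self.effect > 0):
            raise ValueError(f"effect must be > 0, got {self.effect}")
        if self.end <= self.start:
            raise ValueError("planted region end must exceed start")

    @property
    def signed_effect(self) -> float:
        return self.effect if self.direction == "gain" else -self.effect


def _default_planted() -> list[PlantedRegion]:
    return [
        PlantedRegion("chr1", 10_000_000, 14_000_000, "pathology_1", "gain"),
        PlantedRegion("chr1", 60_000_000, 64_000_000, "pathology_1", "loss"),
        PlantedRegion("chr2", 30_000_000, 34_000_000, "pathology_2", "gain"),
    ]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one simulated cohort.

    Defaults describe a two-group case/control comparison of 20 patients
    per pathology on two chromosomes, with 90% penetrant single-copy
    aberrations (|log-ratio| 1.0), 5% sporadic background aberrations, and
    segment noise of 0.2 log-ratio units.
    """

    n_groups: int = 2
    samples_per_group: int = 20
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 80_000_000}
    )
    segments_per_chrom: dict = field(
        default_factory=lambda: {"chr1": 50, "chr2": 40}
    )
    breakpoint_rate: float = 3e-7  # oligo mode: expected breakpoints per bp
    planted_regions: list = field(default_factory=_default_planted)
    noise_sd: float = 0.2
    background_rate: float = 0.05
    background_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.samples_per_group < 1:
            raise ValueError("need at least one group and one sample per group")
        if self.noise_sd < 0 or not (0 <= self.background_rate <= 1):
            raise ValueError("noise_sd must be >= 0 and background_rate in [0, 1]")
        for pr in self.planted_regions:
            if pr.chrom not in self.chrom_lengths:
                raise ValueError(f"planted region on unknown chromosome {pr.chrom!r}")
            if pr.start < 0 or pr.end > self.chrom_lengths[pr.chrom]:
                raise ValueError(
                    f"planted region {pr.chrom}:{pr.start}-{pr.end} outside chromosome"
                )
        known_groups = {f"pathology_{i + 1}" for i in range(self.n_groups)}
        for pr in self.planted_regions:
            if pr.group not in known_groups:
                raise ValueError(
                    f"planted region group {pr.group!r} not among {sorted(known_groups)}"
                )

    def with_(self, **changes) -> "SimulationSpec":
        return replace(self, **changes)

    @property
    def group_names(self) -> list[str]:
        return [f"pathology_{i + 1}" for i in range(self.n_groups)]

    def sample_names(self) -> list[str]:
        n = self.n_groups * self.samples_per_group
        return [f"S{i + 1:03d}" for i in range(n)]

    def labels(self) -> GroupLabels:
        labels = GroupLabels()
        for i, s in enumerate(self.sample_names()):
            labels[s] = self.group_names[i // self.samples_per_group]
        return labels


def _bac_grid(spec: SimulationSpec) -> list[Segment]:
    grid: list[Segment] = []
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        k = spec.segments_per_chrom[chrom]
        bounds = np.linspace(0, length, k + 1).astype(int)
        for a, b in zip(bounds[:-1], bounds[1:]):
            grid.append(Segment(chrom, int(a), int(b)))
    return grid


def _truth_table(spec: SimulationSpec) -> list[dict]:
    return [
        {
            "chrom": pr.chrom,
            "start": pr.start,
            "end": pr.end,
            "group": pr.group,
            "direction": pr.direction,
            "penetrance": pr.penetrance,
            "effect": pr.effect,
        }
        for pr in spec.planted_regions
    ]


def _draw_carriers(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Carrier indicator per (planted region, sample), drawn by penetrance."""
    labels = spec.labels()
    samples = spec.sample_names()
    carriers = np.zeros((len(spec.planted_regions), len(samples)), dtype=bool)
    for r, pr in enumerate(spec.planted_regions):
        for j, s in enumerate(samples):
            if labels[s] == pr.group:
                carriers[r, j] = rng.random() < pr.penetrance
    return carriers


def simulate_bac(
    spec: SimulationSpec,
) -> tuple[SegmentMatrix, GroupLabels, list[dict]]:
    """Simulate a shared-grid (BAC-style) cohort.

    Returns the segment matrix of noisy log-ratios, the group labels, and
    the truth table of planted regions.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _bac_grid(spec)
    samples = spec.sample_names()
    n_r, n_s = len(grid), len(samples)
    values = np.zeros((n_r, n_s))

    inside = np.zeros((len(spec.planted_regions), n_r), dtype=bool)
    for r, pr in enumerate(spec.planted_regions):
        inside[r] = np.array(
            [s.chrom == pr.chrom and s.start >= pr.start and s.end <= pr.end for s in grid]
        )
        if not inside[r].any():
            raise ValueError(
                f"planted region {pr.chrom}:{pr.start}-{pr.end} contains no grid segment"
            )

    carriers = _draw_carriers(spec, rng)
    for r, pr in enumerate(spec.planted_regions):
        values[np.ix_(inside[r], carriers[r])] += pr.signed_effect

    if spec.background_rate > 0:
        bg = rng.random((n_r, n_s)) < spec.background_rate
        signs = np.where(rng.random((n_r, n_s)) < 0.5, 1.0, -1.0)
        values += bg * signs * spec.background_effect
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, (n_r, n_s))

    mat = SegmentMatrix(grid, samples, values, np.zeros((n_r, n_s), dtype=bool))
    return mat, spec.labels(), _truth_table(spec)


def simulate_oligo(
    spec: SimulationSpec,
) -> tuple[list[SegmentedProfile], GroupLabels, list[dict]]:
    """Simulate per-sample segmentations (oligo-style).

    Each sample's breakpoints are a Poisson process along every chromosome
    (count Poisson(rate * length), positions uniform), with planted-region
    edges forced for carriers so the aberration occupies whole segments.
    Values per resulting segment follow the same aberration + noise model
    as BAC mode.
    """
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_names()
    labels = spec.labels()
    carriers = _draw_carriers(spec, rng)

    profiles: list[SegmentedProfile] = []
    for j, sample in enumerate(samples):
        segs: list[Segment] = []
        for chrom in sorted(spec.chrom_lengths):
            length = spec.chrom_lengths[chrom]
            n_bp = rng.poisson(spec.breakpoint_rate * length)
            points = {0, length}
            if n_bp:
                points.update(int(p) for p in rng.integers(1, length, size=n_bp))
            for r, pr in enumerate(spec.planted_regions):
                if pr.chrom == chrom and carriers[r, j]:
                    points.update((pr.start, pr.end))
            bounds = sorted(points)
            for a, b in zip(bounds[:-1], bounds[1:]):
                value = 0.0
                for r, pr in enumerate(spec.planted_regions):
                    if (
                        pr.chrom == chrom
                        and carriers[r, j]
                        and a >= pr.start
                        and b <= pr.end
                    ):
                        value += pr.signed_effect
                if spec.background_rate > 0 and rng.random() < spec.background_rate:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    value += sign * spec.background_effect
                if spec.noise_sd > 0:
                    value += rng.normal(0.0, spec.noise_sd)
                segs.append(Segment(chrom, a, b, value))
        profiles.append(SegmentedProfile(sample, segs))
    return profiles, labels, _truth_table(spec)


def make_tracks(
    spec: SimulationSpec,
) -> tuple[dict[str, list[AnnotationRecord]], list[dict]]:
    """Build gene and CNV track fixtures keyed to the planted regions.

    Each planted region gets one gene centered inside it; planted regions
    at even positions in the list are fully covered by a CNV record (and
    should end up masked downstream), odd ones get no CNV overlap.  A few
    decoy genes and one decoy CNV are placed away from all planted
    regions.  Returns (tracks, manifest); the manifest lists, per planted
    region, its genes and whether it should be masked.
    """
    genes: list[AnnotationRecord] = []
    cnvs: list[AnnotationRecord] = []
    manifest: list[dict] = []
    for idx, pr in enumerate(spec.planted_regions):
        quarter = (pr.end - pr.start) // 4
        gene_name = f"GENE_PR{idx + 1}"
        genes.append(
            AnnotationRecord(
                pr.chrom,
                pr.start + quarter,
                pr.end - quarter,
                "gene",
                {"name": gene_name, "disease": f"syndrome_{idx + 1}"},
            )
        )
        masked = idx % 2 == 0
        if masked:
            cnvs.append(
                AnnotationRecord(
                    pr.chrom, pr.start, pr.end, "cnv", {"name": f"CNV_PR{idx + 1}"}
                )
            )
        manifest.append(
            {
                "chrom": pr.chrom,
                "start": pr.start,
                "end": pr.end,
                "group": pr.group,
                "direction": pr.direction,
                "genes": [gene_name],
                "masked": masked,
            }
        )
    # decoys well away from any planted region
    planted_by_chrom: dict[str, list[PlantedRegion]] = {}
    for pr in spec.planted_regions:
        planted_by_chrom.setdefault(pr.chrom, []).append(pr)
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        step = length // 10
        for k in range(1, 10):
            start = k * step
            clear_until = lambda end: all(
                end <= pr.start or start >= pr.end
                for pr in planted_by_chrom.get(chrom, [])
            )
            gene_end = start + step // 5
            if clear_until(gene_end) and k % 3 == 0:
                genes.append(
                    AnnotationRecord(
                        chrom, start, gene_end, "gene", {"name": f"DECOY_{chrom}_{k}"}
                    )
                )
            # decoy CNVs are kept short (< half a typical grid segment) so
            # only the planted full-cover CNVs drive masking
            cnv_end = start + step // 12
            if clear_until(cnv_end) and k % 4 == 1:
                cnvs.append(
                    AnnotationRecord(chrom, start, cnv_end, "cnv", {"name": f"CNV_{chrom}_{k}"})
                )
    cnvs.sort(key=lambda r: (r.chrom, r.start, r.end))
    genes.sort(key=lambda r: (r.chrom, r.start, r.end))
    return {"gene": genes, "cnv": cnvs}, manifest
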