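"""End-to-end orchestration: transform -> call -> test -> mask -> annotate -> cluster.

The pipeline is a pure function of its inputs and configuration: given the
same files and the same :class:`RunConfig`, every artifact it writes is
byte-identical across runs.  Progress and per-stage record counts are
logged to stderr; a machine-readable run manifest (JSON) summarises the
parameters and outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import association, clustering, io, regions, transform

logger = logging.getLogger("cghkit")

__all__ = ["RunConfig", "run_pipeline", "results_from_dataframe"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; flat, YAML-serializable."""

    output_dir: str
    input_wide: str | None = None
    input_long: str | None = None
    labels: str | None = None
    genes_track: str | None = None
    cnv_track: str | None = None
    notes_track: str | None = None
    variants_track: str | None = None
    m: float | None = None  # None -> estimate per sample from the data
    tl: float = 2.0
    tg: float = 2.0
    alpha: float = 0.05
    correction: str = "bh"
    force_test: str = "auto"
    min_cnv_fraction: float = 0.5
    cluster_k: int = 2
    cluster_chroms: list[str] | None = None
    cluster_selected_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_wide is None) == (self.input_long is None):
            raise ValueError("exactly one of input_wide / input_long is required")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def results_from_dataframe(df: pd.DataFrame) -> list[association.AssociationResult]:
    """Rebuild association results from a written association table."""
    from .core import Segment

    out = []
    for row in df.itertuples(index=False):
        table = association.ContingencyTable2x3(
            (
                (int(row.f11), int(row.f12), int(row.f13)),
                (int(row.f21), int(row.f22), int(row.f23)),
            )
        )
        stat = None if pd.isna(row.statistic) else float(row.statistic)
        out.append(
            association.AssociationResult(
                region=Segment(str(row.chrom), int(row.start), int(row.end)),
                pathology=str(row.pathology),
                table=table,
                statistic=stat,
                p_value=float(row.p_value),
                test_used=str(row.test_used),
                p_adjusted=float(row.p_adjusted),
                selected=bool(row.selected),
                cnv_masked=bool(row.cnv_masked),
            )
        )
    return out


def _estimate_params(mat, cfg: RunConfig) -> dict[str, transform.TransformParams]:
    params = {}
    for j, sample in enumerate(mat.samples):
        if cfg.m is not None:
            m = cfg.m
        else:
            ok = ~mat.missing[:, j]
            vals = mat.values[ok, j]
            chroms = [mat.segments[i].chrom for i in np.flatnonzero(ok)]
            m = transform.mad1dr_estimate(vals, chroms)
        params[sample] = transform.TransformParams(m=m, tl=cfg.tl, tg=cfg.tg)
    return params


def _load_tracks(cfg: RunConfig) -> dict[str, list]:
    tracks: dict[str, list] = {}
    for kind, path in (
        ("gene", cfg.genes_track),
        ("cnv", cfg.cnv_track),
        ("note", cfg.notes_track),
        ("variant", cfg.variants_track),
    ):
        if path is not None:
            tracks[kind] = io.read_track(path, kind)
    return tracks


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all artifacts into cfg.output_dir.

    Returns the run manifest (also written as run_manifest.json).
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- load & harmonize -------------------------------------------------
    if cfg.input_long is not None:
        profiles = io.read_segmented_long(cfg.input_long)
        logger.info("loaded %d profiles from %s", len(profiles), cfg.input_long)
        mat = regions.harmonize(profiles)
        logger.info("harmonized onto %d minimal common regions", mat.n_regions)
    else:
        mat = io.read_segment_matrix(cfg.input_wide)
        logger.info(
            "loaded %d x %d segment matrix from %s",
            mat.n_regions,
            mat.n_samples,
            cfg.input_wide,
        )
    counts["regions"] = mat.n_regions
    counts["samples"] = mat.n_samples

    if cfg.labels is None:
        raise ValueError("labels file is required")
    labels = io.read_labels(cfg.labels)
    labels.validate_against(mat.samples)

    # --- transform & call -------------------------------------------------
    params = _estimate_params(mat, cfg)
    transformed = transform.transform_matrix(mat, params)
    io.write_segment_matrix(transformed, out / "transformed.tsv")
    calls = transform.ternary_call(transformed)
    io.write_segment_matrix(calls, out / "calls.tsv")
    acc = regions.accumulate(calls)
    acc.to_csv(out / "accumulated.tsv", sep="\t", index=False)
    counts["aberrant_cells"] = int(np.nansum(np.abs(calls.values)))
    logger.info("called %d aberrant cells", counts["aberrant_cells"])

    # --- association test & CNV masking -----------------------------------
    results = association.select_segments(
        calls,
        labels,
        alpha=cfg.alpha,
        correction=cfg.correction,
        force_test=cfg.force_test,
    )
    tracks = _load_tracks(cfg)
    if "cnv" in tracks:
        results = annotate_mod.mask_cnv(results, tracks["cnv"], cfg.min_cnv_fraction)
    counts["tests"] = len(results)
    counts["selected"] = sum(r.selected for r in results)
    counts["cnv_masked"] = sum(r.cnv_masked for r in results)
    logger.info(
        "%d tests, %d selected, %d CNV-masked",
        counts["tests"],
        counts["selected"],
        counts["cnv_masked"],
    )
    io.write_report([r.to_dict() for r in results], out / "association.tsv", "tsv")

    # --- annotation reports ------------------------------------------------
    reports = annotate_mod.annotate_regions(results, tracks)
    io.write_report(reports, out / "reports.json", "json")
    io.write_report(reports, out / "reports.tsv", "tsv")
    counts["reports"] = len(reports)

    # --- clustering ---------------------------------------------------------
    mask = np.ones(calls.n_regions, dtype=bool)
    if cfg.cluster_chroms:
        wanted = set(cfg.cluster_chroms)
        mask &= np.array([s.chrom in wanted for s in calls.segments])
    if cfg.cluster_selected_only:
        selected_ivs = {r.region.interval() for r in results if r.selected}
        sel_mask = np.array([s.interval() in selected_ivs for s in calls.segments])
        if sel_mask.any():
            mask &= sel_mask
        else:
            logger.warning("no selected regions; clustering on all regions in scope")
    if not mask.any():
        raise ValueError("clustering scope selects no regions")
    d = clustering.distance_matrix(calls, mask)
    tree = clustering.upgma(d, calls.samples)
    io.write_newick(tree, out / "tree.nwk")
    groups = clustering.cut_tree(tree, min(cfg.cluster_k, calls.n_samples))
    io.write_labels(groups, out / "cluster_groups.tsv")
    counts["cluster_regions"] = int(mask.sum())

    manifest = {
        "config": asdict(cfg),
        "counts": counts,
        "artifacts": sorted(
            str(p.name)
            for p in out.iterdir()
            if p.is_file() and p.name != "run_manifest.json"
        ),
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete; artifacts in %s", out)
    return manifest
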