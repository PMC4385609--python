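# cghkit

Downstream analysis of **segmented array-CGH data**: turning per-sample
segmented log-ratios into gain/loss calls, finding the chromosomal regions
associated with a pathology, clustering patients by their aberration
profiles, and producing annotation reports that let an expert judge each
candidate region.

It is aimed at labs that already run normalization and segmentation
(DNAcopy/GLAD/snapCGH or a vendor pipeline) and need the statistical and
bookkeeping machinery that comes after: BAC-style arrays where every
patient shares one segment grid, and oligo-style arrays where every
patient has private breakpoints.

## What it computes

**Calling.** Each array's segmented log-ratios `x` are rescaled by its
noise level `m` — the *mad1dr*, the median absolute deviation of lag-1
differences of the log-ratios — with a dead zone of `t_l`/`t_g` MAD units:

```
f(x) = 0                 −t_l·m ≤ x ≤ t_g·m
f(x) = (x − t_g·m) / m   x >  t_g·m        (gain, positive)
f(x) = (x + t_l·m) / m   x < −t_l·m        (loss, negative)
```

The sign of `f(x)` is the ternary call: +1 gain, 0 no variation, −1 loss.

**Minimal common regions.** Oligo profiles are cut at the union of all
samples' breakpoints, giving the finest grid on which every sample is
constant; values are conserved exactly and uncovered cells become missing.

**Region selection.** For each region and each pathology (one-vs-rest),
ternary calls are cross-tabulated into a 2×3 table (gain/normal/loss ×
pathology/not). Pearson's χ² test is used when at least 80% of expected
cell counts exceed 5; otherwise the **Freeman–Halton exact test** (full
enumeration of 2×3 tables over the fixed margins) takes over. P-values are
Benjamini–Hochberg adjusted per pathology (configurable) and regions with
adjusted p ≤ α are selected.

**Clustering.** Samples are compared by mean absolute difference of their
ternary calls over chosen regions (range [0, 2], missing pairwise-deleted)
and clustered by UPGMA; trees are exported as Newick and can be cut into
k groups and manually corrected.

**Annotation.** Selected regions are joined against local BED-like tracks
of genes, catalogued CNVs, variants and expert notes; regions mostly
covered by known CNVs are flagged and dropped from the default selection;
expert notes can be retained into the local track for future runs.

## Worked example

```python
import numpy as np
from cghkit import (SimulationSpec, simulate_bac, TransformParams,
                    transform_matrix, ternary_call, select_segments)

spec = SimulationSpec(seed=1)                 # 20 vs 20 samples, 3 planted regions
mat, labels, truth = simulate_bac(spec)       # 90 regions x 40 samples
calls = ternary_call(transform_matrix(mat, TransformParams(m=0.1)))
results = select_segments(calls, labels, alpha=0.05, correction="bh")
for r in results:
    if r.selected:
        print(r.region.chrom, r.region.start, r.region.end,
              r.pathology, r.test_used, f"{r.p_value:.2e}")
```

prints (pathology_1 block shown):

```
chr1 10000000 12000000 pathology_1 fisher 2.57e-08
chr1 12000000 14000000 pathology_1 fisher 1.13e-06
chr1 60000000 62000000 pathology_1 fisher 1.83e-05
chr1 62000000 64000000 pathology_1 fisher 1.39e-07
chr2 30000000 32000000 pathology_1 fisher 2.57e-08
chr2 32000000 34000000 pathology_1 fisher 1.54e-07
```

— exactly the six 2-Mb grid segments inside the three planted aberrations
(with two groups the one-vs-rest tests are symmetric, so the same regions
appear under pathology_2). The exact-test branch fired because with 20
samples per group the expected gain/loss cell counts fall below 5.

The same flow is available from the shell:

```sh
cgh simulate --seed 1 --out-dir demo
cgh transform --in demo/segments_wide.tsv --out demo/tr.tsv --mad 0.1
cgh call --in demo/tr.tsv --out demo/calls.tsv
cgh test --calls demo/calls.tsv --labels demo/labels.tsv --out demo/assoc.tsv
cgh cluster --calls demo/calls.tsv --out-tree demo/tree.nwk --out-groups demo/groups.tsv
cgh annotate --assoc demo/assoc.tsv --genes demo/genes.bed --cnv demo/cnv.bed \
             --out demo/reports.json
```

or as one deterministic pipeline from a YAML config: `cgh run --config cfg.yaml`.

## Layout

| module | responsibility |
|---|---|
| `cghkit.io` | TSV/BED/Newick/report readers and writers |
| `cghkit.transform` | mad1dr scale, soft-threshold transform, ternary calls |
| `cghkit.regions` | breakpoint union, minimal common regions, accumulation, interval index |
| `cghkit.association` | 2×3 tables, χ²/Freeman–Halton tests, switching rule, BH, selection |
| `cghkit.clustering` | ternary distances, UPGMA, cophenetic, tree cutting |
| `cghkit.annotate` | annotation joins, CNV masking, note retention |
| `cghkit.synthetic` | simulated BAC/oligo cohorts with planted aberrations |
| `cghkit.pipeline`, `cghkit.cli` | orchestration and the `cgh` command |

See `docs/methods.md` for the statistical model, parameter defaults and
design decisions.
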