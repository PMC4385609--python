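# Methods

## Scope and data model

cghkit starts where segmentation ends. Its inputs are segmented,
normalized log-ratio profiles: either a shared grid of segments × samples
(BAC-style arrays; wide TSV, 1-based inclusive coordinates on disk) or
per-sample segment lists with private breakpoints (oligo-style arrays;
long TSV). Internally every interval is 0-based half-open; BED tracks are
read as-is, segmented TSVs are shifted on read/write. Chromosome names are
opaque strings — no "chr" normalization is attempted, so inputs must be
self-consistent. Missing cells (a sample with no covering segment) are
first-class: they propagate through calling, are excluded from
contingency counts, and are pairwise-deleted in distances.

## Soft-threshold calling

To compare arrays with different noise levels, each array's values are
divided by its scale `m` and small excursions suppressed:

* `f(x) = 0` for `−t_l·m ≤ x ≤ t_g·m`;
* `f(x) = (x − t_g·m)/m` above the gain threshold;
* `f(x) = (x + t_l·m)/m` below the loss threshold.

This is the unique piecewise-affine form that is continuous, zero on the
dead zone, monotone with slope `1/m` outside it, and odd-symmetric when
`t_l = t_g`; those are the properties the transform is meant to have and
the properties the test suite enforces. The ternary call is the sign of
the transformed value. Calls are invariant under rescaling `(x, m) →
(cx, cm)`, so the absolute log-ratio scale of a platform does not matter.

**Parameters.** `t_l = t_g = 2.0` MAD units by default (a two-sigma-like
dead zone); both configurable per run. `m` is ideally the vendor-reported
mad1dr of the array. When unavailable it is estimated as

    m = 1.4826 · median(|d − median(d)|) / √2,

where `d` are lag-1 differences of the log-ratios within each chromosome.
Differencing removes slow copy-number structure, the √2 accounts for the
variance doubling of a difference of two independent noise terms, and
1.4826 is the usual MAD-to-Gaussian-sigma consistency constant. The
estimator refuses degenerate input (all differences equal → `m = 0`) and
asks the caller to supply `m` directly. It accepts probe- or
segment-level values; with few segments it is noisy, which is another
reason to prefer the vendor value when it exists.

## Minimal common regions

Oligo samples are made comparable by cutting every profile at the pooled
breakpoint set per chromosome. Each resulting region lies between two
consecutive pooled breakpoints, so no region spans any sample's
breakpoint, and the covering segment of a (region, sample) pair is unique
when it exists; its value carries over unchanged (value conservation, a
tested invariant). Cells with no covering segment become *missing* rather
than 0 — a zero would assert "measured, no variation" where nothing was
measured. Regions covered by no sample at all are dropped. Shared-grid
input is a fixed point of the operation.

The accumulated view (per-region gain/loss/informative counts across
samples) is the summary used to eyeball recurrent aberrations.

## Region–pathology association

For each pathology the samples are split one-vs-rest and each region's
non-missing calls are tabulated into a 2×3 table with columns
gain/normal/loss. The test of independence is chosen by the classical
expected-frequency rule: with expected counts `E_rc = f_r·f_·c / f_··`,
Pearson's χ² is trusted only when at least 80% of the six cells have
`E > 5` — operationalized strictly as "fewer than 5 of 6 cells with
`E > 5` ⇒ exact test". χ² drops zero-margin columns and reduces the
degrees of freedom to `k − 1` for `k` retained columns; no continuity
correction is applied. If fewer than two columns remain, or a row is
empty after missing-exclusion, the test is undefined: the region gets
`p = 1`, `test_used = "none"`, and can never be selected.

The exact branch is the Freeman–Halton extension of Fisher's test:
enumerate every 2×3 table with the observed margins, assign each its
multivariate hypergeometric probability
`P(T) = (Πrow!·Πcol!)/(n!·Πcells!)`, and sum `P(T)` over tables with
`P(T) ≤ P(observed) + ε`, `ε = 1e−12` absorbing floating-point ties.
Probabilities are computed in log-gamma space; enumeration is capped at
`n = 500` (beyond that χ² is both safe and demanded). No installed
library offers an r×c exact test, so this is implemented here and checked
in the tests against an independent rational-arithmetic enumeration.

P-values are adjusted per pathology by Benjamini–Hochberg (default) or
left raw (`correction="none"`); selection is `p_adjusted ≤ α`, `α = 0.05`
default. One-vs-rest is run for every pathology separately; no omnibus
multi-group test is attempted. Note that with exactly two groups the two
one-vs-rest passes are the same test twice — consumers counting
discoveries should count distinct regions.

## Clustering

The distance between two samples is the mean absolute difference of their
ternary calls over a chosen region mask, range [0, 2]; coordinates where
either sample is missing are deleted, and having no shared coordinate is
an error rather than an imputation. The mask exists because clustering is
typically restricted to the chromosomes or the selected ("highlighted")
segments of interest.

UPGMA is implemented directly: repeatedly merge the pair at the smallest
distance at a height equal to that distance, updating distances by the
size-weighted average (equivalent to the mean over all leaf pairs). Ties
on the minimum are broken by the lexicographically smallest pair of
cluster-creation indices, making the tree deterministic under any input
order. Heights are non-decreasing (ultrametric), a tested invariant.
`cut_tree(k)` undoes the `k − 1` highest merges; `reassign` supports the
manual correction workflow. Newick export writes branch length = parent
height − child height. scipy's hierarchy module is used only as an
independent cross-check in the tests.

## Annotation and CNV masking

Annotation tracks are local BED4+ files (genes with cross-reference and
disease payload attributes, catalogued CNVs, variants, expert notes);
there is no network dependence. Region reports join each tested region
with every overlapping record — overlap means ≥ 1 bp intersection under
half-open arithmetic, so abutting intervals do not overlap — via an
interval-tree index whose correctness is defined (and tested) against a
brute-force all-pairs scan.

A region is *CNV-masked* when the union of its CNV overlaps covers at
least `min_fraction` of its length (default 0.5). Masked regions keep
their statistics but are flagged and removed from the default selected
set, reflecting the convention that an aberration coinciding with a
common germline CNV is usually not pathogenic. The 0.5 default is a
judgment call — any-overlap is too aggressive with large CNV catalogs —
and is configurable. Masking is monotone in the threshold. Expert notes
are retained by appending (deduplicated) to the local note track, so
later runs see them: a deterministic retrieve/reuse/retain loop with the
revision step left to the human.

## Synthetic cohorts

The generator emulates a small clinical cohort: pathology groups of flat
(copy-neutral) profiles plus three effects — planted recurrent
aberrations (carriers drawn per region with a penetrance, adding ±effect
log-ratio), sporadic background aberrations (per-cell/per-segment
Bernoulli, random sign), and Gaussian segment noise. Default study
conditions: 2 groups × 20 samples, two chromosomes (100 and 80 Mb) with
2-Mb grid segments, three planted 4-Mb regions (penetrance 0.9, effect
1.0), background rate 0.05, noise SD 0.2, and calling at `m = 0.1`,
`t_l = t_g = 2` — i.e. a dead zone of 0.2 log-ratio units, one noise SD.
Oligo mode draws each sample's breakpoints as a Poisson process
(default 3×10⁻⁷/bp ≈ 30 breakpoints per 100 Mb) with planted-region edges
forced for carriers. All randomness flows from the single `seed` through
one `numpy` Generator.

What the generator does **not** model: probe-level intensities, dye bias,
GC waves, segmentation errors, aneuploidy-scale events, or correlated
noise along the genome. Passing the recovery tests therefore demonstrates
that the statistical machinery behaves as designed under its own model,
not that real cohorts of this size will show the same power.

`make_tracks` emits gene and CNV fixtures keyed to the planted regions
(one gene centered in each; full-cover CNVs over alternating planted
regions; short decoys elsewhere) plus a manifest of which regions should
end up masked, so annotation and masking can be verified against a known
answer.

## Measured operating characteristics

The suite and `scripts/acceptance.py` recompute, rather than assume:

* **Null calibration** — with no planted signal the raw-p selection rate
  at α = 0.05 is checked against the 99% binomial band over ~2,070
  region-tests. This uses 40 samples per group, a size at which the
  expected gain/loss cell counts (~6) put the χ² branch of the switching
  rule inside its asymptotic comfort zone; at 20 per group the exact test
  dominates and its discreteness makes selection conservative.
* **Power / false selections** — under the default planted conditions all
  planted regions are recovered at BH ≤ 0.05 over 20 seeded cohorts with
  a false-selection fraction well under 5%.
* **Cluster recovery** — two pathologies with disjoint, fully penetrant
  four-region profiles are separated by `cut_tree(·, 2)` over the
  aberrant segments in ≥ 95 of 100 seeded runs (full penetrance and
  16 informative segments are what "well-separated" means here; at
  penetrance 0.9 over 8 segments the noise floor of the 0.2-SD/0.2-dead-zone
  regime already costs a few percent).
* **Exactness** — the Freeman–Halton p equals an independent
  rational-arithmetic enumeration; UPGMA's cophenetic matrix equals naive
  leaf-pair averaging; interval joins equal the all-pairs scan.

Problem sizes in the tests (90-region grids, ≤ 40 samples, ≤ 8-leaf
oracle comparisons, 100-seed recovery loops) were chosen so the whole
suite runs in seconds while keeping every binomial band meaningful.

## Numerical and degenerate-input policy

* Exact-test tie tolerance `ε = 1e−12` on table probabilities; p clipped
  to 1 from above (a one-table support can give `1 − 4e−16`).
* Zero-margin χ² columns dropped with df reduction; one remaining column
  → undefined test, `p = 1`, never selected.
* `mad1dr` of constant (or alternating-constant) input is an error, not 0.
* Distances with no shared non-missing coordinate are an error, not 0.
* Writers emit shortest round-trip float representations, so
  `read(write(x))` is bit-exact and pipeline reruns are byte-identical.

## Known limitations

* The exact test enumerates 2×3 tables only; larger group structures are
  handled one-vs-rest, not jointly.
* The mad1dr estimator assumes locally flat profiles; extremely
  fragmented genomes inflate it.
* UPGMA inherits average-linkage pathologies (chaining on elongated
  clusters); the manual `reassign` step exists precisely because expert
  correction is part of the intended workflow.
* BAC wide input must share one grid across samples; heterogeneous wide
  files should be exported long and harmonized.
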