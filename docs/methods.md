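# Methods

## Coordinate model and interval algebra

All genomic regions are 0-based half-open intervals (BED convention). Two
intervals overlap iff they share at least one base pair; book-ended
intervals do not overlap. `merge_with_gap` reproduces `bedtools merge -d`
semantics: intervals on one chromosome are stitched when
`next.start − prev.end ≤ gap`, so `gap = 0` merges overlapping and
book-ended intervals. `normalize()` on an interval set is a gap-0 merge,
after which intervals are sorted and pairwise non-overlapping. Distances
from an interval to a point are edge distances — 0 if the point is covered,
otherwise the distance to the nearest covered base (`end − 1` being the
last one). These choices are conventions of the underlying tools rather
than published statements; in particular no minimum overlap fraction is
imposed anywhere (1 bp suffices), and the half-open convention is an
internal decision applied consistently.

The implementations are simple sweep lines over sorted coordinates. The
test suite checks them against an independent base-pair bitmap oracle
(paint, dilate by the gap, read off runs) on ≤100 kb toy genomes and
against the `bedtools` command-line tool.

## Enhancer and super-enhancer calling

A *putative enhancer* in a sample is a region supported by both H3K27ac
and H3K4me1: the union of the two peak sets is merged at gap 0 and merged
regions overlapped by at least one peak of each mark are retained. Merging
first and filtering for dual support keeps "double positive" a per-element,
testable property while matching the union-merge construction on
non-pathological inputs. H3K4me1-only regions are never retained.

*Super enhancers* are called from H3K27ac peaks alone: peaks within
12.5 kb (inclusive, the `-d 12500` semantics) are stitched, and stitched
spans strictly larger than 15 kb are super enhancers, each carrying the
number of constituent peaks. Both thresholds live in `LandscapeConfig` and
are user-variable; the defaults are the field's standard stitching
parameters. There is no signal-ranked (hockey-stick) step and no promoter
exclusion — the rule is purely geometric.

*Consensus* sets union-merge all samples' elements at gap 0, annotate each
merged region with the number of supporting samples (any-overlap), and
keep regions supported by at least `min_support` samples (default: all).
Consensus elements are reported as merged-union intervals, not per-sample
originals; per-sample "shared" fractions are computed as the fraction of a
sample's own intervals overlapping consensus regions, which is how
per-specimen percentages are naturally quoted. Whether consensus regions
should instead be bp-intersections is genuinely open; any-overlap union
regions were chosen and are what the support partition reports.

## Expression strata and gene linking

Raw RNA-seq counts are scaled per sample by `56.5e6 / total mapped pairs`
(the reference depth is configurable). Active genes are FPKM ≥ 1
(inclusive) in FPKM mode, or cross-sample mean normalized count strictly
> 1 in count mode — the two filters deliberately differ in strictness at
the boundary, matching their separate definitions. FPKM strata partition
[0, ∞): inactive < 1 ≤ low < 5 ≤ mid < 15 ≤ high. The mid stratum is named
explicitly (only low and high are usually discussed) because a total
classification is needed.

Elements are associated with **every** gene whose TSS lies within a window
(default 100 kb) of the element's edge on the same chromosome — not only
the nearest gene — because element–stratum fractions count relations, not
unique neighbours. When gene models arrive as spans, the TSS is the start
for `+` genes and `end − 1` for `−` genes; an explicit `tss` column
overrides. Per-stratum association fractions are element-level: the
fraction of elements with at least one associated gene in the stratum, an
element possibly counting in several strata. Colocalization with a TF's
occupancy peaks is the percentage of elements overlapping at least one
occupancy interval.

Loop-scoped candidate selection picks loops with one anchor containing the
gene's TSS and returns all peaks overlapping the selected loops' full
spans (anchor1 start to anchor2 end). Activity scores (e.g. signature
T-scores) are consumed as an input vector; their computation is out of
scope, and the activity–expression relation is summarized by the standard
product-moment correlation.

## Perturb-seq activation calling

Cells with exactly one detected gRNA are grouped by that gRNA; multi-gRNA
cells are excluded, and zero-gRNA cells are excluded with them because
they carry no identity to group by. The none/single/multi fractions are
reported. Normalization is median-total scaling (each cell's counts scaled
to the median cell total), a deliberately simple stand-in for heavier
single-cell normalizations, switchable to raw mode; rank-based testing is
invariant to this monotone scaling, so the choice mainly affects fold
changes. Fold changes are ratios of group means in linear space (no log
convention), stabilized by a pseudocount (default 0.01, configurable, and
set to 0 when exact scale invariance is wanted).

A known target is *activated* when FC > 1.5 (strict). Discovery mode runs
a two-sided Mann–Whitney rank-sum test per gene against the control group,
adjusts across genes with Benjamini–Hochberg (via statsmodels, checked in
tests against a direct step-up computation), and calls genes with FC > 1.5
and adjusted p < 0.05, ranked by adjusted p then |log FC|. Both thresholds
are strict inequalities. Groups must have at least `min_cells_per_group`
(default 10) cells.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure of the pipeline's inputs,
with exact planted truth:

- **Landscape** — planted double-positive regions appear in both marks of
  every sample (edges jittered ±100 bp by default, keeping the region
  centre covered), and drop out of a sample with probability `dropout`
  (default 0.2), which controls consensus fractions; single-mark decoys
  carry one mark only. Valid super-enhancer clusters satisfy the
  gap ≤ 12.5 kb and span > 15 kb rules by construction; decoys violate
  exactly one (an oversized internal gap whose resulting pieces each span
  ≤ 15 kb, or a compliant-gap cluster whose whole span is ≤ 15 kb). Peak
  widths are lognormal with median ≈ 1 kb and σ_log 0.4 — a generic
  ChIP-peak stand-in, since no width distribution is published.
- **Placement** — planted entities are laid out left-to-right with a guard
  spacing exceeding both twice the association window and twice the merge
  gap, on chromosomes reserved for the landscape; far-placed genes and
  loops get their own chromosomes. This makes every recovery exact at
  truth level and is the reason the generator errors out, rather than
  degrading, when the genome is too small.
- **Genes/expression** — stratum counts are exact (largest-remainder
  quotas); for each configured association fraction, exactly
  `round(f · n_elements)` elements receive one gene of that stratum at a
  uniform 5–95 kb edge distance; all other genes are placed farther than
  the window from every element. Per-sample FPKM is drawn uniformly inside
  the gene's stratum bounds (high capped at 150), so classification of the
  emitted table reproduces the planted strata exactly. Counts are negative
  binomial with mean ∝ FPKM (dispersion 0.3); per-sample depths default to
  50, 56.5 and 65 million pairs.
- **Occupancy/loops** — each planted super enhancer/enhancer independently
  receives an overlapping occupancy interval with probability 0.76 / 0.20;
  loops have one anchor over a dedicated gene's TSS, the other ~90 kb
  away, with 7 candidate peaks planted inside the span and one decoy
  beyond it — the operating point of the worked cis-element example.
- **Perturb-seq** — cells are 16.3 % gRNA-free, 56.7 % single-gRNA and
  27.0 % multi-gRNA by default (the reported assay mixture); identities
  are uniform over eight targeting gRNAs plus a scramble control. Counts
  are negative binomial (dispersion 0.5) around lognormal baseline means;
  each targeting gRNA's responder gene has its mean multiplied by the
  planted fold change (default 3×) in that gRNA's single-gRNA cells.
- **Activity correlation** — bivariate-normal (score, expression) pairs
  with planted ρ = 0.47 over 43 specimens by default.

One global seed expands into named substreams (landscape, genes,
occupancy/loops, perturb, activity) via `numpy` `SeedSequence.spawn`, so
generators are individually reproducible and adding draws to one does not
perturb the others. All emitted files are plain text (BED, BEDPE, TSV,
MatrixMarket) and byte-identical across runs with the same configuration.

The generators do **not** emulate read-level noise, peak-calling
uncertainty, signal strength, sequence content, GC or mappability biases,
correlated dropout between marks or samples, ambient RNA, or doublets.
Passing planted-truth tests therefore demonstrates that the decision rules
and their thresholds are implemented correctly and recover known structure
under realistic interval geometry and count noise — not that the pipeline
is robust to upstream artefacts of real ChIP-seq or scRNA-seq data.

## Numerical and testing choices

Problem sizes in the test and acceptance runs — 50 planted regions for
exact-recovery checks, 1,000 regions for the dropout closed form, 2,000
elements for fraction recovery, 40–50 replicates for calibration and power
and 200 for correlation recovery — were chosen so binomial sampling error
is comfortably inside the asserted tolerances while a full run stays in
the seconds range. Shared-fraction recovery is asserted on the mean across
samples (the per-sample fractions are exchangeable and each carries ~1.8
points of binomial noise at 1,000 regions). Degenerate inputs fail loudly:
empty mark sets warn and return empty enhancer sets, empty control groups
after gRNA filtering are errors, zero-variance correlation inputs are
errors, and malformed BED/BEDPE lines are reported with their line number.

## Known limitations

- Consensus "common" regions are any-overlap union intervals; studies
  reporting bp-intersections will count slightly differently.
- The activation caller's known-target mode has no significance test by
  design (a pure fold-change rule); its false-positive behaviour under
  strong overdispersion is governed entirely by the 1.5× margin.
- The discovery mode's rank-sum test treats cells as exchangeable
  replicates; batch structure and cell-cycle covariates are not modelled.
- BED extra columns are preserved through I/O but never interpreted;
  there is no bigWig/signal support and no peak calling.
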