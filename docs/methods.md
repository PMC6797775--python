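# Methods

## Model and procedure

`epivariant` treats a case-control ChIP-seq cohort as a peaks × samples
matrix of normalized coverage *q* and asks, per case sample and per
locus, whether that sample is an outlier relative to the entire control
panel.

**Normalization.** Depth correction is promoter-anchored rather than
whole-library: 4-kbp windows centered on every TSS are merged
(maximal-union semantics, touching windows merge) into a promoter set;
each sample's reads inside the set give a tally *T* and the factor
*s* = *T*/10⁷. Per-base coverage is divided by *s* and summed over each
peak. Anchoring on promoters assumes the aggregate promoter signal is
stable across individuals — appropriate for a promoter mark like H3K4me3,
where most of the genome-wide signal sits in promoters and global
promoter activity is not expected to differ between groups. A read counts
toward the tally when its 5′ mapped position lies in the promoter set;
users with another convention can supply tallies directly. Windows are
clipped at coordinate 0; clipping at chromosome ends would require
chromosome lengths and is deliberately not performed.

**Outlier rule.** A peak is called up in a case when its *q* is at least
5, at least 1.5× *every* control, and the upper-tail probability of the
case value under a normal fit to the controls (mean, *n*−1 SD) is below
0.01; down calls mirror this (every control ≥ 5, case ≤ 0.5× every
control, lower tail < 0.01). All threshold comparisons are inclusive
("at least"/"at most") and exact — no epsilon. The tail is one-sided in
the direction tested, matching the separate up/down selection. With
σ̂ = 0 the fitted normal degenerates to a point mass and the p-value is
defined as 0 when the case differs from the control mean in the tested
direction, else 1; this keeps identical-control fixtures callable.

**Locus filters.** Before testing, peaks are removed when (a) the pooled
fraction of reads with MAPQ < 10 is ≥ 0.75 (mappability artifact — a
locus property, so fractions are pooled across all cohort samples), or
(b) the cohort mean of *q* across all samples is < 2.5. The low-coverage
rule could plausibly target the case value or the control mean instead;
the cohort mean was chosen as the symmetric reading, and the exclusion
reason is recorded per peak in the calls table so users can audit the
choice. Peaks with no MAPQ information are not excluded by rule (a):
absence of evidence of bad mappability.

**Recurrence.** Calls are grouped by (peak, direction) — the primary
view — and also per peak irrespective of direction, since one locus can
be up in one case and down in another. The singleton fraction (share of
called loci seen in exactly one case) is reported for both groupings; it
is undefined (NaN) when there are no calls.

**Subgroup screen.** Pairwise Pearson correlation of the per-peak *q*
vectors over all samples; a case pair (or larger cluster) is flagged when
every within-cluster correlation exceeds each member's mean correlation
to all samples outside the cluster by at least δ = 0.05. Candidate pairs
are closed into connected components and each component is re-verified;
the procedure is deterministic. δ = 0.05 separates the motivating
pattern (a mutual PCC near 0.97 against a cohort mean near 0.89) with
margin while not firing on homogeneous cohorts. Flagged subgroups are
intended to be re-run as separate case subsets against the full control
panel (`case_subsets` in the run config).

**Enrichment.** A peak links to a gene when any of the gene's TSSs lies
strictly within 2,000 bp of the peak (distance 0 inside). Categories
partition the catalog: protein_coding if any linked transcript is
protein-coding (dominance — required for disjoint counts, and
conservative for claims about noncoding enrichment), noncoding if linked
only to non-coding transcripts, else unannotated. All enrichment tests
are one-tailed Fisher exact tests in the enrichment direction
(hypergeometric upper tail via `scipy.stats.hypergeom`); category rows
use Bonferroni with m = number of rows tested in the run (4 by default:
annotated union + three categories; m is logged), gene-set and
GWAS-overlap batteries use Benjamini–Hochberg FDR at 0.05
(`statsmodels`). GWAS region sets are built by flanking every variant
below a p threshold (default 5 × 10⁻⁸) by 100 kb on each side and
merging; the overlap test restricts the peak universe to peaks
overlapping the analogous regions built from *all* tested variants, which
reads the "whole tested variant set as background" prescription as a
peak-universe restriction. The canonical battery is six tests per
dataset: up, down and all peaks for each of two case subsets.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `up_fold` / `down_fold` | 1.5 / 0.5 | fold | per-control fold thresholds (inclusive) |
| `min_case_cov_up` / `min_ctrl_cov_down` | 5 | normalized units | coverage floors for up/down rules |
| `nominal_p_max` | 0.01 | probability | normal-model tail cutoff |
| `low_cov_exclude` | 2.5 | normalized units | cohort-mean coverage filter |
| `mapq_frac_exclude` | 0.75 | fraction | pooled low-MAPQ exclusion (inclusive) |
| `gene_link_dist` | 2000 | bp | TSS-to-peak linkage (strict <) |
| promoter half-window | 2000 | bp | 4-kbp promoter windows |
| GWAS flank | 100000 | bp | region half-width around passing variants |
| subgroup δ | 0.05 | PCC units | margin for flagging correlated case pairs |

## Synthetic cohorts

`simulate_cohort` emulates the statistical structure the detector
assumes: per-peak baseline *q* is log-normal (log-mean ln 20, log-sd 1.0 —
a heavy-tailed spread with most peaks in the tens of normalized units,
so the 2.5 eligibility floor removes only a small tail), each sample
multiplies by independent log-normal noise with CV 0.15 (a realistic
between-individual spread for a well-behaved promoter mark), spiked
(peak, case) pairs multiply by a configured fold, and per-sample library
factors in [0.5, 2] scale raw coverage and promoter tallies jointly so
normalization cancels them exactly. Cohort defaults are 16 cases and 16
controls. Randomness is split into named child streams (baseline,
per-sample noise, artifacts, library factors) from one seed, so bundles
are byte-reproducible and changing one knob cannot perturb unrelated
draws; the seed and file checksums go into the bundle manifest.

Two constructions keep recovery experiments meaningful rather than
silently vacuous: down-spiked peaks have their baseline floored at 25
normalized units and their control values floored at 5, because the down
rule requires every control ≥ 5; and the 1% of peaks assigned a
mappability-artifact fraction (uniform in [0.75, 1]) are drawn from
non-spiked peaks, so artifact filtering is tested independently of spike
recovery. Emitted bedGraph tracks use rectangular per-peak profiles
(uniform per-base value *q·s*/width) — sufficient because quantification
only sums per-base values.

What the generator does **not** model: real peak shapes, genome sequence
and mappability structure, fragment-length effects, GC bias, correlated
(batch) noise between samples, or biological covariance between nearby
loci. Passing recovery and calibration tests therefore demonstrates that
the decision rules behave as specified under their own distributional
assumptions, not that those assumptions hold for any particular real
dataset.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; reports print 1-based
  inclusive. Chromosome names are matched verbatim.
- Coverage tracks are step functions on disjoint sorted intervals;
  overlapping bedGraph records are rejected, gaps read as zero. Interval
  sums use prefix sums (exact for the rational inputs involved;
  oracle-checked to 1e-9).
- The up-call fold against controls is computed as *q*/max(controls); a
  control at 0 satisfies the fold clause trivially, and the down rule's
  own coverage floor (≥ 5) rules out division by zero there.
- Zero-variance samples get missing (NaN) correlations; the diagonal is
  1 by definition.
- Fisher odds ratios report (a·d)/(b·c), with 0/0 as missing and x/0 as
  infinity. Empty foregrounds, empty universes, empty gene lists and
  empty promoter tallies raise immediately rather than returning
  degenerate results.
- Normalization factors accept non-integer tallies so rescaled or
  averaged tallies keep the factor exact.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
data at desk scale, the package's own choice of problem size: detector
oracle-equivalence uses 1,000 random 200-peak, 4-case/8-control
matrices; recovery and null calibration use 16 + 16 cohorts of 5,000
peaks (50 + 50 spikes over 10 seeds for recovery in the suite, 3 seeds
in the acceptance script; 20 and 5 null seeds respectively); the exact
test is swept exhaustively over all 2×2 tables with N ≤ 200. Cohort-scale
headline counts from any particular real study (which depend on raw data
not shipped here) are outside what these checks can reproduce; the
self-contained published contingency rows and shares that are
recomputable from printed margins are recomputed exactly.

## Known limitations

- The normal model for the nominal p is a convenience fit to 16 control
  values; with heavy-tailed real noise its tail probabilities are
  optimistic, which is why the fold-versus-every-control clause, not the
  p-value, carries most of the specificity.
- No multiple-testing correction is applied to nominal outlier p-values
  (by design, matching the operating point); recurrence counts and
  enrichment q-values are the cohort-level evidence.
- Covariates (age, sex) are carried as metadata only; no adjustment.
- BAM ingestion is not built in: per-peak coverage, promoter tallies and
  MAPQ summaries arrive as text tables, which standard tooling
  (samtools/bedtools) produces readily.
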