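# Methods

This note documents the models, conventions and numerical choices
behind `mhsig`, in the spirit of a statistical software methods
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinates and normalization

All internal intervals are 0-based half-open; COSMIC-style cohort
tables (1-based inclusive) are converted on input and BED is consumed
natively.  Half-open arithmetic makes the ±20 bp flank windows
off-by-one safe.  Every deletion is left-aligned (shifted to its
leftmost equivalent representation, the VCF normalization convention)
before flank extraction, because cohort dialects report equivalent
deletions at different coordinates and the signature must not depend on
the representation.  Left-alignment invariance is property-tested
against a brute-force oracle that enumerates all same-length intervals
with the same derived sequence.

## The microhomology scan

For a deletion with deleted sequence D (length L) and flanks within a
window W = 20 bp:

* a **right-side** candidate of length k compares `D[0:k]` with the
  first k bases of the right flank (the retained downstream MH copy);
* a **left-side** candidate compares `D[L-k:L]` with the last k bases
  of the left flank;
* k ranges over 1..min(L, W, flank length).

A single mismatch is tolerated only when `allow_mismatch` is on, the
raw match length is ≥ `min_k_for_mismatch` (default 4), and the first
and last compared bases match exactly.  Rationale: a 2-bp "MH" with one
mismatch is 50% identity and would inflate the MH class, and a terminal
mismatch is indistinguishable from a shorter exact match; anchored
termini follow annealing intuition.  Any comparison involving `N`
counts as a mismatch.  The call maximizes effective length k − m, ties
preferring fewer mismatches and then the right side (the orientation
the repair model depicts).  Classification uses the effective length,
so a 3-bp match with one mismatch does not reach the 2-bp MH bar.

Both junctions are scanned and the maximum taken: for an arbitrary
deletion either junction may carry the homology.  The scanner is
verified against `mh_oracle`, a deliberately naive exhaustive
enumeration of every (side, k, mismatch placement), on ≥ 10⁴ random
contexts per run.

Classification thresholds (≥ 5 bp long, ≥ 2 bp MH, < 5 bp short) and
the curation thresholds (MAF ≥ 1e-4 removed; ≥ 10 unique samples for
the recurrent view) live in one `ScanConfig` object.

## Cohort curation

The filter chain runs dedup → isoform merge → myeloid tissue → region →
adjacent SNPs → population MAF → publication count, mirroring the order
such cohort analyses describe, with a per-step audit report.  Choices
where the procedure is under-specified:

* canonical CDS name for isoform-merged records = most frequent name,
  ties lexicographic;
* "adjacent" SNPs = within the same 20 bp window used for MH scanning;
* `region_class` **unknown** is retained (only what can be annotated is
  filtered); empty publication sets count as single-publication
  (conservative removal);
* missing MAF is kept distinct from 0.0 and never filters a record;
  site/histology matching is case- and separator-insensitive substring
  matching.

Every filter is idempotent and the chain report reconciles
(input = removed + retained, stepwise).

## MMEJ product prediction

Given a cut at gap position c, a product is an exact k-mer pair
(i, j, k) with `seq[i:i+k] == seq[j:j+k]`, 2 ≤ k ≤ 25, the cut between
the copies (i + k ≤ c ≤ j), and both copies within 60 bp of the cut.
The deletion is [i, j) — one copy plus the spacer — and its length is
at least k.  Cuts inside an MH copy are excluded (conservative reading
of the annealing geometry; configurable k/window bounds cover a 52-bp
product with margin).  For each (i, j) only the maximal k is reported,
and a pair whose match interval is contained in a longer reported pair
on the same diagonal is suppressed as a sub-match.  Ranking is
structural — k descending, deletion length ascending, then position —
because product *frequencies* are an experimental observable, not
something this geometry predicts.  The enumerator is property-tested
against a brute-force triple enumeration and against the scanner
(closure: every predicted product, treated as a deletion, scans back
with MH ≥ k).

## CRISPR quantification

Per experiment: variants shared with the unedited control are removed
by exact (pos, ref, alt) key; allele percent is each variant's
modified-read count over the sum of modified reads; overall
modification frequency is the sum of modified reads over the mean
depth.  By default only indel alleles enter these sums (whether
substitution reads belong in the denominator is ambiguous in the
field's descriptions; a flag includes them).  "Modified reads" per
variant is the caller's alt-supporting count field (AD-style by
default, configurable).  Replicates are summarized as mean ± SEM with
the sample standard deviation (ddof 1), the convention behind n = 3
figure legends; conditions are compared with Student's pooled-variance
two-tailed t-test (Welch behind a flag — "unpaired two-tailed t-test"
conventionally means the pooled form).

## Statistics

The chi-squared statistic with Yates continuity correction is computed
from its formula, with the correction term floored at zero when
|O − E| < 0.5; p-values come from scipy's chi2 and t distributions.
Both tests are cross-checked in the suite against
`scipy.stats.chi2_contingency` / `ttest_ind` to ≤ 1e-10 relative error
on 10³ random tables.

The correlation contrast computes Pearson r between an anchor gene and
each test gene twice — over a metacell subset and over all metacells —
and flags subset-restricted co-expression: r_subset ≥ r_hi and
r_all ≤ r_lo.  Constant expression vectors yield *missing* r, never 0.
Defaults r_hi = 0.45, r_lo = 0.1: at the 50-metacell subset size used
throughout, r = 0.45 corresponds to a correlation p ≈ 1e-3, which
keeps a null gene's false-flag rate near 10⁻³ so that a 20-gene panel
stays clean in ≥ 95% of null runs while a planted r = 0.8 is flagged
essentially always.  A lower magnitude bar (e.g. 0.3 ≈ 2σ at n = 50)
cannot achieve both properties at this subset size for any panel of
more than a few genes.  Both thresholds are arguments, echoed in the
output.

## Synthetic data

The generators are pure functions of (seed, parameters) — identical
bytes per seed — and each emits a ground-truth manifest that downstream
recovery tests treat as the only source of truth.

* **Planted-MH references.**  Each locus embeds one k-mer twice around
  a spacer.  The background is constructed over disjoint two-letter
  alphabets on the two sides of the cut ({A,C} upstream, {G,T}
  downstream), which guarantees no unplanned repeat straddles the
  break — over a 4-letter alphabet with 60 bp windows, uniformly random
  background almost surely contains spurious 2–3-mer pairs, so
  uniqueness of small planted MHs is otherwise unattainable.  The
  exhaustive scanner and the product enumerator verify every locus
  (planted pair unique at ≥ k, rank 1 at the midpoint cut, effective
  length exactly k), with bounded rejection (default 1000 attempts;
  failure is an error, never a silent parameter change).
* **Deletion cohorts.**  Class labels are apportioned exactly
  (largest-remainder rounding of n × mixture), so a perfect classifier
  recovers planted counts exactly; MH records use natural uniform
  background verified by the exhaustive scanner, long-no-MH records are
  rejection-sampled to ≤ 1 bp effective MH, short records are
  unconstrained.  Contaminants are mutually exclusive per-record
  Bernoulli draws: germline-like (MAF ≥ 1e-4 in one population
  dataset), lymphoid histology, or single-publication.
* **CRISPR calls.**  Three outcomes (the recurrent MH deletion, a 2-bp
  deletion and a 1-bp insertion at the cut) receive
  Multinomial(Binomial(depth, editing_rate), fractions) read counts at
  depth 5000, the depth of the amplicon experiments being emulated;
  two background variants are shared with the control table.
  Replicates share a locus via `amplicon_seed`.  VCFs are written as
  deterministic text and read back through pysam.
* **Metacell expression.**  The anchor/planted pair is bivariate normal
  with the planted correlation inside the subset and independent
  outside; other genes are independent noise; values are shifted
  non-negative (Pearson r is shift-invariant).  Defaults: 20 genes ×
  2000 metacells, subset 50.

What the generators do **not** model: sequencing error profiles,
read-level data, microsatellite context for short deletions, realistic
gene-expression distributions, or LD structure among SNPs.  Passing
recovery tests therefore demonstrates correctness of the computations
under the stated statistical models, not robustness to real-data
artifacts upstream of variant calling.

## Problem sizes and determinism

The test suite and the acceptance script use: 10⁴ random contexts for
scanner–oracle equivalence, 1000-record cohorts, 500 planted loci for
predictor closure, 20 seeded CRISPR runs at depth 5000, and 100 + 100
seeded runs for the correlation power/null rates — sizes at which every
stochastic acceptance bound holds with comfortable margin while the
whole battery completes in seconds.  All randomness flows through
`numpy.random.default_rng` seeds; reruns with the same configuration
are byte-identical, and pipeline runs echo their effective
configuration and version into the output directory.

## HGVS conventions

Only deletion (`c.100_104del5`), nonsense (`p.R693*`) and frameshift
(`p.E635fs*15`) forms are parsed.  A declared deletion-length suffix
must equal the coordinate span.  For `fs*N` the default convention
takes the changed residue as codon 1 of the shifted frame and codon N
as the stop, so the last intact residue is pos + N − 2; the alternative
reading (N readthrough codons before the stop, pos + N − 1) is
available via `fs_convention="stop_excluded"` since published usage is
ambiguous at ±1 residue.

## Known limitations

* MH scoring is unweighted: no thermodynamic or distance-decay scores,
  and no templated-insertion detection.
* The predictor enumerates geometry only; it does not rank products by
  expected frequency.
* Short-deletion calls do not discriminate microsatellite context.
* The cohort readers cover the three dialect patterns exercised here;
  other tables need a `CohortDialect` mapping.
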