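# Methods

This note documents the models, defaults and design choices behind
`methdyn`, and what the synthetic-data-based test suite does and does
not demonstrate.

## Data model and conventions

All coordinates are 0-based and intervals half-open `[start, end)`,
internally and in every BED written. A methylome track is an ordered
table of cytosines with a protected-read count (`meth`) and a total
count; the per-site methylation level is their ratio and is undefined
at zero coverage (zero-coverage sites are skipped, never imputed).
methcounts-style input stores `(level, coverage)` rather than counts;
counts are reconstructed as `round(level × coverage)` with
round-half-to-even, which is lossless for any file the package itself
writes. Symmetric CpG dyads (a minus-strand CpG at `p` pairing the
plus-strand CpG at `p − 1`) are merged by summing counts into one
plus-strand record; unpaired sites pass through, making the operation
idempotent and count-conserving. Downstream statistics default to
merged dyads; per-strand analysis is possible by simply skipping the
merge.

The bisulfite conversion rate is estimated from non-CpG (CHH/CHG)
cytosines, which are essentially unmethylated in mammalian somatic
cells: `rate = converted non-CpG reads / total non-CpG reads`.

## HMR segmentation

A two-state hidden Markov chain runs along the covered CpGs of each
chromosome: state 0 "hypo" (regulatory, lowly methylated), state 1
"hyper" (background). Emissions are **beta-binomial** — the methylated
count at coverage *n* is Binomial(*n*, *p*) with *p* ~ Beta(α, β) per
state — because ~5× WGBS counts are overdispersed relative to a plain
binomial (biological heterogeneity, conversion noise). A binomial
emission family is available as a configuration fallback.

Fitting is Baum–Welch EM with a scaled forward–backward pass. The
transition and initial-distribution updates are the standard closed
forms; the beta-binomial emission update has no closed form and is
maximized numerically in (logit mean, log concentration), starting from
the current values and accepting a solution only if it does not
decrease the expected complete-data likelihood — preserving EM's
monotone log-likelihood, which the test suite asserts on every fit.
The concentration is bounded in [0.5, 5000] to keep the likelihood
surface well-conditioned. Defaults: hypo mean 0.1, hyper mean 0.8,
concentration 10, self-transition 0.99, tolerance 1e-3, at most 100
iterations, with optional seed-controlled jitter for restarts. State
identity (hypo = lower mean) is re-imposed after each M-step, so label
switching cannot occur. With `tol = inf` the fit degenerates to a
single E-step and returns the initial parameters — useful for decoding
under fixed parameters.

Decoding is by posterior marginals (γ > 0.5); maximal runs of
hypo-labelled CpGs become HMRs spanning first CpG position to last CpG
position + 2 (covering the dyad). Runs are split wherever consecutive
covered CpGs are more than `gap_limit = 1000` bp apart, so CpG deserts
never bridge two distant hypomethylated loci into one spurious
mega-HMR. A `min_cpgs` filter (default 1) is exposed rather than
hard-coded. The forward–backward recursion is validated against
exhaustive enumeration over all 2ⁿ state paths on chains of ≤ 12 CpGs
(agreement to 1e-9).

**Canyons** are HMRs of length ≥ 3500 bp ("3.5 kb or longer" — the
boundary length itself qualifies); the classifier is a pure threshold
filter, invariant to input order. Length-set comparisons use the
two-sample Kolmogorov–Smirnov statistic (scipy), checked against a
brute-force ECDF supremum in the tests.

## Differential methylation

The per-CpG score is the posterior probability that the level in
track A exceeds that in track B under independent uniform-prior Beta
posteriors, `p_A ~ Beta(k_A+1, n_A−k_A+1)`. With integer parameters
this has an exact finite-sum expression, evaluated in log space; the
suite checks it against numerical quadrature to 1e-8 over the complete
grid of count pairs with totals ≤ 20. This is a reimplementation choice
for "differential methylation score", not a claim of bit-compatibility
with any external program. Sites covered in only one track are skipped
and counted.

DMR candidates are the set-differences of the two HMR sets: the parts
of A's HMRs not covered by B's HMRs are candidate hypo-in-A regions,
and vice versa — a DMR is a place where an HMR exists in one methylome
but not at the same location in the other. A fragment is retained iff
it spans **≥ 10 jointly covered CpGs** of which **≥ 5 are significant**
in the concordant direction, at a one-sided 0.95 level by default
(hypo-in-A ⇔ `P(p_A > p_B) ≤ 0.05`). Both thresholds and the level are
parameters. Swapping the inputs swaps directions but yields identical
intervals (asserted as a property).

DDMRs for one lineage are built from the three pairwise comparisons
(proB vs WT, proB vs KO, WT vs KO): all retained DMR intervals are
union-merged with 0 bp slack, each merged interval must be supported by
at least `min_support = 1` distinct comparisons (exposed up to 3), and
is annotated with its coverage-weighted mean methylation in each
condition — the 3-vector that pattern classification consumes. Region
means come from `Σ meth / Σ total` over CpGs in the half-open interval;
an interval with no covered CpG is reported missing, never 0.

## Pattern catalog and assignment

Templates are 3-vectors over {0.2, 0.5, 0.8} (low / intermediate /
high) across (proB, WT mature, KO mature). With only three points the
Pearson correlation coefficient is invariant to affine maps of the
template, which partitions the 24 non-constant templates into exactly
**12 equivalence classes** — six of "one condition apart" shape
(direction ∝ (2,−1,−1) up to sign and permutation) and six of graded
shape (∝ (1,0,−1)). The default catalog takes one representative per
class, so every non-constant template vector correlates perfectly with
exactly one catalog entry, and ids are chosen to carry the biologically
named trajectories: P1 developmental demethylation (0.8, 0.2, 0.2);
P7 partial demethylation completed by knockout (0.8, 0.5, 0.2);
P4/P9 developmental gain lost in the knockout; P5 knockout-insensitive
gain (0.2, 0.8, 0.8); P6 stable methylation erased only in the knockout
(0.8, 0.8, 0.2); P10/P11 paradoxical knockout gain. The catalog is a
TSV-loadable configuration object, not code, so an alternative vector
set can be dropped in verbatim.

Assignment is argmax-PCC with deterministic tie-breaking: affine ties
are resolved by smallest Euclidean distance to the observed vector
(preserving the low/intermediate/high magnitude semantics that
correlation alone discards), then by catalog order. A constant observed
vector has undefined correlation and is reported unassigned rather than
forced. Summaries report counts and fractions over assigned regions,
with the unassigned bin kept separate.

## TAB-Seq forward model and deconvolution

Let f = TET oxidation efficiency of 5mC, g = glucosylation protection
efficiency of 5hmC, c = bisulfite conversion rate, and (u, m, h) the
per-CpG fractions of unmethylated, 5mC and 5hmC (u + m + h = 1). A read
reports C (protection) with probability

* WGBS: `p_w = (m + h) + u(1 − c)`
* TAB-Seq: `p_t = h[g + (1−g)(1−c)] + m[(1−f) + f(1−c)] + u(1 − c)`

i.e. unprotected 5hmC (fraction 1−g) and oxidized 5mC (fraction f)
convert at rate c, unoxidized 5mC is always protected. Spike-in
controls invert this model directly: c from the unmethylated control's
converted fraction, g from `p_h = g + (1−g)(1−c)` on the pure-5hmC
control, f from `p_m = (1−f) + f(1−c)` on the pure-5mC control. Rates
solving outside [0, 1] are clamped with a warning; controls need ≥ 100
aggregate reads.

Both equations are linear in (m, h), giving a per-CpG 2×2 solve; the
system degenerates when `g ≈ 1 − f` (the two modified states become
indistinguishable in the TAB channel) and this identifiability failure
is raised as an error. At perfect efficiencies the solution reduces
exactly to `h = p_t`, `m = p_w − p_t`. Raw solutions outside the
probability simplex are replaced by the **residual-minimizing point of
the simplex** — a closed-form constrained least squares over the three
edges and corners of the feasible triangle — so the returned point's
model residual never exceeds that of any other simplex point (in
particular the Euclidean projection); raw solutions remain available
via `return_raw`. Per-CpG estimates at ~5× are noisy by construction,
so a region-level mode aggregates counts across an interval before
solving; that is how statements like "fraction of modified CpGs that
are hydroxymethylated" are operationalized. Both efficiency-corrected
and (via ideal efficiencies) uncorrected estimates can be produced.

The 5hmC boundary profile bins CpG-level h by signed distance from HMR
edges (positive pointing into the HMR interior from either edge,
strand-agnostic), with bin count `2·flank/bin`.

## Interval statistics

Jaccard is base-pair intersection over union after union-merging each
set. Reciprocal overlap requires the overlap to exceed `min_frac`
(default 0.5, strictly greater-than) of **both** intervals — the
reciprocal reading of "over 50% overlap" is the documented choice, with
an `either_side` flag for the single-sided variant. Nearest-TSS
distances are measured from the interval midpoint and signed by TSS
strand (negative upstream). Feature annotation labels an interval with
the highest-precedence feature it overlaps — promoter > TTS > 5′UTR >
3′UTR > exon > intron > intergenic — with promoter = TSS ± 1 kb and
TTS ± 100 bp windows by default (both configurable; the precedence
order and windows are this package's documented convention). Gene-set
overlap uses the two-sided Fisher exact test on the 2×2 membership
table against an explicit background (e.g. expressed genes); both sets
must be subsets of the background. Meta-profiles tile fixed-width bins
around interval centers, or resample bodies to a fixed bin count with
flanks, computing coverage-weighted mean levels; empty bins are
missing, not zero, and are excluded from column means so low coverage
cannot drag profiles toward zero. Track correlation over intervals is
Spearman (average ranks on ties) by default, Pearson behind a flag, and
undefined (missing) for constant inputs.

All of these are checked against independent brute-force oracles
(per-base counting, all-pairs scans, exhaustive nearest search,
hypergeometric enumeration, explicit rank computation) on randomized
inputs.

## Synthetic data: what it emulates and what it does not

The generator plants a two-layer methylome: a hypermethylated
background (0.85) with foundational HMRs (0.05) shared identically by
all conditions — a few drawn longer than 3.5 kb to be canyons — and
dynamic DME intervals whose per-condition levels follow a pattern
vector drawn per lineage from the catalog. Defaults encode the study
conditions: mean coverage 5× (Poisson per CpG), bisulfite conversion
0.985, two lineages × (proB, WT, KO), TAB-Seq efficiencies f = 0.90,
g = 0.97, spike-ins of ~10⁴ aggregate reads, and 5hmC as 10% of the
modified fraction. The default lineage pattern weights make ~75% of
one lineage's DMEs developmental-loss patterns (P1 + P7) — a
configuration choice mirroring the biology the pipeline targets, not a
claim. Genome defaults: two 1 Mb chromosomes, geometric inter-CpG gaps
with mean 100 bp, and CpG-island-like densification (mean 30 bp
spacing) inside planted regulatory intervals, reflecting the CpG
richness of real HMRs/enhancers and making the 10-CpG DMR filter
meaningful for ~1 kb intervals. Every draw is a pure function of
(config, seed); per-(lineage, condition, assay) streams are
independent, derived via CRC32-folded child seeds.

Not emulated: sequence content, read-level errors and mapping
artifacts, strand asymmetries, copy-number variation, partially
methylated domains, CpG-density-dependent methylation gradients, or
inter-replicate variability. Passing tests therefore demonstrate the
correctness of the algorithms under the stated noise model, not
robustness to every artifact of real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the default study at two
1 Mb chromosomes (~26,000 CpGs per track after densification, six WGBS
tracks plus TAB-Seq), which keeps a full run in tens of seconds while
leaving every per-interval statistic with ≥ 20 CpGs of support; the
segmentation-recovery check uses a 200 kb genome at 10× as its standard
condition. Degenerate inputs have defined behaviour throughout: empty
tracks, empty interval sets, zero-coverage sites, constant vectors and
identical HMR sets all either return well-defined empty/missing results
or raise a named error, as documented per function.

## Known limitations

* The emission M-step is a bounded quasi-Newton maximization; it
  guarantees monotone EM but not the global optimum — multi-start via
  seeded jitter is available where the likelihood surface is suspect.
* The exact diff-score sum is O(k_B) per site; for coverages in the
  hundreds a normal approximation would be faster, but WGBS coverages
  make this irrelevant and exactness is worth the cost.
* DMR boundaries inherit HMR boundary uncertainty (±2 CpGs under the
  default conditions); no sub-CpG refinement is attempted.
* Pattern classification assumes exactly three conditions; longer
  designs need a different catalog and are out of scope.
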