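# Methods

This note records the statistical models, parameter choices and numerical
conventions behind each analysis, the assumptions of the synthetic-data
generators, and the design decisions taken where more than one reading was
defensible.

## Differential isoform usage

An alternative-isoform event is summarized by four counts: inclusion- and
exclusion-junction reads in condition A (control) and condition B (mutant).
The isoform fraction in a condition is ψ = inc/(inc + exc); an event is
*testable* when both conditions have at least one junction read. An event
with zero reads in exactly one condition is reported with status
`untestable` rather than dropped, because silence and absence of signal are
different findings.

**Test.** Under the null hypothesis that both conditions share one
inclusion probability, that probability is estimated by pooling:
p̂ = (a_inc + b_inc)/(n_A + n_B). The p-value is the exact two-sided
binomial tail for the mutant library: with n_B = b_inc + b_exc,

p = min(1, 2·min( P[X ≤ b_inc], P[X ≥ b_inc] )), X ~ Binomial(n_B, p̂),

computed from the binomial CDF/survival function (scipy). Doubling the
smaller tail is the standard two-sided construction for discrete exact
tests; it is conservative, which the calibration test confirms empirically.
One-sided alternatives are available via the `alternative` argument.

*Asymmetry.* Because the tail is evaluated for the mutant library only, the
statistic is directional: swapping the two conditions changes which library
is tested and can change p when the totals differ. Exact swap-symmetry
holds when the libraries have equal totals and the pooled fraction is ½
(the binomial tails then mirror); Δψ always negates under a swap. A fully
symmetric exact alternative (conditioning on the total, i.e. Fisher's test)
is a different statistic with different tail values and is deliberately not
substituted.

**Log-odds.** The p-value is reported alongside log₁₀((1−p)/p), so a
log-odds of 1 equals 10-to-1 odds. This makes the ranking directly
comparable to a minimum-Bayes-factor-10 filter, whose corresponding chance
probability is 1/(1+10) = 0.0909. The base is configurable; 10 is the
default so the quorum lands at 1.0 exactly. Numerically, p is floored at
machine epsilon before the transform and the result capped symmetrically
(≈ ±15.65 at base 10); p ≥ 1 maps to log-odds 0.

**Filters.** A call is significant when |Δψ| ≥ 0.2 and log-odds ≥ 1.0
(both configurable). No multiple-testing correction is applied by default —
the filter pair already acts as a stringent evidence quorum — but
Benjamini–Hochberg adjusted p-values can be attached with `fdr=True`; they
annotate, never re-gate.

**Fold-change.** Reported unsigned as max(ψ_A, ψ_B)/min(ψ_A, ψ_B); the
direction is recoverable from Δψ. When exactly one fraction is zero the
ratio is unbounded and the sentinel `LARGE` (serialized `Large`) is used;
when both are zero the fold-change is 1. Output ordering is descending
log-odds with event-id tie-breaks, so runs are reproducible byte for byte.

## Conserved pyrimidine-tract scanning

**Tract definition.** A tract is a maximal substring of length ≥ 9
composed of C/U residues plus at most one G (both parameters
configurable). T ≡ U throughout; A and N terminate tracts and N never
counts as the tolerated G. "Maximal" means extendable in neither direction
without breaking the composition rule; when a C/U/G run contains more Gs
than allowed, each maximal ≤-max_g window is reported separately, so two
hits may overlap. The tolerated G may sit anywhere, boundaries included —
the definition constrains composition, not position.

**Conservation.** For each reference-row tract the window extends 25
ungapped reference nucleotides on each side (flank interpretation; a
total-window reading would halve the reach, and the ungapped measure is
chosen because indels should not consume distance). A species supports the
site when the gap-stripped subsequence it aligns to that window itself
contains a qualifying tract — full qualification, not partial homology.
The site is called conserved at ≥ 9 supporting species of the 15 in the
alignment, the reference included (it trivially supports).

**Strand handling.** All coordinates are reported on the forward strand of
the reference genome. A block whose reference row is minus-strand is
reverse-complemented wholesale before scanning (start transformed as
src_size − start − size); a minus-strand species row has its extracted
window reverse-complemented before its tract search. This makes scanning
invariant under reverse-complementing an entire block with flipped strand
annotations, which the property suite checks.

**Limitations.** Blocks are scanned independently, so a site spanning a
block boundary is not detected. Species absent from a block simply cannot
support a site there; blocks missing the reference species are skipped
with a warning.

## Truncation estimation

The full-length fraction surviving past an insertion breakpoint is the
ratio-of-ratios (mutant_down/mutant_up)/(control_down/control_up) of mean
per-base coverages, clamped to [0, 1]. Normalizing by the control cancels
3'/5' coverage bias shared by the genotypes, and the upstream mutant mean
cancels library-size differences, so the estimator is invariant to
rescaling either profile. Upstream/downstream follow transcript strand.
`exclusion_nt` (default 0) omits a window on each side of the breakpoint
for insertion-proximal artifacts — reads spanning the junction are
unmappable over a width that depends on read length, so it is left to the
caller. Zero mutant-upstream or zero control-side coverage makes the ratio
undefined and raises rather than guessing.

## Gene-set overlap

The chance expectation for the intersection of sets of sizes n_A and n_B in
a universe of N genes is the hypergeometric mean n_A·n_B/N; the p-value is
the one-sided upper tail P(X ≥ observed), matching the enrichment
direction of interest. The universe must be supplied explicitly (genes
detectably expressed in the comparison, typically); there is no default
universe because a silently assumed one is the classic way to overstate
enrichment.

## Synthetic data

One `numpy.random.Generator` seeded from `SimConfig.seed` drives each
generator; identical configs give byte-identical files. Truth tables
always accompany outputs.

* **Junction counts:** per-condition totals are Poisson with mean `depth`
  (default 50 reads per event — a typical junction depth for a
  moderately-expressed gene in a ~50M-read library), split
  Binomial(total, ψ) independently per condition. This is the simplest
  model consistent with independent read sampling; a negative-binomial
  totals option (`overdispersion`) adds biological variance for
  robustness checks.
* **Coverage pairs:** control coverage is Poisson around `coverage_depth`
  (default 200×) along a 2 kb region; the mutant drops to
  `coverage_depth · full_length_fraction` (default 0.04) downstream of a
  mid-region breakpoint. This emulates transposon-mediated truncation as a
  step change in mean; it does not model fragment-level autocorrelation,
  mappability variation or 3' bias, so recovery tests show estimator
  correctness under the model, not robustness to those artifacts (the
  ratio-of-ratios form addresses shared bias by construction).
* **Alignments:** one multiz-style block over 15 species (reference
  `sp00`), purine-biased background (pyrimidine fraction 0.3, so chance
  tracts are rare but not impossible), 10% per-species uniform
  substitution, and sparse indels with geometric lengths of mean 2 —
  substitution realism (rate matrices, phylogenetic correlation) is
  intentionally out of scope since the scanner is composition-based.
  Planted sites use a 21-nt G-free C/U consensus by default, long enough
  that any single substitution leaves a qualifying 9-mer; per-species
  offsets up to ±10 nt are realized by shifting the planted copy, and
  indels avoid planted neighbourhoods so the truth table is exact while
  reference-gap columns (from insertions in other species) still exercise
  the window arithmetic. Non-conserved species have the site region
  ablated with purines.
* **Gene sets:** the target intersection is `overlap_enrichment` times the
  chance expectation, clipped to feasibility.

## Numerical and testing choices

Exact-test agreement with brute-force PMF summation is asserted to 1e-12
absolute over the exhaustive grid of events with per-condition totals up
to 30; calibration and power use 2,000 and 3×500 simulated events
(depths 50 and 100) — sizes at which binomial standard errors make the
bounds meaningful while the whole suite stays fast. Truncation recovery
averages 50 replicates at 200× depth; the scanner's randomized oracle
comparison uses 200 alignments of ≤ 5 species × ≤ 60 nt against a
quadratic enumeration, plus a 50 kb, 20-site planted screen checked
against a per-start extension enumeration. Monte-Carlo assertions use 3
standard-error bands with fixed seeds.

## Known limitations

* Junction counts are the input contract; junction discovery and read
  mapping are upstream concerns.
* Single library per condition; replicate modelling (e.g. dispersion
  estimation across replicates) is out of scope.
* The scanner is presence/absence on a composition rule: no PWM scoring,
  no affinity prediction, no partial-homology credit.
* MAF blocks are treated independently; no stitching across blocks.
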