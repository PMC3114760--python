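# Methods

## The question and the measurement

Aligned orthologous regions of closely related genomes show clusters of
nucleotide substitutions around indels.  Three mechanisms could produce
them: the indel itself is mutagenic while polymorphic; the indel and
the substitutions are products of one multi-mutation event; or the
*region* — typically a repeat tract that stalls replication forks and
recruits error-prone polymerases — elevates both indel and substitution
rates persistently.  The analyses in this package separate these
explanations using only the geometry of divergence around indels.

The primary measurement is the windowed divergence profile.  Indels are
called as maximal gap runs in gapped alignments; for each indel the
1,000 alignment columns on each side of its anchors are split into
windows (50 / 8×100 / 150 columns by default; all-50 and all-100
schemes are provided for robustness checks) and each window's
divergence is the Jukes–Cantor distance of the pooled mismatch/site
counts.  A *comparable site* is a column where both compared rows carry
an unambiguous base; N is never comparable and never a gap edge.  A
flank shorter than 1,000 columns, or containing any other indel, is
discarded entirely rather than truncated, so window denominators stay
comparable across indels.  Per-indel window D values are retained
separately because the distributional tests (KS) operate on them, but
profile D is pooled-counts-then-JC: per-indel 50-bp windows are
zero-inflated and averaging them would weight empty flanks incorrectly.
The background divergence Db is the arithmetic mean of pooled D over
the windows whose offsets lie beyond the reach of the indel/region
effect (windows 3–10 in the default scheme).

## Partition of divergence and the attribution ratio

With two ingroups and an outgroup, the indel haplotype is the ingroup
row whose state over the gap span differs from the outgroup (parsimony;
an outgroup sharing the gap means the other ingroup gained an
insertion).  Ambiguous outgroup states (N, mixed gap/base) drop the
indel from the partition but not from plain profiles.  Di and Dni are
pooled window divergences of the indel and non-indel haplotype against
the outgroup, over columns non-gap in all three rows; Db is taken from
the ingroup–ingroup comparison (the two-genome background), so R =
(Di−Db)/(Dni−Db) is exactly 1 when both haplotypes carry the same
excess.  R is reported as undefined (NaN, with a warning) when
Dni−Db ≤ 0.

Old/new dating uses quartets of two recently diverged pairs.  Spans
must match exactly across rows to count as the same indel (a
conservative homoplasy guard); a gap in exactly one row is *new*, a gap
in both rows of one pair and neither of the other is *old*, all other
patterns are discarded.  New-indel profiles compare the two genomes of
the pair containing the gap; old-indel profiles compare one genome per
pair, which automatically scores a "double mutation" column (the two
similar genomes differing from each other and from the other pair) as a
single substitution.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is demonstrated.

A region's ancestor is i.i.d. random sequence (GC fraction 0.5 by
default) with repeat tracts implanted at logged positions.  Evolution
along a rooted topology applies, per branch, Poisson per-site
substitution counts with rate `branch length × local multiplier`;
multiple hits are applied and logged individually (at the divergences
used, ≤ 0.025, they are rare).  Substitutions are transitions with
probability 2/3 far from repeats; inside the repeat neighbourhood the
transversion probability can be overridden (`tv_bias_near_repeat`),
emulating the transversion-prone signature of error-prone polymerases.
Indel lengths are geometric with mean 2 bp — a deliberately minimal
length model.  PRNG streams are split hierarchically (one child stream
per branch), so adding lineages never perturbs existing ones, and
identical (config, seed) reproduces output byte-for-byte.

The model's key knobs, with defaults:

* `region_multiplier` λ = 3 and `region_radius` = 50 bp.  Nothing in
  comparative data pins these down; they are chosen once so that a
  window-1 excess of the observed kind is clearly visible at divergence
  0.01, and are not tuned thereafter.
* `divergence_per_branch` spans 0.001–0.0125 per branch (0.002–0.025
  pairwise), the range over which incipient indel divergence is
  observable in closely related genomes.
* `transient_indel_pulse` — expected number of extra substitutions
  deposited once, within `pulse_radius` = 50 bp, on the indel lineage
  at indel birth.  This is the one-off multi-mutation alternative; with
  the pulse on, the attribution ratio starts high and decays toward 1
  as background divergence accumulates, reproducing the
  decline-with-divergence signature.

Two generation paths exist.  `evolve_lineages` is fully general
(arbitrary topologies, random indels, insertions evolving after
birth) and is the oracle-equivalence reference.  `simulate_region_set`
is a vectorised batch path producing many independent regions with one
indel at the region centre (inside an implanted tract when a
`repeat_spec` is given); insertions there duplicate the anchor sequence
(slippage-style), and inserted bases do not accumulate further
substitutions on descendant branches — at 1–3 bp per insertion and
divergence ≤ 0.025 the omission is far below sampling noise.

What the generator does **not** emulate: realistic indel length
spectra, selection, recombination, context-dependent substitution
models beyond the repeat-radius multiplier, alignment error (the
emitted alignment is the truth alignment), or repeat tracts arising and
dying over time.  Passing tests therefore demonstrate that the
*method* recovers the planted structure — not that real genomes contain
it.

Fluctuation assays are simulated under the Lea–Coulson model: Poisson
mutational events per culture, each founding a clone whose size follows
P(S ≥ k) = 1/k (sampled as ⌊1/U⌋, capped at Nt).  Mutant collections
draw independent single events over a gene with sites within 5 bp of a
chosen motif carrying `cluster_odds` times the baseline probability;
event kinds are substitution/indel at 3:1 by default, roughly the
proportion seen in spontaneous loss-of-function collections.

## Clustering test

Each gene site is *mutable* iff ≥ 1 observed substitution lies within
±5 bp of it.  For the indel/substitution association, the map is built
from substitutions only and the test counts indels on mutable sites:
k successes in n draws from N sites of which m are mutable, upper-tail
hypergeometric.

For the tetranucleotide scan, k is the number of occurrences of a motif
that are *contiguous* (overlapping or immediately adjacent) with a
mutable site.  Pairing that k with m = "number of mutable sites" makes
the null success probability exceed m/N (the mutable set is effectively
dilated by the motif span) and the test anti-conservative by
construction.  The scan therefore computes m by applying the same
contiguity predicate to every candidate start position, so the draw
space and the success set are consistent and the statistic is exactly
hypergeometric under uniform placement.  This is the package's own
correction of an under-specified recipe; the mutability radius and the
predicate are pluggable.  256 motifs are scanned (4⁴; an occasionally
quoted count of 264 has no combinatorial basis), raw p-values are
reported with a Bonferroni column, and the chance expectation 256·α is
printed alongside.

Calibration note: the 256 per-scan tests share one mutable map and
overlapping occurrences, so per-replicate false-positive counts are
correlated; the calibration test checks the mean count against
256·α on the scale of the per-replicate count SD, the exchangeable
unit, rather than an independent-binomial SEM that the discreteness of
hypergeometric tails makes unattainable.

## Fluctuation-assay estimation

The Lea–Coulson pmf follows the Ma–Sandri–Sarkar recursion
p₀ = e^(−m), p_k = (m/k) Σ p_i/(k−i+1).  The tail decays like m/k², so
partial sums converge only like 1 − O(m/max_k); likelihoods never need
the full tail because counts above a jackpot ceiling (default 150,
matching plate-count saturation) are right-censored via the tail mass.
m is maximised by golden-section search on log m over [10⁻⁶, 50]
(deterministic; the likelihood in log m is unimodal in practice), with
the boundary MLE m = 0 when all counts are zero.  µ = m/Nt; 95% CIs use
the Rosche–Foster approximation σ_ln m = 1.225·m^(−0.315)/√C — an
approximation whose coverage is checked by simulation (≥ 90% at
m = 2, C = 30) rather than assumed.  `m` here is the MSS likelihood
parameter (expected mutational events per culture); "mutant frequency"
is a looser synonym sometimes used for the same FALCOR quantity.  Nt is
taken as given; its own sampling error is not modelled.

## Test-selection gate

Pairwise distribution comparisons record Shapiro–Wilk normality
p-values, then run a two-sample KS test: if KS rejects at the gate
level (0.05) the KS result is reported, otherwise the Wilcoxon rank-sum
result (exact null distribution for n ≤ 25 without ties).  All tests
are two-tailed.  The gate uses KS both as the shape check and as the
reported test when it rejects — a circularity inherited from the
protocol being encoded, kept deliberately and flagged here.

## Numerical and bookkeeping choices

* Coordinates are 0-based half-open everywhere; alignment columns from 0.
* Orthology filters: length ≥ 3,000 ungapped columns of row 0 and
  identity ≥ 80% — both inclusive, both configurable; identity is
  computed over non-gap columns (the all-columns alternative would
  conflate indel content with identity).  Filters commute, and a
  uniqueness map of multiply-hit source intervals removes ambiguous
  regions.
* Indel "position" for all distance arithmetic is the pair of anchor
  columns (last non-gap column left, first non-gap right).
* Jukes–Cantor is undefined at p ≥ 3/4 (domain error) and returns a NaN
  sentinel for empty windows; pooled windows at the divergences studied
  never approach the boundary.
* Repeat runs are computed on a designated reference row's ungapped
  sequence; for density binning a run interrupted in the partner row
  (fewer than min_len contiguous identical bases remain) is not
  counted, and windows overlapping gap columns or with < 50 comparable
  sites are dropped.
* Degenerate inputs yield sentinels with warnings, not silent numbers:
  empty background windows, Dni ≤ Db, all-or-nothing mutability maps.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which the checked effects are
statistically unambiguous: 500 indels per profile replicate (50
replicates for directional claims), 300 indels per point of the
5-step divergence ladder (20 replicate ladders), 2,000 indels for the
R → 1 null, 240 quartet regions per old/new replicate, 1,000 replicates
for clustering calibration (30-kb gene, 900 events) and for fluctuation
recovery (30 cultures, m = 2).

## Known limitations

* The simulator's truth alignments bypass alignment error entirely;
  conclusions about aligner-induced artefacts are out of scope.
* The region effect is binary (inside/outside the radius) rather than
  decaying with distance, which sharpens the window-1 step relative to
  real profiles.
* Old/new dating discards insertion-type new indels whose gap pattern
  spans three rows; this is conservative, not biased, under the
  symmetric simulation model.
* The Rosche–Foster CI is an approximation; its simulated coverage at
  small C runs a few points below nominal.
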