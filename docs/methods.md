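# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. Everything quantitative stated here is
computed by the test suite or the analysis drivers; nothing is quoted
from external sources.

## Codon substitution model and branch tests

The selection machinery is a Goldman–Yang-style Markov model on the 61
sense codons of the universal code, ordered lexicographically over
T, C, A, G (the PAML convention, to ease cross-checking against CODEML
output). The instantaneous rate from codon i to j is

- 0 if i and j differ at more than one position,
- π_j for a synonymous transversion,
- κ·π_j for a synonymous transition,
- ω·π_j (× κ if a transition) for nonsynonymous changes,

with the diagonal set so rows sum to zero and the matrix rescaled so that
Σ π_i(−q_ii) = 1, i.e. branch lengths are expected substitutions per
codon. With frequencies of the π_j form the chain is time-reversible
(detailed balance π_i q_ij = π_j q_ji is asserted in the tests), so P(t)
is computed by symmetric eigendecomposition — one decomposition per
(κ, ω, π) serves all branch lengths, which is what makes the fitting loop
cheap.

Equilibrium frequencies default to F3×4 (positional nucleotide counts of
the analyzed alignment, renormalized over sense codons); uniform and
empirical-codon modes are available. π is held fixed during optimization,
as is standard.

**Likelihood.** Felsenstein pruning over site patterns
(duplicate columns collapsed). Codon columns containing a gap or N in any
taxon are excluded entirely (complete-column analysis) — consistent with
the pre-filters below, and it keeps the brute-force oracle exact. The
inside pass is unscaled float64, which is safe to roughly 25 taxa; trees
here have at most 16. Tests verify the pruned lnL against explicit
enumeration over internal-node states on 3- and 4-taxon trees, and
rerooting invariance (the pulley principle).

**Fitting.** Bounded L-BFGS-B over (log κ, log ω(s), log branch lengths).
Branch-length gradients are analytic via an inside–outside pass; κ and ω
derivatives use forward differences in log space (step 1e−6). The
objective is the per-site mean log-likelihood — normalizing this way
keeps gradient components O(1), without which L-BFGS-B's first line
search can jump to the parameter bounds and stall. Bounds:
κ ∈ [0.05, 100], ω ∈ [1e−4, 50], t ∈ [1e−7, 30]; convergence at relative
ftol 1e−10 with one retry, non-convergence flagged on the returned fit
rather than raised. Multi-start is deterministic (default three fixed
perturbations of the heuristic start); bulk simulation runs use a single
start plus warm-starting, which testing showed sufficient given
initialization at the generating tree. The two-ratio fit warm-starts from
the one-ratio optimum, which both speeds it up and guarantees the nested
lnL ordering the LRT needs. The LRT statistic is clamped at 0 and
referred to χ²(1), one-sided; at α = 0.05 the critical value is 3.84.

**Pairwise Ka/Ks** is the two-taxon special case (the two terminal
branches collapse to one identifiable path length). Sites are counted by
mutational opportunity: the nonsynonymous site fraction is the
nonsynonymous share of substitution flow at the fitted κ and π with ω
forced to 1; then Ka = t·p_N/(3 p_N1), Ks = t·p_S/(3 p_S1), and Ka/Ks
equals the fitted ω by construction. Identical sequences drive t to its
floor; Ka = Ks = 0 is reported with ω flagged undefined (Ks ≈ 0).

## Loss-of-constraint dating

The dating model assumes the focal branch of duration T (My) splits into
a constrained era at ω_c followed by a neutral era at ω = 1, with the
switch happening quickly. The branch-average ω then obeys the mixture
identity ω_obs·T = ω_c·(T − t_loss) + t_loss, inverted as
t_loss = T·(ω_obs − ω_c)/(1 − ω_c), clamped to [0, T]. ω_obs > 1 is
rejected (positive selection is outside the mixture; clamping it would
silently fabricate t_loss = T), ω_c = 1 is degenerate, and
ω_obs < ω_c warns and returns 0. T is a user input: the estimate is
linear in it, and the analysis driver reports a grid (30/40/50 My, the
last being the natural upper bound for the focal lineage). Both the
Table-style branch ω and a separately averaged lineage ω are accepted as
ω_c — the two disagree slightly in practice and the choice is the
caller's.

The simulator's `shift` option implements the matching generative model.
One subtlety matters: the two eras must share a **synonymous clock**.
Both era matrices are unit-rate (one substitution per codon per unit t),
so the neutral era is run faster by the ratio of synonymous flow
fractions p_S(ω_c)/p_S(1); this equalizes per-time synonymous rates, and
a single-ω refit of the whole branch then estimates the *time*-weighted
average ω_c(1 − f) + f — exactly what the closed form inverts. Without
the clock correction the refit estimates a substitution-weighted average
and the recovered time is biased low by roughly a third at ω_c = 0.1,
f = 0.4 (observed while validating the generator).

A focal branch of length 0.12 subs/codon on a 2,000-codon alignment
carries only ~100 nonsynonymous substitutions, putting the one-replicate
standard error on t_loss near 3 My of a 20-My truth. Recovery checks
therefore compare the replicate-mean (4–8 alignments) against the planted
value at ±15 %.

## Coverage baseline and copy number

Genome-wide windowed depth is stratified into GC bins of width 0.01 (the
finest binning that keeps hundreds of windows per occupied bin at the
simulated genome sizes). Each bin stores its mean depth; empty bins are
NaN and raise a named error on lookup unless the caller explicitly allows
nearest-occupied-bin fallback — silently substituting a global mean would
defeat the GC correction. A region's correction factor is its mean depth
over its GC bin's mean; factors are floored at 1 (an annotated gene is at
least one copy) and rounded half-up to integers for the family total,
with the unrounded sum reported alongside since the rounded total reads
as an upper bound.

Caveat the simulation makes visible: if the duplicated family occupies a
non-negligible fraction of the genome, its own inflated windows
contaminate the baseline bins and shrink the factors; the drivers use a
4-Mb genome with ~2 % of windows in family loci, where the effect is
under 2 %.

ORF classification order: frameshift (length mod 3), then premature stop
(any stop before the final codon; codons containing N are skipped rather
than guessed), then truncation below 0.8× the family reference length in
amino acids (a configurable threshold — 0.8 is a conventional
full-length cutoff for single-exon receptor genes). The intact fraction
is reported at full precision and as an integer percent.

## Entropy and the signed-rank test

Column entropy uses log base 2, so the 20-residue maximum is
log₂ 20 = 4.322 bits. Gaps are excluded from column frequencies by
default (optionally a 21st symbol); columns empty after gap handling are
skipped and counted. Species summaries report mean, SD (ddof = 1) and SE
over columns — dispersion quoted as "±" in the field is ambiguous
between the two, so both are emitted.

The Wilcoxon signed-rank test drops zero differences, mid-ranks ties, and
computes the exact null of W⁺ for n ≤ 25 by dynamic programming over
doubled (hence integral) rank sums — equivalent to full 2ⁿ sign
enumeration, which the tests verify directly for n ≤ 10. Above n = 25 a
normal approximation with tie correction and continuity correction takes
over. Two-sided p doubles the smaller tail, capped at 1. The pairing
scheme (per-column H values, per-species means, …) is deliberately the
caller's choice; the analysis driver pairs per-column entropies on the
shared consensus coordinate.

## k-mer genome size and N50

k-mers are counted canonically (lexicographic min of forward and reverse
complement); k-mers containing N are skipped. The error cutoff is the
multiplicity at which the count curve first turns upward — the trough
between the sequencing-error spike and the coverage peak; a spectrum that
never turns upward is rejected as unseparable. Peak depth c_k is the
count argmax above the cutoff, and size = Σ_{m>cutoff} m·count(m) / c_k.
With read length L the peak sits at c·(L−k+1)/L of the per-base coverage
c; the alternative reading that divides by per-base coverage instead is
reported as `size_bp_corrected`. The estimator models a single peak only
— no heterozygosity or repeat-peak decomposition — which is the main
limitation against real, polymorphic genomes. N50 is the smallest piece
length such that pieces at least that long contain half the total bases.

## Enrichment screen

Upper-tail hypergeometric P(X ≥ k) per category (FUNC-style), exact via
scipy's distribution and verified against subset enumeration for small
universes. FWER control is Bonferroni by default (Holm available; it
dominates Bonferroni and the tests assert it). The relaxed filter is
strict in p (< 0.05) and inclusive in the count and fraction criteria
(k ≥ 3, k/K ≥ 0.05). Gene significance feeding the screen is per-gene
uncorrected at α — the two-stage design puts multiplicity control at the
category level. Annotations are used as given: ancestral ontology terms
are honored only if pre-propagated; the package does not traverse the
ontology graph.

## Conserved-element screen

Catalog validation enforces the definition strictly: length must exceed
200 bp and sequences must be pure ACGT; rejection is reported data, not
an error. Orthologs are globally aligned to the reference with affine
gaps (match +1, mismatch −1, open −5, extend −1, via Biopython's
PairwiseAligner); variation = (mismatches + gap columns)/reference
length, gaps counting as differences (the conservative reading), and the
5 % threshold is strict with optional per-element overrides. Ortholog
retrieval is the caller's job — homology search is out of scope. With
per-site divergence d the observed variation is Binomial(L, ~d)/L, so
planted-divergence recovery needs L large enough that the planted rates
straddle the threshold by well over the binomial noise; the drivers and
tests use 1-kb elements (sd ≈ 0.9 points at d = 0.08).

## Synthetic-data generators

Every generator is a pure function of its parameters including the seed
(NumPy `default_rng`), and emits a truth record sufficient to score
recovery. What they emulate — and what they do not:

- Codon alignments evolve exactly under the model's per-branch transition
  matrices (column-i.i.d.), so likelihood-based recovery is testing the
  estimator, not alignment quality: no indels, no alignment error, no
  among-site rate variation.
- Coverage tracks draw per-window depth Poisson(mean·bias(GC)·copies)
  (negative-binomial overdispersion, mappability, and edge effects are
  not modeled). Default mean depth 35-fold, window 200 bp, GC ~
  N(0.42, 0.08) clipped — an avian-like compositional range.
- Receptor families mutate a shared consensus at per-species rates,
  giving monotone rate→entropy ordering; no indels or paralog structure.
- Reads are uniform error-free-or-substitution-only samples; no quality
  decay or indel errors.
- Category tables plant enrichment by an odds multiplier on the
  significance probability within one category.
- Conserved-element orthologs carry i.i.d. substitutions at mapped rates.

Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to real-data artifacts.

## Problem sizes and determinism

The LRT null calibration uses 200 replicates of 8 taxa × 300 codons
(ω = 0.3, κ = 2) on the demo bird tree — enough that the 95 % binomial
band around the 5 % nominal level spans roughly 2–8 %. Recovery
experiments use 300–2,000 codons as noted above; the genome-size check
uses a 100-kb genome at 30-fold. These sizes were chosen so each claim
is tested with adequate statistical power while the whole suite stays
comfortably runnable on a laptop core. Replicate seeds spawn
deterministically from a single run seed via `SeedSequence`.

## Pipeline

`run_selection_screen` applies the two alignment pre-filters in order —
the strict no-frameshift-indel pass, then the longest clean block of
≥ 200 aligned bases (gap- and N-free in every sequence, trimmed inward to
codon boundaries, leftmost on ties) — fits both models per gene, and
isolates per-gene failures (one bad gene is logged and skipped, never
fatal). `run_nocturnality_report` collates stage payloads and marks
missing sections as absent. The CLI (`kiwigenomics …`) is a thin wrapper
over these functions; the numbered drivers under `analysis/` are the
primary entry points and each writes its tables under `results/`.
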