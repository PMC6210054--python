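# Methods

This note documents the model, its assumptions, the tunable parameters, the
synthetic data the tests run on, and the numerical choices made where the
design was genuinely open.

## Model and assumptions

The pipeline treats a cancer cohort as a binary sample × gene matrix of
high-level somatic copy-number events and asks which gene sets show *less*
co-alteration than expected under fixed alteration rates. The underlying
assumptions are:

- **Only high-level events are drivers' footprints.** Calls of ±1 (shallow
  gains/losses) are ignored; +2/−2 are counted, and each gene is reduced to
  its dominant event type (ties resolved to amplification,
  deterministically).
- **A functional alteration shows a cis-expression effect.** Genes whose
  expression does not shift in the direction of their copy-number event are
  filtered out (one-tailed Mann–Whitney rank-sum; the altered group is
  compared against all other samples, including carriers of the non-dominant
  event type).
- **Mutual exclusivity within a hallmark signals functional redundancy.**
  Exclusivity is only interpreted against protein-coding genes of the same
  cancer hallmark; lncRNAs are unconstrained candidates in every hallmark
  network because their functional annotation is largely missing.
- **The permutation null must respect heterogeneity.** Both patient-wise and
  gene-wise alteration rates are preserved when building the null for the
  exclusivity score, so tumours with many alterations do not create spurious
  exclusivity.

## The exclusivity objective

For a gene set M, `F = Γ(M) / (ΣΓ(gᵢ) − Γ(M) + α)` with α = 1. The
denominator is the total pairwise "excess" of alterations over the union —
zero exactly when members never co-occur, in which case F equals the
coverage Γ(M). Greedy expansion from maximal-clique seeds accepts a
candidate only when F strictly increases, so the F trace is strictly
increasing and termination is guaranteed. Candidate eligibility follows four
rules: presence in the profile; hallmark membership (PCGs only); significant
exclusivity against the module's pooled alteration vector (hypergeometric
lower tail, p < 0.05; a per-member variant is available via
`exclusivity_target="per_member"`); and, against every member, fewer shared
than unique altered samples on both sides.

## Permutation null

Rewiring uses the checkerboard-swap Markov chain on the bipartite
sample–gene incidence structure: two 1-entries (r₁,c₁), (r₂,c₂) are proposed
uniformly at random and swapped to (r₁,c₂), (r₂,c₁) when those cells are
free. The proposal is symmetric and the state space of matrices with fixed
margins is connected under such swaps, so the stationary distribution is
uniform; each draw restarts from the observed matrix and attempts
`swap_factor × (number of 1s)` swaps (default factor 10; the uniformity
test in the suite uses factor 100, i.e. a long chain on a tiny matrix).
Because member genes' Γ values are preserved by construction, F exceeds its
observed value iff the permuted coverage Γ(M) does, so the test compares
integer coverages — exact and bit-reproducible given a seed.

**Empirical p and ties.** The default estimator is the fraction of
permutations with F strictly greater than observed — the printed rule, in
which ties favour significance. Consequently any module that is perfectly
exclusive as observed has p = 0 (no permutation can exceed perfect
exclusivity), which is why strongly exclusive sub-modules of a planted
module also survive selection. For calibration work two alternatives are
provided: `add_one` ((b+1)/(n+1) smoothing) and `randomized` (ties split
uniformly). With a discrete statistic no deterministic tie rule can give a
uniform null p; the `randomized` estimator is the standard variant that is
exactly uniform under the null, and the calibration test in the suite uses
it for that reason.

One shared set of `n_perm` rewired profiles serves all modules of a run
(fresh rewires per module are available by calling `permutation_test`
per module). Modules are deduplicated on (hallmark, member set) before
Bonferroni adjustment over the m tested modules; Benjamini–Hochberg is
available via `correction="bh"`.

## Semantic similarity and hallmark mapping

Wang's graph-based measure over is_a paths (edge contribution 0.8) with
best-match-average aggregation is used for term–set similarity; this is the
canonical configuration of the GO semantic-similarity tooling the field
uses, and the measure is a pluggable callable so information-content
variants can be swapped in. part_of edges are ignored. The expansion
threshold is derived from the data: the minimum leave-one-out similarity of
curated terms against their own hallmark set (inclusive ≥ at the cut, since
the threshold is itself an observed minimum). Gene membership uses
true-path propagation of annotations to all is_a ancestors.

## Functional assessment

Samples are split by module alteration status and transcriptome-wide PCGs
are tested with a two-sided rank-sum on log2(x+1), BH FDR < 0.05. This is a
deliberately self-contained, assumption-light backend behind a pluggable
interface (`de_backend`); it is less powerful than moderated-statistics
pipelines at very small group sizes but adequate at the cohort sizes this
stage sees. The GO-enrichment background is the set of PCGs present in the
expression matrix; a module is confirmed when ≥ 1 enriched term belongs to
its hallmark's term set.

## Parameters (defaults and units)

| parameter | default | meaning |
|---|---|---|
| `min_freq` | 0.025 | minimum fraction of samples with the dominant event (inclusive) |
| `rpkm_threshold` | 0.3 RPKM | detectability cut (strictly greater) |
| `detect_fraction` | 0.3 | fraction of samples that must pass the RPKM cut (inclusive) |
| `concordance_alpha` | 0.05 | one-tailed dosage-concordance p cut |
| `edge_alpha` | 0.05 | pairwise exclusivity p cut (plus the zero-overlap rescue rule) |
| `pool_alpha` | 0.05 | candidate-vs-module exclusivity cut in greedy expansion |
| `alpha_const` | 1 | α in the F denominator |
| `n_perm` | 1000 | permutation draws |
| `correction` / `module_alpha` | bonferroni / 0.05 | module selection |
| `max_dist` | 10 000 bp | same-strand proximity cut (inclusive, gap between closest ends, half-open arithmetic) |
| `swap_factor` | 10 | attempted swaps per 1-entry per rewire |

## Synthetic data: what it emulates and what it does not

The generator plants perfectly exclusive modules (disjoint sample blocks
summing to the requested coverage; an `overlap_rate` knob degrades them),
adds independent Bernoulli ±2 background per cell, gives expression a
log-normal baseline with a ±`dosage_effect` log2 shift per event, and adds
"responder" PCGs whose expression tracks a module's alteration status —
the transcriptional consequence that the assessment stage looks for. The
GO forest is a set of hallmark-rooted is_a subtrees under one root with
within-hallmark gene annotations and a configurable cross-hallmark leak.
Gene loci are non-overlapping spans with strands and cytobands, optionally
with planted antisense/proximal pairs on isolated chromosomes.

Deliberately **not** emulated: correlated segment-level CNAs (events are
per-gene independent apart from the planted blocks), GISTIC peak structure,
expression covariance beyond the dosage and responder effects, and
realistic GO topology/annotation depth. Passing tests therefore demonstrate
correctness of the inference machinery under its own model assumptions —
not robustness to segmental co-alteration, which real data exhibit and the
meta-gene merge (same cytoband + identical network neighbourhood, merged
transitively with a deterministic lexicographic representative) only
partially absorbs.

**Default study conditions** (used by the recovery experiments and the
acceptance script): 200 samples; three planted 3-gene modules (two PCGs +
one lncRNA) at 60% coverage in three different hallmarks; 2% background;
dosage effect 2; 40 PCGs / 20 lncRNAs total; 1000 permutations; Bonferroni
< 0.05. The calibration experiment uses 100-sample, 10-gene pure-noise
profiles at rate 0.1 with random 3-gene modules and 200 permutations ×
200 replicates. These sizes keep the full suite and the acceptance script
fast on a single CPU while leaving the planted signal at the stated
operating point.

## Numerical and degenerate-input choices

- Frequency/detectability fractions are inclusive (≥); the RPKM cut is
  strict (>). Dominant-type ties go to amplification. Sample ids are
  intersected between calls and expression.
- Rank tests use exact enumeration for small tie-free groups, normal
  approximation with continuity correction otherwise (scipy's automatic
  switch); constant expression rows get p = 1.
- The pairwise test is the lower-tail CDF P(X ≤ k), including the observed
  overlap; it equals a one-sided Fisher exact test ("less").
- A profile matrix with no valid swap is returned unchanged with a warning;
  empty networks and empty profiles are legal outputs, not errors; a module
  covering all samples skips assessment with a warning.
- Greedy ties between equal-F candidates resolve to the lexicographically
  smallest gene id; all orderings in outputs are deterministic, so a fixed
  seed reproduces every table byte-for-byte.
- All-zero tissue-expression rows have an undefined specificity and are
  reported as missing (NA).

## Known limitations

- The strict-greater empirical p saturates at 0 for perfectly exclusive
  observed modules, so selection is permissive for small perfect modules;
  module-level Bonferroni controls the family but cannot reintroduce
  resolution below 1/n_perm.
- Greedy expansion is not globally optimal; an adversarial profile can make
  the best single addition block a better pair (the suite contrasts greedy
  with exhaustive search on small universes).
- The confounder stage encodes only the automatic proximity + known-driver
  rule; literature-based rescue of individual candidates is inherently
  manual and out of scope.
- Transcript-level overlap is approximated at gene-span level unless
  transcript rows are supplied in the annotation.
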