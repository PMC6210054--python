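# hallmarkmex

Discovery of **cancer-hallmark-associated candidate driver lncRNAs** from
somatic copy-number and expression profiles, using mutual exclusivity with
known hallmark biology as the driver signal.

## The problem

Long non-coding RNAs are extensively hit by somatic copy-number alterations
(CNAs), but most of those events are passengers. Under the functional-
redundancy hypothesis, alterations of genes acting in the same pathway tend to
be **mutually exclusive** across tumours: one hit is enough. A lncRNA whose
high-level amplifications or deletions are mutually exclusive with the
alterations of protein-coding genes (PCGs) of a specific cancer hallmark —
and whose alteration shifts hallmark-related transcription — is a strong
driver candidate. `hallmarkmex` implements that inference as a tested Python
library with a CLI, for computational cancer genomicists working from
gene-level CNA calls (GISTIC-thresholded style) and expression matrices.

## The method

1. **Binary alteration profile.** Keep only high-level events (±2); per gene
   take the dominant event type. A gene is retained when it is altered in
   ≥ 2.5% of samples, detectably expressed (RPKM > 0.3 in ≥ 30% of samples),
   and its expression tracks its copy number (one-tailed rank-sum, p < 0.05).
2. **Hallmark gene sets.** Curated hallmark GO-term sets are expanded with
   candidate terms whose Wang/BMA semantic similarity to the curated set
   reaches the minimum leave-one-out similarity of the curated terms
   themselves; hallmark PCGs are the genes annotated (true-path propagated)
   to those terms.
3. **Mutual-exclusivity networks.** Per hallmark, every pair among the
   hallmark's PCGs and *all* lncRNAs in the profile gets an edge when the
   overlap of their altered samples is hypergeometrically small (lower tail,
   p < 0.05) or never observed.
4. **Module discovery.** Maximal cliques seed a greedy expansion maximising

   ```
   F = Γ(M) / ( Σᵢ Γ(gᵢ) − Γ(M) + α ),   α = 1
   ```

   where Γ(gᵢ) is the number of samples altered in member gᵢ and Γ(M) the
   number altered in at least one member. Significance comes from a
   margin-preserving permutation null — checkerboard rewiring of the binary
   matrix keeping every patient- and gene-wise alteration rate fixed
   (1000 rewires) — followed by Bonferroni correction (< 0.05).
5. **Functional assessment.** Samples are split by module alteration status;
   a module is confirmed when the differentially expressed PCGs are enriched
   for at least one GO term of the module's own hallmark.
6. **Confounder exclusion.** Candidate lncRNAs antisense-overlapping, or
   within 10 kb on the same strand of, a copy-number-affected known driver
   PCG are removed as likely passengers.

Downstream metrics include the module coverage Γ(M)/N, the fraction of module
samples explained by lncRNA members, and the tissue-specificity index
`Σᵢ (1 − expᵢ/exp_max) / (n − 1)`.

## Worked example

Real cohorts are large downloads, so the package ships a first-class
synthetic generator whose defaults plant three perfectly exclusive 3-gene
modules (two PCGs + one lncRNA each, 60% combined coverage) in three
hallmarks over 2% background noise, with a 2-log2-unit dosage effect on
expression:

```python
from hallmarkmex import HallmarkDriverModel, RunConfig

model, truth = HallmarkDriverModel.from_synthetic(1, config=RunConfig(n_perm=1000, rng_seed=1))
results = model.fit(seed=1)
print(results.summary())
```

```
========================================================================
Hallmark-associated mutually exclusive module discovery
========================================================================
Samples:                 200
Profile genes:           16 (12 PCG, 4 lncRNA)
Hallmark networks:       10
Exclusivity edges:       47
Modules tested:          33
Selected (bonferroni, p<0.05): 33
Hallmark-confirmed:      10
Candidate lncRNAs:       4
After confounder filter: 4
Mean coverage:           37.2% of samples
Mean lncRNA contribution: 42.3%
========================================================================
module_id                           hallmark                 members  ...
       M1 Sustaining Proliferative Signaling LNC0001;PCG0001;PCG0002  ...
```

The three planted modules appear among the confirmed modules with exact
membership (e.g. `M1 = LNC0001;PCG0001;PCG0002`, F = 61 with coverage 122 of
200 samples and empirical p = 0); additional smaller modules are perfectly
exclusive subsets that also survive the permutation null — a property of the
strict-greater empirical p, whose ties favour significance. `truth` carries
the planted ground truth for comparison.

The same flow is scriptable:

```bash
hallmark-mex simulate --seed 1 --out-dir sim/
hallmark-mex run --no-synthetic --seed 1 --out-dir out/ \
    --cna sim/cna_calls.tsv --expr sim/expression.tsv \
    --annot sim/annotation.tsv --hallmark-genes sim/hallmark_genes.gmt
```

Stage-level subcommands (`profile`, `hallmarks`, `network`, `modules`,
`filter`, `metrics`) expose each step separately; every output directory
contains a `manifest.json` with the configuration and seed, and repeated runs
with the same seed are byte-identical.

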