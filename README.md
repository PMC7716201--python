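# nichesig

Detecting genomic signatures of habitat adaptation in closely related
bacterial strains from profile-HMM bitscores.

When a bacterial lineage splits between habitats — say, host
gastrointestinal tracts versus the external environment — the earliest
genomic traces of that split are not wholesale gene losses but subtle
functional decay: point mutations and small indels that erode how well a
protein conforms to its family model. `nichesig` implements an analysis
pipeline for exactly this regime, designed for comparative studies of
*Escherichia* and similar genera where only a handful of genomes per habitat
are available:

1. **Delta-bitscore (DBS) functional divergence.** Each strain's proteins
   are scored against profile HMMs (Pfam, eggNOG) upstream with `hmmsearch`;
   this package consumes the tabular output. For two orthologs aligned to
   the same profile,

   `DBS = X_ref − X_var`  (bits)

   where `X_ref`, `X_var` are the full-sequence bitscores of the reference
   and variant proteins. Positive DBS = the variant is degraded. For
   multi-proteome comparisons each strain is compared against the per-gene
   median across strains.

2. **HAC calling.** From the empirical DBS distribution of a comparison, the
   tail whose 2.5% quantile lies closer to zero (the *least dispersed* tail)
   calibrates technical noise; its magnitude becomes the cutoff applied to
   the opposite side. Genes beyond it are **hypothetically attenuated coding
   sequences (HACs)**. Wilcoxon signed-rank tests compare degradation rates
   between proteome pairs; one-way ANOVA compares HAC counts between habitat
   groups.

3. **Random-forest habitat classification with iterative sparsity pruning.**
   Strains are classified from their bitscore profiles (ntree = 10,000 by
   default, mtry = n/10). After the first fit, predictors with variable
   importance (VI) ≤ 0 are pruned; later rounds keep the top 50% by VI until
   the out-of-bag (OOB) majority votes classify every training strain
   correctly. The terminal model's vote proportions classify unseen strains.

4. **Label-permutation significance.** The whole pipeline is rebuilt on
   label-shuffled datasets (1000 by default); p = frequency of shuffles
   matching the original terminal accuracy, with vote-margin comparisons for
   the accuracy-matching shuffles.

5. **Conservation direction and category tests.** Per predictor gene, Mood's
   median test (with Benjamini–Hochberg FDR at 0.25) asks which habitat
   keeps the gene more conserved; per functional category (COG/KEGG),
   PERMANOVA tests group separation in the category's bitscore space.

A synthetic-data module generates labeled bitscore datasets with planted
habitat-informative genes, lineage confounders, and explicit gene absences,
so every stage is testable without downloading genomes or HMM collections.

## Worked example

`examples/03_classify_strains.py` simulates 4 environment vs 5
gastrointestinal strains scored on 800 ortholog groups, 40 of which are
degraded by 3 within-gene standard deviations in the gut group, then runs
the selection loop:

```
predictors per iteration: [800, 55]
OOB accuracy per iteration: [0.556, 1.0]
status: converged; terminal model uses 55 genes
minimum majority vote among training strains: 70.5%
planted informative genes in terminal set: 22/55 (base rate 5.0%)
midpoint strain votes: environment 45.4%, gastrointestinal 54.6% -> called gastrointestinal
```

Reading this: the full 800-gene forest classifies poorly out of bag (most
genes are noise), but pruning the non-positive-VI predictors leaves 55
genes on which every training strain is classified correctly, with the
least confident strain still at a 70.5% majority. The terminal predictor
set is 7-fold enriched for the genes that actually carry the planted
habitat signal, and a strain synthesised exactly between the two group
archetypes lands near the 50/50 voting boundary — the model is confident
only where it should be.

The other scripts in `examples/` walk through dataset simulation, DBS/HAC
calling, permutation significance, and conservation-direction analysis, in
the same style. The `nichesig` command exposes the same stages for file-based
use (`nichesig simulate | ingest | dbs | classify | permtest | conserve |
run`); `nichesig run --config run.yaml` executes the full pipeline and
writes a reproducibility manifest.

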