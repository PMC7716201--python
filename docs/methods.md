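# Methods

This note records the models, conventions and numerical choices behind
`nichesig`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Delta-bitscore model

A protein's bitscore against its family profile HMM is a log-odds measure of
how well the sequence conforms to the family model. For two orthologs aligned
to the same profile, the delta-bitscore

    DBS = X_ref − X_var    (bits)

isolates *functional* divergence: neutral variation barely moves the
bitscore, while substitutions at conserved positions, truncations and
frameshifts depress it. Positive DBS means the variant is degraded relative
to the reference. For cohort comparisons, each strain is compared against
the per-gene median across strains (computed on genes present in every
strain; an even strain count uses the midpoint of the two central order
statistics). Median-benchmark DBS is invariant to adding a per-gene constant,
so only relative conformance matters.

Genes absent from one member of a comparison are excluded from pairwise DBS
by default; a policy flag (`absent_as_zero`) instead scores absence as 0
bits (deletion read as total loss). Absence is carried through the whole
pipeline as an explicit marker (NaN in memory, `NA` on disk), never a
numeric sentinel, so each stage's absence policy is a separate, visible
decision.

## HAC calling

HACs (hypothetically attenuated coding sequences) are called from the
empirical DBS distribution of one comparison. Both `tail_fraction` (default
0.025) quantiles are taken; the side whose quantile magnitude is smaller is
the *least dispersed* tail. Under the assumption that one proteome is not
systematically *better* than its comparator, that tail contains only
technical noise, so its magnitude is the cutoff applied to the opposite
side: genes strictly beyond it are HACs. Calling is one-sided by default
(the dispersed side carries the signal); `two_sided=True` flags both tails.
An exact tie in tail magnitudes treats the negative side as least dispersed
— deterministic and documented. A distribution that is identically zero
yields a zero cutoff and no HACs. The tail quantile requires
`n * tail_fraction >= 1` records (40 at the default).

Under a symmetric null the expected flagged fraction is slightly above
`tail_fraction` because the cutoff is the smaller of two noisy quantile
magnitudes; at n = 10,000 the excess is a few hundredths of a percentage
point (the acceptance script measures it directly).

Degradation-rate tests: the Wilcoxon signed-rank test of DBS symmetry about
zero uses the exact null when the non-zero count is ≤ 25 and tie-free,
otherwise the normal approximation with continuity correction. The HAC-count
comparison between habitat groups is a plain one-way ANOVA on raw counts
(with two groups, F = t² of the equal-variance t-test).

## Random-forest classifier and iterative feature selection

Strains are samples, ortholog bitscores are features, habitat
(gastrointestinal vs. environment) is the response. The engine is an
explicit bagging loop over scikit-learn decision trees because the selection
loop needs three things together: per-strain OOB vote proportions, OOB
permutation variable importance, and bit-reproducibility from one seed.

* **Forest**: `ntree` bootstrap trees (default 10,000; desk-scale runs use
  ~1,000), `mtry` candidate features per split (default `n/10` of the
  *current* predictor count, recomputed each iteration — the only reading
  consistent with a shrinking predictor set — minimum 1).
* **OOB votes**: each strain is voted on by the trees whose bootstrap missed
  it; vote proportions sum to 1. "Perfect OOB accuracy" means every training
  strain's OOB majority vote (> 0.5 for the gut class, ties to environment)
  matches its label.
* **Variable importance**: mean decrease in OOB accuracy — per tree, each
  feature used by that tree is permuted among the tree's OOB samples and the
  accuracy drop averaged over all trees. Features never used by any tree get
  exactly 0; misleading features go negative. Impurity importance is
  available as a config option.
* **Selection loop**: iteration 1 fits all genes; predictors with VI ≤ 0 are
  then pruned (a `VI == 0` variant is a config flag); each later iteration
  keeps the top 50% by VI, retaining boundary ties. The loop stops at the
  first iteration with perfect OOB accuracy, at `max_iterations` (default
  20), or if pruning empties or fails to shrink the set (reported as a
  distinct non-converged status; if the VI ≤ 0 rule would remove nothing,
  the halving rule is applied instead so the trace always shrinks strictly).
  If no iteration converges, the terminal model is the best-accuracy
  iteration, latest on ties (favouring the sparser model).
* **Missing values**: absent bitscores are imputed as the gene's observed
  minimum minus one standard deviation — absence read as maximal
  degradation, consistent with the DBS view of deletion. Median imputation
  is a flag (and is the default for the exported heatmap matrix, which is
  row-centered and unit-variance scaled).
* **Prediction**: unseen strains get full-forest vote proportions on the
  terminal predictor genes, absences imputed with the training-time fill
  values; a predictor gene missing from the new data entirely is imputed
  and flagged, not fatal. A strain is called gastrointestinal when its gut
  vote share exceeds `vote_threshold` (default 0.5).

### Behaviour at very small strain counts

With ~9 strains, a large fraction of pure-noise genes perfectly separates
any bootstrap sample, so gini gain cannot distinguish them from genuinely
informative genes within a single tree; signal emerges only in the OOB
aggregate. Two practical consequences, measured on synthetic data and
reflected in the tests:

* A *single* informative gene among hundreds of noise genes is not
  recoverable as a high-accuracy classifier at `mtry = n/10`; it is
  recoverable as the top-ranked VI gene when all features compete at each
  split (`mtry = n`) against a modest noise background.
* The selection loop converges to perfect OOB accuracy on *pure-noise*
  datasets most of the time (94% of 50 seeds at 4v5 strains, 500 genes,
  100 trees, 10 iterations): iterating feature selection against the OOB
  criterion overfits it. Perfect OOB accuracy is therefore **not** evidence
  of signal on its own — which is exactly why the permutation test and the
  vote-margin comparison exist.

## Permutation significance

Habitat labels are shuffled across strains (group sizes preserved), the
entire selection pipeline is rerun per shuffle, and
`p = n_matching / n_perm` where a shuffle matches when its terminal OOB
accuracy reaches the original's. This is the plain frequency estimator; the
`(count+1)/(n_perm+1)` form is reported alongside as `conservative_p`. Each
permutation draws its RNG stream from `(seed, index)`, so results are
independent of execution order.

Because permuted pipelines also overfit the OOB criterion at small strain
counts, p is often large even with real signal; the informative contrast is
the *margin*: accuracy-matching permuted models vote with systematically
smaller majorities than a model fit on genuine structure. The result object
therefore reports the original per-strain majority-vote proportions next to
a summary of the matching permutations' margins, and leaves interpretation
to the analyst.

The package's own null-honesty check runs at 7v7 strains: at 4v5, ties at
perfect accuracy concentrate so much probability mass that the mean of the
frequency-p under the null sits near 0.5 + P(tie)/2 ≈ 0.75 by construction;
at 14 strains the null accuracy distribution has support below 1.0 and the
mean p is central.

## Conservation direction and PERMANOVA

Per gene, Mood's median test forms the 2×2 table of counts strictly above
vs. not above the pooled grand median by group and tests it with chi-squared
(1 df, Yates continuity correction by default — the sample sizes here are
small; both the strictness of the split and the correction are flags). Genes
whose table has an empty margin (heavy ties) return p = 1; all-identical
values are an error. BH flags across genes use the step-up procedure at FDR
q = 0.25. Direction is simply the group with the higher median.

Category-level PERMANOVA uses Euclidean distances between strain profiles
on the category's complete-case genes (correlation distance is a flag). The
pseudo-F comes from the standard squared-distance partition
(`SS_total = Σ d²/n`; between = total − within; df 1 and n − 2 for two
groups). When the number of distinct label arrangements is ≤ `n_perm`, the
p-value is exhaustive (fraction of arrangements with F ≥ observed, identity
included); otherwise it samples and uses `(count+1)/(n_perm+1)` — the
standard convention for this named method, intentionally different from the
classifier permutation test's frequency definition. The output records
which route was taken.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
per-gene baseline means drawn uniformly from `baseline_mean_range`
(default 50–500 bits, the typical span of full-sequence bitscores of
bacterial proteins against family HMMs), Gaussian within-gene noise
(`baseline_sd`, default 5 bits), informative genes shifted down by
`effect_size × baseline_sd` in the degraded group (gastrointestinal by
default), confounder genes shifted along a random strain bipartition drawn
once per dataset (lineage signal, not habitat), and i.i.d. random absences
(`missing_rate`, default 2%). Defaults describe the package's benchmark
condition: 4 environment vs 5 gastrointestinal strains, 6709 ortholog
groups, 200 informative genes at a 3-SD effect.

What the generator does **not** emulate, and hence what passing tests do
not demonstrate about real data: phylogenetic covariance beyond a single
bipartition, gene-length- and family-dependent bitscore dispersion,
correlated absence (operons, genomic islands), non-Gaussian DBS tails from
frameshifts, and habitat-correlated missingness. Conclusions about real
genomes still require the permutation and margin diagnostics on the real
matrix.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by the package's own
choice: forests of 50–1,000 trees, 60–6,709 genes, 9–14 strains,
permutation tests of 5–30 shuffles in tests (1000 remains the library
default), 100 Monte-Carlo replicates for the null-HAC calibration, and 500
null datasets for the PERMANOVA type-I check. The benchmark selection run
(6,709 genes, 1,000 trees) converges in a few seconds on one CPU.

## Known limitations

* Bitscores are treated as exchangeable within a gene across strains; no
  correction for gene length or family information content.
* The classifier's OOB machinery assumes two classes; multi-habitat designs
  are out of scope.
* Ortholog-group definition is delegated to the upstream profile collection
  (one profile = one ortholog group); paralog resolution beyond best-hit
  selection is not attempted.
* With ≤ 9 strains the PERMANOVA permutation space is small (126 distinct
  arrangements at 4v5), bounding attainable p-values at 1/126.
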