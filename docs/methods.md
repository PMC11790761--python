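# Methods

This note documents the models implemented in `proteodpe`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a user auditing results should know
about.

## Synthetic cohorts

The generator (`proteodpe.simulate`) produces bulk-proteome cohorts whose
every downstream quantity has a known ground truth.

**Generative model.** Bulk signal is additive in molecule counts, so each
sample is a convex mixture of cell-type signature profiles on the linear
intensity scale, logged afterwards:

```
observed_gj = log2( Σ_c  p_cj · 2^(signature_gc) )
              + de_effect_g[diagnosis_j] + severity_slope_g · stage_j
              + batch_offset_g[pool_j] + age/sex terms + ε_gj ,   ε ~ N(0, σ²)
```

Additive log-scale terms shared across cell types factor out of the
mixture exactly, which gives the `mixture conservation` identity the test
suite asserts: with all nuisance terms off, `2^observed` equals the
proportion-weighted mean of `2^signature`.

**Defaults and rationale** (all in `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| cohort | 48 control / 48 disease_1 / 12 disease_2 / 12 disease_3 | the 73/73/18/17 imbalance typical of a parkinsonism brain-bank series, scaled to 120 samples |
| proteins × cell types | 4000 × 5 (neurons, astrocytes, oligodendrocytes, microglia, endothelial) | desk-scale version of a TMT brain proteome |
| markers per type / margin | 40 / 3 log2 | a marker is ~8× enriched in its own type; panels of tens of markers are standard |
| base proportions | 0.40/0.20/0.25/0.10/0.05 | coarse cortical composition, neurons dominant, endothelial rare |
| proportion shifts | disease_1: −0.10 neurons, +0.04 astrocytes, −0.015 endothelial; smaller shifts for diseases 2–3 | neuronal loss with gliosis, strongest in the largest group |
| disease effects | 120 proteins per disease, |log2 FC| ≈ 0.5, concentrated in 3 designated gene sets | matches the fold-change scale of printed top tables and makes enrichment recoverable |
| severity | ordinal 0–6 in disease_1 only, correlated with neuron loss; slope 0.1 log2/stage on 30 proteins | Braak-style staging available for the main disease group only |
| batches | 6 pools, per-protein offsets sd 0.05; the last pool inflated to sd 0.6 | mild pool effects plus one designated outlier pool to exercise batch QC |
| noise | σ = 0.3 log2 units | typical residual spread of TMT log-ratios |
| missingness | left-censored, per-sample lowest 5% masked | the dominant TMT missingness mode — intensity-dependent, which stresses the imputer the way real data would |

**What the generator does not emulate:** peptide-level quantification and
rollup, isobaric ratio compression, correlated protein co-regulation
beyond the cell-type mixture, non-Gaussian heavy-tailed noise, and
missingness that is informative about diagnosis. Passing tests therefore
demonstrate correctness of the algorithms under a faithful compositional
confounding model — not robustness to every artifact of real spectra.

## Preprocessing

*Reference scaling* follows the two-step TMT convention: channel totals
are equalized to the highest-total channel, then each protein row is
scaled so the reference channel reads 100 (ratios-to-reference × 100).
The op is a single pass; re-applying it changes columns only by scalar
factors (the normalized form is unique up to per-column scale), which is
the idempotence property the tests assert. Proteins with a zero/missing
reference value cannot be row-scaled and are returned as a flagged list.

*Filtering* removes low/medium-confidence identifications first, then
proteins missing in **strictly more than** 25% of samples — a protein at
exactly the boundary is retained.

*Imputation* is local least squares on the log2 scale: for each protein
with missing cells, the 10 fully-observed proteins most |Pearson|-
correlated over the protein's observed samples serve as regressors; an
OLS fit on observed samples predicts the missing ones. `k = 10` follows
the common default of the local-least-squares literature. Observed cells
are never altered; a rank-deficient neighbor system falls back to the
neighbor mean with a warning. Imputing before vs after log transformation
is exposed by simply feeding linear-scale data; the pipeline imputes on
log2.

*Batch QC* runs PCA on the centered matrix (samples as observations) and
rank-sum-tests each pool against the rest on the first 5 component scores;
pools with p < 10⁻³ on any component are flagged. Flagging never removes
samples. The orchestration layer, when `exclude_flagged_batches` is on
(default), drops only *extreme* separations (p < 10⁻⁸) — mild pool
effects remain in the data and are adjusted by the batch covariate, which
avoids discarding half a cohort over detectable-but-small offsets.

## MGP deconvolution

A cell type's marker gene profile is PC1 of the marker × sample submatrix
after per-marker z-scoring (centering on markers only — the method
summarizes the marker subspace, not the whole matrix). Estimates are raw
PC1 scores: relative, unitless, no simplex projection, because marker
profiles rank samples by cell content but carry no absolute scale. Sign
is aligned so the estimate correlates positively with the majority of
markers (ties break toward positive mean loading); markers loading
against the majority after alignment are reported for QC but retained.
An optional flag removes markers with low inter-marker correlation before
the decomposition (off by default — the upstream marker panels are
curated). Per-marker affine changes are removed exactly by the z-scoring;
per-sample global shifts are not, and are instead handled by the
reference normalization upstream.

Validation statistics: two-sided rank-sum tests per (cell type, disease
vs reference) — exact enumeration when both groups have ≤ 10 tie-free
observations, normal approximation with tie correction otherwise;
Kendall τ-b with tie-corrected p against the ordinal severity stage;
Pearson correlation matrices between cell types per group. Wilcoxon
p-values are reported unadjusted across cell types (a BH flag exists).

## Surrogate variables and covariate selection

SVs are right singular vectors of the residual matrix after fitting the
current design per protein. The number retained comes from permutation
parallel analysis: each singular value is compared with its null
distribution under 50 independent row-wise permutations of the residuals,
re-projected onto the design's orthogonal complement so the null matches
the observed geometry. Retention uses a **studentized** rule — keep a
component while its observed singular value exceeds the null mean by more
than 3 null standard deviations. A raw upper-quantile rule is
anti-conservative here: the permutation spread of the top singular value
is narrower than its sampling spread, so the observed value lands above
the 95th null percentile far more than 5% of the time under a true null.
The studentized rule brings the null false-retention rate to ~2% while
leaving planted-factor detection unchanged.

The covariate-selection loop correlates SV1 (only — matching the
diagnostic use of the *first* surrogate variable; a flag extends to SV2)
with every remaining candidate, adds the max-|r| candidate while that
maximum is ≥ 0.2, and stops when it falls below the threshold, no SV
survives parallel analysis, or candidates run out. Ties go to the
earlier-listed candidate and are logged. SVs are never entered into the
final model as covariates; measured covariates and cell estimates are.

## Moderated differential expression

Per protein: OLS on the shared design (categoricals indicator-expanded
with one reference level dropped; one indicator per disease vs control).
Empirical Bayes fits a scaled inverse-χ² prior to the residual variances
by method of moments on log s²_g: with
`e_g = log s²_g − ψ(d_g/2) + log(d_g/2)`,
`d₀` solves `ψ′(d₀/2) = Var(e) − ψ′(d_g/2)` (trigamma inverted by Newton
iteration) and `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`; when the
moment estimate of the prior variance is non-positive, `d₀ = ∞` and
`s₀² = exp(mean(e))`. Posterior variances
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` give moderated t with `d₀ + d_g`
df. Limits: `d₀ = 0` reproduces ordinary per-protein t exactly; `d₀ = ∞`
the pooled-variance t. The implementation is verified against the
Bioconductor reference implementation on a fixture to ~1e-8 and against a
naive per-protein OLS to 1e-10. Zero residual variances are floored at
1e-12 with a warning. Log fold-changes are in log2 units (base
configurable by transforming the input).

All three disease contrasts are fit in one shared design rather than three
case-control subsets — one residual variance per protein, as in the
single-stratification model. BH adjustment is applied within contrast;
the step-up is implemented directly (and cross-checked against
statsmodels). The severity model restricts to severity-defined samples,
screens the leading expression PCs for batch association (one-way rank
test), and substitutes the most-associated PC for the batch indicator
block to save degrees of freedom at small n, falling back to indicators
with a warning when no PC associates at p < 0.01. Severity enters as a
numeric linear term. The Bonferroni sub-analysis multiplies the raw p of
nominated-family proteins with nominal p < 0.05 by their count.

## Enrichment

Preranked GSEA ranks proteins by the moderated t (default; signed −log10 p
available), collapsing duplicate symbols to the max-|statistic| row and
breaking ties by accession for determinism. ES is the maximum deviation
of the running sum with hit increments |r|^w (w = 1, the classic weighted
score) normalized by the in-set total and miss decrements 1/(N − N_set).
p-values are two-sided on |ES| by gene-label permutation with add-one
correction (minimum attainable p = 1/(n+1)); the permutation count
doubles adaptively until at least 10 exceedances are observed or a cap of
2¹⁷ is reached — an approximation of multilevel p-refinement that
restores small-p resolution without the exact split algorithm. NES
divides ES by the mean |permutation ES| of the same sign. Set-size
filters default to [10, 500]. The leading edge is the in-set prefix
(suffix for negative ES) up to the running-sum extremum.

Over-representation uses the hypergeometric upper tail with the measured
(pre-filtered) protein universe as background — every hit must belong to
it.

Kappa de-redundancy represents each set as a binary membership vector
over the chosen universe (default: the measured proteins), repeatedly
merges the max-κ pair while κ > 0.4 (union membership, labels
concatenated), and terminates because each merge removes a set. The
representative of a cluster is its largest original member set, ties
lexicographic. κ depends on the universe; it is an explicit argument.

## Discriminative features

The differentially expressed protein list is split 70/30 into train/test
*feature* sets (floor rounding for train; a `split_axis`-style choice is
available by splitting samples instead — the protein split is the
documented default). An XGBoost classifier (binary logistic, `hist`,
single-thread for determinism) is tuned by exhaustive grid search over
learning rate, tree depth, split penalty γ, column subsample and row
subsample, selecting by mean stratified 5-fold CV F1 and refitting on all
samples. Importance is the mean absolute per-sample TreeSHAP attribution
from the booster itself (`pred_contribs`); attributions sum per sample to
the margin prediction, and features unused by every tree score exactly 0.
PCA of the non-zero-importance feature submatrix is tested against
diagnosis (rank-sum) and severity (Kendall τ-b); constant features are
dropped with a warning. The stage defaults to the disease_1-vs-control
contrast — the largest, best-powered comparison.

## Numerical and engineering choices

- All randomness flows from explicit integer seeds; identical
  configuration ⇒ byte-identical result tables (floats written with
  `%.17g`, re-read with round-trip parsing; stable mergesort-based row
  ordering everywhere).
- Rank-deficient designs are rejected with the collinear columns named;
  all-control cohorts yield no contrast columns and a warning.
- Exact rank-sum enumeration is used only for tie-free groups of ≤ 10;
  ties switch to the corrected normal approximation.
- Degenerate gene sets (empty intersection, whole-universe) are skipped
  with a log message rather than scored.
- The scenario sizes used by the verification suite (e.g. 2000 × 40 with
  1000 pooled replicates for calibration, 20 replicates for confounder
  correction, 1500-protein cohorts for determinism) were chosen as the
  smallest sizes at which the measured quantities are stable to the
  reported precision.

## Known limitations

- MGP estimates are relative; between-cohort comparisons of their scale
  are meaningless, and strong unremoved batch factors load onto marker
  PC1 (hence batch QC runs first).
- The moderated model assumes one shared residual variance per protein
  across groups; strong variance heterogeneity between diagnoses is not
  modelled.
- The adaptive-permutation GSEA p is an approximation below ~1/2¹⁷; for
  smaller p the add-one floor applies.
- Kappa merging is greedy; it guarantees the residual-κ bound but not a
  globally optimal clustering.
- The severity PC-substitution assumes batch structure is visible in the
  leading PCs of the severity subset; when it is not, the model reverts
  to indicator encoding, spending more degrees of freedom.
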