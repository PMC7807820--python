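# Methods

This note documents the statistical machinery implemented in `cecanova`,
the defaults it ships with, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Study design and the combined factor

The package is organized around an unbalanced four-factor design: two
farms (A, a semi-open-air facility; B, environmentally controlled), five
batches (1–4 in farm A, 5 in farm B), in-feed antibiotics (all of farm A
and 66 of 89 farm-B animals supplemented; 23 farm-B animals
antibiotic-free) and feeding regime (ad libitum, AL, vs restricted to
75%, R). The packaged `design_fixture()` reproduces the 425-animal
distribution over the 12 observed cells exactly.

Because batch is nested in farm and antibiotic varies only inside farm
B, no factorial model is identifiable. All analyses therefore fit a
**one-way cell-means model** on the single combined factor whose levels
are the observed cells, and express every scientific comparison as a
zero-sum contrast of *unweighted* cell means:

* farm: +1/8 on each farm-A cell, −1/4 on each farm-B cell (A − B);
* feeding within farm: R − AL cells inside one farm;
* antibiotic within farm B: without − with.

Unweighted averaging over cells (rather than sample-size weighting) keeps
the batch imbalance from leaking into the farm comparison; it mirrors
Type-III-style marginal means. The feeding effect is reported nested
within farm by default, because farm × feeding interaction is the
expected regime; `feeding="auto"` applies a per-response
difference-of-differences permutation test at 0.05 and falls back to the
farm-averaged feeding contrast when the interaction is not supported,
and `feeding="averaged"` forces the averaged form.

## Filtering and normalization

Filtering defaults follow the source pipeline exactly: samples with
total count < 5000 are dropped (strict); OTUs with grand total ≤ 2
(singletons and doubletons) are removed — the doubleton rule is
implemented as ≤ 2 rather than exactly 2 because open-reference OTU
picking rarely leaves informative singletons, and the threshold is a
parameter; inference-level OTUs must be detected in ≥ ⌈0.05 n⌉ samples
(inclusive) *and* exceed 0.01% of the grand total (strict).

CSS normalization computes, per sample *j*, the scaling factor
`s_j = Σ {c_ij : c_ij ≤ q_j(l)}` where `q_j(l)` is the *l*-th quantile of
the sample's nonzero counts, and reports `c_ij / s_j × 1000`. Quantiles
are linearly interpolated (numpy default, identical to R type-7, the
convention of the method's reference implementation), the quantile
distribution is taken over nonzero counts only, and the scale constant
is 1000. When no quantile is supplied, `l` is chosen adaptively as the
smallest grid probability (1%…99%) at which the median absolute
deviation of sample quantiles around the across-sample median reference
changes by ≥ 10% relative to its previous value, floored at 0.5; if the
instability criterion never fires the quantile falls back to 0.5 with a
logged warning. CSS is scale-equivariant per sample at a fixed quantile
and maps zeros to zeros.

Rarefaction draws a multivariate hypergeometric sample (subsampling
*without* replacement) of exactly 10,000 counts per sample by default;
samples below the depth are dropped with a log message rather than
raising, matching standard practice. The rarefied table is used only for
alpha diversity; composition analyses run on CSS values.

Taxonomy collapse sums **CSS-normalized** values within each taxon at a
rank (OTUs unassigned at that rank pool into `unclassified`) and
rescales each sample to percentages. Collapsing normalized values rather
than raw counts matches the provenance of the relative-abundance tables
the OTU-level analysis is compared against.

Average daily gain is the OLS slope of the weekly body weights on age in
days (g/day), fitted within animal.

## Permutation ANOVA

For each taxon the response is its CSS-normalized abundance (or
collapsed percentage). The F statistic of a 1-df contrast *w* is

    F = (Σ_g w_g m̄_g)² / (σ̂² Σ_g w_g²/n_g)

with σ̂² the pooled within-cell variance; for two cells it equals the
squared pooled t statistic. Because OTU abundances are grossly
non-Gaussian, the null distribution is generated empirically: the
response vector is globally permuted against the design 1000 times
(permutation without replacement — the resampling described for the
source analysis, despite its "bootstrap" label) and the p-value is the
proportion of permuted F values reaching the observed one, ties counting
as exceedances.

Two estimator variants are exposed. `permutation_pvalue` defaults to the
plain proportion `#{F* ≥ F_obs}/n_perm`, whose minimum is 0. The
pipeline-level `run_differential_abundance` defaults to the smoothed
variant `(1 + #{F* ≥ F_obs})/(1 + n_perm)`: a permutation p-value of
exactly 0 occurs with probability ≈ 1/(n_perm+1) per null taxon, and
feeding zeros into Benjamini–Hochberg destroys finite-permutation FDR
control (with hundreds of taxa the expected false-discovery proportion
approaches the probability that *any* null taxon ties the permutation
minimum, far above the nominal level). The smoothed estimator is a valid
p-value and restores BH's guarantee; the plain definition remains
available via `add_one=False`.

BH adjustment is applied per contrast across all tested taxa at one
taxonomic level, matching per-table reporting; significance means
adjusted p ≤ 0.05. Note the resolution consequence: with *m* taxa and
n_perm permutations, the smallest achievable adjusted p for an isolated
signal is ≈ m/(n_perm+1) · 1/rank, so a lone true effect among many taxa
may be undetectable at 1000 permutations while a group of strong effects
(sharing low ranks) is not.

Permutation streams derive from a master seed and a CRC-32 hash of the
taxon name, so per-taxon results are independent of processing order and
of which other taxa are present; a taxon's contrasts share one set of
permutations.

Alpha-diversity contrasts reuse the same cell-means machinery but with
the classical F reference distribution (1, residual-df): the indices are
approximately Gaussian sample aggregates, and the empirical-null
apparatus is reserved for the taxon-level responses. The BH family for
diversity is the set of reported contrasts per index.

## Sparse PLS-DA

Classes are dummy-coded into an indicator matrix Y; X and Y columns are
centered and scaled to unit variance (scaling of X can be disabled). Per
component the leading singular pair of X′Y (current deflated matrices)
is found by alternating iteration; after each update the X-weight vector
is soft-thresholded at the (keepX+1)-th largest magnitude — exactly
keepX entries survive, magnitude ties broken by feature order — and
renormalized. Scores are t = X a; X is deflated by regression on t and Y
in regression mode (Y ← Y − t(t′Y)/(t′t)). Successive scores are exactly
orthogonal. Explained variance per component is ‖t‖²‖p‖²/‖X₀‖²_F with p
the X regression loading, which sums to ≤ 1 over components.

Prediction centers/scales new samples with the training parameters,
reproduces the sequential deflation with the training weights and
loadings, and assigns the nearest class centroid in score space
(Euclidean; exact ties go to the lexicographically smallest label).
Mahalanobis and maximum-distance rules are deliberately not implemented:
centroid distance is the stated criterion of the analysis this package
reproduces.

Tuning is forward and one component at a time: with earlier components
fixed, each grid value of keepX is scored by the mean overall BER of
repeated stratified 5-fold cross-validation (10 repeats); the smallest
keepX wins ties, and components (up to 4) are added only while the best
mean BER strictly improves. Evaluation re-runs stratified 5-fold CV
(1000 repeats at the CLI default) on the chosen configuration; each
repeat classifies every sample exactly once, per-class error rates give
the BER (unweighted mean over classes), and the mean/SD over repeats is
reported together with each feature's selection frequency over all
folds × repeats (features above 0.9 are flagged as stable). Stratified
folds place 20% of every class in each validation set, degrading
gracefully (with a warning) for classes smaller than the fold count.

## Synthetic data generator

The generator is the package's test bed and defines the conditions under
which the validation suite runs:

* **Design** — the exact 425-animal fixture by default; any validated
  design table can be substituted (e.g. the 60 + 60 two-farm design used
  for classification experiments).
* **Library sizes** — log-normal with log-mean ln 28,000 and log-sd 0.7,
  truncated below at 10,157 by rejection; this reproduces the reported
  scale (mean ≈ 35k, minimum 10,157) without modelling the extreme upper
  tail.
* **Composition** — base relative abundances are log-normal over OTUs
  (log-sd 1.8), giving the heavy-tailed rank-abundance profile typical of
  16S data: a few dominant OTUs, a long rare tail, and a small fraction
  falling below the 0.01% abundance filter.
* **Counts** — Dirichlet-multinomial per sample with concentration 200:
  the Dirichlet respects compositionality (unlike independent negative
  binomials) and the concentration sets biological overdispersion —
  at 200, moderately abundant OTUs appear in essentially all samples
  while rare ones drop out, qualitatively matching the reported
  prevalence profile. The marginal mean is library size × expected
  relative abundance; as the concentration → ∞ the draw collapses to a
  plain multinomial (both properties are tested).
* **Effects** — multiplicative on expected relative abundance before
  renormalization (an OTU with log2 fold change λ is multiplied by 2^λ
  in the affected cells), matching the relative-abundance scale on which
  contrasts are estimated. Affected groups: farm effects multiply farm
  A, feeding effects multiply R within the named farm, antibiotic
  effects multiply antibiotic-free farm-B samples. The applied effect
  list is returned as ground truth and `expected_composition` gives the
  exact per-cell expected relative abundances.
* **Body weights** — linear growth from a 700 g weaning weight at the
  recording ages 32, 39, 46, 53, 60 days plus Gaussian noise, with
  per-cell average daily gain.

What the generator does **not** emulate: taxonomy-assignment error,
chimeras or any sequence-level artifact; litter/cage structure and other
random effects (none are fitted by the analysis either); correlations
between OTUs beyond the compositional constraint; zero-inflation beyond
what the Dirichlet-multinomial induces; and the extreme library-size
outliers of real runs. Passing validation on these simulations therefore
certifies the inferential machinery — calibration, power, recovery — not
robustness to the full messiness of real 16S data.

## Validation scales and numerical choices

The validation suite uses sizes chosen to exercise the full design while
staying desk-runnable: the null-calibration study runs 200 replicates of
200 OTUs × 425 samples at 200 permutations; the power study plants 50
signed effects with |log2FC| ∈ [1.5, 2.5] on the abundant half of 400
OTUs (so planted taxa survive the prevalence/abundance filter and
"sensitivity" measures the test, not the filter) at the default 1000
permutations; classifier evaluation uses 50 CV repeats where the CLI
default is 1000. Classification scenarios plant 8–16-fold shifts —
"strong" separation in the sense of the farm effect they imitate, which
touched most of the real community.

Degenerate inputs are handled explicitly: a constant response gives
F = 0 and permutation p = 1; zero residual variance with a nonzero
estimate gives F = ∞ (classical p 0); zero-variance features are dropped
from sPLS-DA with a warning; all-zero samples are rejected before CSS;
empty filter results raise rather than returning empty tables. The
NIPALS iteration stops at a 1e-9 update norm or 500 iterations;
orthogonality of scores holds to 1e-8 relative tolerance.

## Known limitations

* SEs of contrast estimates are OLS (homoscedastic pooled variance);
  abundance heteroscedasticity across cells is absorbed by the
  permutation null for testing but not reflected in the reported SE.
* Global (unrestricted) permutation is used even for within-farm
  contrasts; under strong farm main effects this tests the sharp null of
  full exchangeability rather than the within-farm null. A stratified
  permutation mode was considered and deferred — the analysis this
  package models permutes globally.
* The empirical p-value grid (resolution 1/n_perm) bounds attainable
  FDR-adjusted significance; see the resolution note above.
* sPLS-DA tuning minimizes plain mean BER; no parsimony test is applied
  to prefer smaller keepX beyond exact ties.
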