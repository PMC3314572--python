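# Methods

This note records the statistical model the package implements, the defaults
and numerical conventions it commits to, what the synthetic generator does and
does not emulate, and the known limitations of the module-search objective.

## Model and assumptions

Samples from class *k* ∈ {A, B} are modelled as draws from N(μ_k, Σ) with a
shared covariance that is block-diagonal over gene modules. Under that
assumption the Bayes-optimal linear discriminant decomposes into a sum of
per-module discriminants, which is what MLDA computes: each module
contributes `(x_c − ½(μ̂_Ac + μ̂_Bc))ᵀ Σ̂_c⁻¹ (μ̂_Ac − μ̂_Bc)` and a sample is
assigned to A when the sum reaches `log(n_B/n_A)` — the plug-in threshold for
class priors estimated by the training frequencies. The boundary itself is
assigned to A; this is an arbitrary but fixed convention, also used by MPCLR
(`p ≥ 0.5 → A`) and DQDA (score ties → A).

The block structure is *discovered*, not given: seeds are the top-*m* genes
by |T|, and each seed's module is the correlation neighbourhood (over the
cutoff grid 0.50–0.95, step 0.05) maximising the average |T| of its members.
The grid is configurable; the default is the ten cutoffs above, and on score
ties the largest cutoff (smallest module) wins, for parsimony and
determinism.

### Disjointification

A block-diagonal covariance needs non-overlapping blocks, but independent
seed searches can produce overlapping neighbourhoods. The package resolves
this greedily by seed rank: higher-ranked seeds claim genes first, and later
searches run on the unclaimed remainder; a seed absorbed by an earlier module
yields no module. This keeps the strongest signals' modules intact and is
deterministic. An overlap-permitting variant (relevant for MPCLR, where
blocks need not be disjoint) was considered and not implemented; only the
disjoint rule exists.

### Covariance estimation and shrinkage

Within a module the pooled covariance uses the unbiased per-class estimates
weighted by their degrees of freedom (denominator `n_A + n_B − 2`). The
shrinkage step replaces all off-diagonal entries with `σ̂_i σ̂_i′ r̂_c`, where
`r̂_c` is the median of the module's pairwise pooled correlations (mean of
the two central values for an even pair count) and the `σ̂_i²` are the pooled
diagonal itself. Pairwise correlations are computed from within-class-centred
data — consistent with the pooled covariance; a per-class-averaged variant
would be a reasonable alternative but is not the default. Shrinkage is on by
default; disabling it (`shrinkage=False`) recovers the raw pooled block
covariance and realises the exact one-block = classical-LDA reduction.

Blocks are inverted through SVD. Singular values below `rel_tol = 1e-8`
times the largest are zeroed along with their reciprocals, giving the
Moore–Penrose pseudo-inverse whenever a module holds more genes than the
training samples can support; well-conditioned blocks reproduce the exact
inverse to numerical precision. A block of numerical rank 0 is an error.

### Differential-expression statistics

The pooled two-sample t requires at least two samples per class; genes with
exactly zero pooled variance get a NaN statistic, are excluded from ranking,
and trigger a warning — they are never assigned infinite scores. The
SAM-style statistic adds a fudge constant `s0` to every gene's standard
error; because the literature admits several recipes for `s0`, it is
configurable (median of the gene-wise standard errors by default, or a
percentile, or a fixed value), and `s0 = 0` reduces exactly to the t
statistic. Rank ties break by ascending gene index so results are identical
across platforms.

### Co-expression network

The default correlation mode centres each gene within its class before
correlating ("pooled"), so a pure class-mean shift does not register as
co-expression — the same spirit as the pooled covariance. A plain
("overall") Pearson mode is available for comparison. Zero-variance genes
are excluded from the network with a warning.

### MPCLR

Module genes are z-scored with training means and standard deviations
(ddof = 1); the first right-singular vector of the normalised n × p_c matrix
gives the loadings, with the sign fixed so the largest-|loading| coordinate
is positive (SVD signs are otherwise arbitrary and the logistic fit absorbs
either choice; the convention buys bit-reproducibility). The logistic model
is fit by IRLS (statsmodels GLM, binomial family) with a capped iteration
count; complete separation is detected and flagged in the model diagnostics,
and the unpenalised coefficients at the stopping point are returned — no
penalisation is added. Class A maps to Y = 1; which observed label plays "A"
is configurable at load time (lexicographically first by default).

## Cross-validation

Folds are stratified by class (within-class sizes differ by at most one,
with a running offset so total fold sizes stay balanced); an unstratified
mode exists. Everything label-dependent — statistics, seed ranking, module
discovery, model fitting — is recomputed from each training complement, so
no information from held-out samples reaches the classifier; the test suite
asserts this by refitting after deleting held-out samples from the dataset.
The error rate is computed per repeat (misclassified / n) and averaged over
repeats. A failure inside any fold aborts the run with the repeat/fold
context rather than skipping the fold, which would bias the average. All
fold randomness derives from one integer seed; a fixed seed makes the entire
result, including the per-sample prediction log, bit-reproducible.

## Synthetic data

The generator draws class-conditional multivariate normals whose covariance
is block-diagonal with compound-symmetry blocks: each block's genes share a
latent factor, giving exact within-block correlation ρ and zero between-block
correlation. Differential signal is a mean shift of δ·σ on each block's first
gene in class A (or on all block genes with `shift_all`). Defaults — 50 + 50
samples, 100 genes, five blocks of sizes 5–20 at ρ = 0.8, δ = 2 — reflect a
small two-class cohort with strongly co-expressed modules and a clearly
detectable single-gene marker; a two-standard-deviation shift at n = 100
yields |t| ≈ 10, typical of top genes in benchmark tumour/normal sets.
Requiring ρ < 1 keeps every design positive definite, which is validated
before sampling.

What the generator does **not** emulate: probe-level artefacts, batch
effects, heavy-tailed or heteroscedastic noise, correlation between blocks,
and preprocessing (e.g. RMA) of raw arrays — the package treats its input as
an already-normalised real-valued matrix and leaves any transformation to
the caller. Passing tests on this generator therefore demonstrates
correctness of the algorithms under the model's own assumptions, not
performance on real microarray data.

## Known limitations

- **The module-search objective favours singletons around top seeds.** The
  average |T| over any neighbourhood containing the seed is bounded by the
  largest member |T|; for the top-ranked seed that bound is its own score, so
  whenever no neighbour correlates above the largest grid cutoff the search
  returns the singleton {seed}. Multi-gene modules arise only when a seed's
  neighbourhood contains a gene with a larger |T| (which then raises the
  average) or when correlations exceed the top cutoff so the singleton is
  unreachable. Consequently, on compound-symmetry blocks at ρ ≈ 0.8 the
  discovered modules are mostly singletons and planted blocks are *not*
  recovered as wholes — block recovery via this objective requires either
  extremely tight co-expression (ρ near or above the 0.95 cutoff) or
  heterogeneous member statistics. This is a property of the objective
  itself, not of the implementation; the brute-force oracle tests confirm
  the implementation optimises the objective exactly.
- Only two classes are supported; the decision rule is inherently binary.
- The shrinkage target (single median correlation per block) is coarse for
  large heterogeneous modules.
- MPCLR uses one principal component per module; modules whose
  discriminative signal sits in later components are summarised poorly.
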