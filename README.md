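# modlda

Modular discriminant classification of two-class gene-expression samples.

Expression studies routinely need a diagnostic rule — tumour vs normal, say —
built from a matrix with thousands of genes and only tens of samples. In that
regime a full linear discriminant is unusable (the pooled covariance cannot be
inverted) while diagonal discriminants throw away all gene–gene correlation.
`modlda` takes the middle road: it finds small modules of co-expressed genes
around differentially expressed *seed* genes and assumes the covariance is
block-diagonal over those modules, so correlation is modelled exactly where
the data support it and ignored elsewhere.

## The method

Given log-scale expression `x_ij` (gene *i*, sample *j*) with classes A and B:

1. **Seed selection.** Rank genes by the absolute two-sample statistic
   `T_i` (pooled t, or a SAM-style moderated t with fudge constant `s0`) and
   take the top *m* as seeds.
2. **Correlation-sharing module search.** On the Pearson co-expression
   network, for each seed *i\** scan cutoffs `r ∈ {0.50, 0.55, …, 0.95}` and
   form `C_r(i*) = {s : |corr(x_i*, x_s)| ≥ r}`; keep the neighbourhood whose
   average `|T_s|` is maximal (ties → largest `r`). Higher-ranked seeds claim
   genes first, so modules are disjoint.
3. **Modular LDA (MLDA).** Per module *c*, estimate the pooled within-class
   covariance `Σ̂_c = ((n_A−1)S_Ac + (n_B−1)S_Bc)/(n_A+n_B−2)`, then shrink:
   keep the diagonal `σ̂_i²` and set every off-diagonal entry to
   `σ̂_i σ̂_i′ r̂_c` with `r̂_c` the median pairwise pooled correlation in the
   module. Invert by SVD (Moore–Penrose when singular) and sum the per-module
   linear predictors

   `LP(x) = Σ_c (x_c − ½(μ̂_Ac + μ̂_Bc))ᵀ Σ̂_c⁻¹ (μ̂_Ac − μ̂_Bc)`,

   assigning class A iff `LP ≥ log(n_B/n_A)`. With one module holding all
   genes (and shrinkage off) this is classical LDA; with every gene its own
   module it is DLDA.
4. **MPCLR.** Alternatively, summarise each module by the first principal
   component of its z-scored genes (a "super-gene") and fit a logistic
   regression of the class indicator on the module scores.

Baselines (DLDA, DQDA, 1-nearest-neighbour), a leakage-free repeated
stratified 10-fold cross-validation harness (statistics, seeds, modules and
models all refit inside every training fold), and a block-structured
multivariate-normal simulator with known ground truth round out the package.

## Worked example

Simulate a cohort of 50 + 50 samples with three tightly co-expressed
differential blocks, inspect the discovered modules, and cross-validate:

```sh
cat > design.json <<'JSON'
{"n_a": 50, "n_b": 50, "p": 100,
 "blocks": [{"size": 6,  "rho": 0.95, "delta": 2.0},
            {"size": 10, "rho": 0.95, "delta": 2.0},
            {"size": 8,  "rho": 0.95, "delta": 2.0}],
 "shift_all": true}
JSON
mlda simulate --design design.json --seed 11 \
     --out-expr X.tsv --out-labels y.tsv --out-truth truth.json
mlda modules --expr X.tsv --labels y.tsv --seeds 5 --out modules.tsv
mlda cv --expr X.tsv --labels y.tsv --method mlda,mpclr,dlda,dqda,1nn \
     --seeds 5 --repeats 3 --seed 17 --out cv.tsv
```

`modules.tsv` lists each module's seed, chosen cutoff, mean |T| score and
members — here the five seeds collapse into three modules of correlated genes:

```
module_index  seed_gene_id  chosen_r  score      n_genes  member_gene_ids
0             G0007         0.95      11.630757  2        G0007,G0011
1             G0012         0.95      11.839689  2        G0012,G0015
2             G0010         0.95      11.573000  3        G0009,G0010,G0014
```

`cv.tsv` is a seed-count × method table of mean cross-validated error rates
(fraction of misclassified samples, averaged over repeats):

```
n_genes  mlda      mpclr     dlda      dqda      1nn
5        0.123333  0.133333  0.130000  0.130000  0.136667
```

so with 5 seed genes the modular discriminant misclassifies ~12% of samples,
slightly ahead of the diagonal baselines on this draw. `mlda fit` /
`mlda predict` save a model as versioned JSON and apply it to new samples
(reporting LP for MLDA, class probability for MPCLR).

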