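# gsprog

Prognosis-relevant gene-set screening for censored survival cohorts.

A single prognostic gene is easy to find and hard to interpret; a *gene set*
(pathway, signature, functional module) that predicts patient survival carries
mechanistic meaning. `gsprog` implements a two-round screening strategy for
bulk transcriptome cohorts with right-censored survival (e.g. disease-specific
survival):

1. **Gene-level round** — every gene is screened with a univariate Cox
   proportional-hazards model; the signed score-test statistic
   `z = U(0)/sqrt(I(0))` is both the test and, later, the gene's weight.
2. **Enrichment screen** — genes ranked by `-log10 p` feed a one-tailed
   preranked running-sum enrichment test per gene set (only the
   survival-significant end of the ranking is scanned), selecting candidates.
3. **Gene-set round** — each candidate set gets a per-patient **Composite
   Gene Expression Score**

   ```
   CGES = 1 / (1 + exp(-(Σᵢ βᵢ xᵢ - m)))
   ```

   where `xᵢ` is the standardized log expression of gene *i*, `βᵢ` its Cox
   score z, and `m` the median of the weighted sum over the training
   patients. Scores are computed by leave-one-out cross-validation (the
   weights are supervised, so raw scores would overfit), patients are split
   at the median CGES, and the two groups are compared with a log-rank test.
   Significance comes from permuting (time, event) pairs and refitting the
   weights each time: `p_perm = #(χ²_perm ≥ χ²_obs) / n_perm`. Zero p-values
   are real and expected; tied zeros are ranked by the z-score of the
   observed statistic against the permutation null.
4. **Optional corroboration** — gene-set rewiring between paired tumor and
   normal expression (dominant-eigenvector weight distance on absolute
   correlation matrices, permutation-tested per dataset, pooled across
   datasets with a random-effects logit model and dataset bootstrap), plus
   differential-coexpression link classification and two kinds of set–set
   crosstalk networks (hypergeometric cross-link enrichment; significance-
   profile similarity).

Everything runs on plain TSV/GMT files or in-memory objects, and a synthetic
cohort/panel generator with known ground truth exercises every stage.

## Worked example

Simulate a 150-patient cohort in which a planted 5-gene module (genes loading
on a shared latent factor) drives hazard at 0.7 log-hazard per factor SD with
30% censoring, then test the planted set against a background set:

```python
from gsprog import CGESModel, CohortSpec, GeneSet, PlantedSet, simulate_cohort

spec = CohortSpec(n_patients=150, n_genes=40, seed=7,
                  planted_sets=(PlantedSet(5, 0.7),), censor_rate=0.3)
expr, surv, sets, truth = simulate_cohort(spec)

background = GeneSet("BACKGROUND_SET", tuple(expr.gene_ids[20:25]))
model = CGESModel(expr, surv, list(sets) + [background])
results = model.fit(n_perm=1000, seed=11)
print(results.summary())
```

```
Composite Gene Expression Score survival test
========================================================
gene sets tested:      2
skipped:               0
permutations per set:  1000
significant at 0.05:    1
--------------------------------------------------------
set                           chi2   p_perm      z     HR
PLANTED_1                    17.67   0.0000   8.52   2.30
```

Reading the row: the planted set's median-split log-rank statistic is 17.67,
larger than all 1000 permutation statistics (`p_perm = 0`, so ranking falls
back to the permutation z-score, 8.52), and patients in the high-CGES half die
at 2.3 times the hazard of the low half. The background set comes out flat
(`χ² = 1.46`, `p_perm = 0.74`, HR ≈ 0.79 — noise around 1):

```
      set_name  n_genes_used  chi2_obs  p_perm   z_score  hazard_ratio
     PLANTED_1             5 17.668049   0.000  8.524180      2.299288
BACKGROUND_SET             5  1.459799   0.742 -0.726337      0.787794
```

The same pipeline is scriptable from the shell — `gsprog simulate`,
`gsprog gene-surv`, `gsprog gsea`, `gsprog cges`, `gsprog diffcoexp`,
`gsprog crosstalk` — each stage reading/writing TSV with a JSON run-metadata
sidecar; see `gsprog --help`.

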