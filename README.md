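# pemtscope

Quantifying **partial epithelial–mesenchymal transition (pEMT)** in bulk
tumor transcriptomes, with explicit correction for fibroblast
contamination.

Carcinoma cells in a pEMT state retain epithelial identity while gaining
mesenchymal traits; in head-and-neck squamous cell carcinoma the extent
of pEMT predicts nodal metastasis and poor survival. A single-sample,
rank-based signature score makes pEMT measurable per patient from bulk
RNA-seq or microarray data — but bulk tissue also contains
cancer-associated fibroblasts (CAFs) that constitutively express many
pEMT genes, so stromal content inflates the score. `pemtscope`
implements the full quantification protocol:

1. **Singscore** — for an up-regulated gene set of size *m* against a
   background of *n* ranked genes, each sample's score is the
   normalized, centered mean rank of the signature genes,

   *s* = (r̄ − r_min)/(r_max − r_min) − 1/2,  r_min = (m+1)/2,
   r_max = (2n−m+1)/2,

   bounded in [−0.5, 0.5] with expectation 0 under random placement,
   plus a dispersion diagnostic (scaled MAD of the signature genes'
   normalized ranks). The 15-gene common pEMT signature ships as a GMT
   fixture.
2. **Deconvolution** — EPIC-style constrained weighted least squares
   estimates non-malignant cell-type fractions per sample
   (min Σ_g w_g(b_g − Σ_c f_c R_gc)², f ≥ 0, Σf ≤ 1), with the remainder
   attributed to an uncharacterized "otherCells" compartment and a
   per-sample convergence flag.
3. **Cohort refinement** — backward/forward stepwise selection under the
   Gaussian AIC finds the cell types whose fractions model the score,
   Ward clustering on those fractions isolates the CAF-high patient
   cluster (mean CAF ≥ 48.3% by default), those patients are excluded,
   and the cohort is re-scored.
4. **Survival** — univariable Cox PH screen (Wald p ≤ 0.05, optionally
   HR > 1), multivariable Cox PH, 40/40 score dichotomization and
   Kaplan–Meier/logrank comparison, including crossing with a second
   binary factor such as nodal status.
5. **Specificity** — a permutation null: thousands of random same-size
   gene sets are scored and tested, and the fraction reaching
   significance is the empirical alpha error of the procedure.
6. **Differential expression** — built-in rank-sum high-vs-low test with
   BH correction, plus direction-aware consensus intersection across DE
   result tables (e.g. from DESeq2/edgeR/limma run externally).

A synthetic-cohort generator (`pemtscope.simulate`) reproduces the
statistical structure all of this assumes — Dirichlet cell-type
mixtures with an optional fibrotic (CAF-dominant) subgroup, a latent
pEMT activity driving tumor-cell signature expression, constitutive
signature expression in CAFs, log-normal noise, and survival whose
log-hazard is proportional to activity — together with ground truth for
recovery tests.

## Worked example

```python
import pemtscope as ps

cfg = ps.SimulationConfig(n_samples=200, n_genes=800,
                          caf_signature_strength=4.0, seed=12)
expr, clinical, truth = ps.simulate_cohort(cfg)
gs = ps.GeneSet("pEMT", ps.simulate.signature_genes(cfg))

scores = ps.score_cohort(expr, gs)
fractions = ps.deconvolve_cohort(expr, ps.make_reference_profiles(cfg))
report, retained_expr, rescored = ps.refine_cohort(expr, scores, fractions, gs)

print(len(report.excluded_samples),
      round(report.spearman_before.loc["CAFs", "rho"], 3),
      round(report.spearman_after.loc["CAFs", "rho"], 3))
```

```
67 0.692 0.442
```

67 of 200 samples fall in the CAF-high cluster and are excluded; the
Spearman correlation between the pEMT score and the CAF fraction drops
from 0.69 to 0.44 — the score on the retained cohort reflects tumor-cell
pEMT rather than stromal content. Survival analysis then proceeds on the
retained samples:

```python
df = clinical.subset(report.retained_samples).data.copy()
df["pEMT_score"] = rescored.scores
fit = ps.cox_univariable_screen(ps.ClinicalTable(df), ["pEMT_score"])[0]
print(fit.summary())
```

which reports the hazard ratio, 95% CI and Wald p of the continuous
score.

The same steps are scriptable from the shell:

```bash
pemtscope simulate --n-samples 200 --caf-signature-strength 4 --seed 12 --out cohort/
pemtscope score --expr cohort/expression.tsv --gmt sets.gmt --out scores.tsv
pemtscope deconvolve --expr cohort/expression.tsv --ref cohort/reference.tsv --out fractions.tsv
pemtscope run --config config.yaml
```

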