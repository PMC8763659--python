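# Methods

## The measurement problem

Bulk expression of a tumor biopsy mixes malignant cells with stroma.
A rank-based signature score computed on bulk data therefore measures
"signature expression by anything in the tissue", not "signature
expression by tumor cells". For mesenchymal programs such as pEMT this
matters acutely: cancer-associated fibroblasts (CAFs) express many
signature genes constitutively, so a fibrotic sample scores high
regardless of its tumor cells' state. The pipeline treats this as an
explicit estimation-then-selection problem: estimate stromal
composition, identify the cell types that statistically explain the
score, and remove the patient cluster whose score is dominated by CAF
content before any survival inference.

## Singscore

Within each sample, genes are ranked 1..n ascending with average ties
(`scipy.stats.rankdata`). For an up-only signature of size m the score
is the signature genes' mean rank r̄ mapped affinely onto [−0.5, 0.5]:
score = (r̄ − (m+1)/2) / ((2n−m+1)/2 − (m+1)/2) − 0.5. Properties relied
on throughout: invariance under any strictly increasing per-sample
transform (so linear vs log2 input is irrelevant to the score — the
optional log2(x+1) preprocessing is retained purely for convention),
expectation 0 under random placement, and strict monotonicity in the
signature genes' ranks. The dispersion diagnostic is
1.4826 × MAD(normalized ranks r/n) of the signature genes; the scale
constant and the use of normalized (rather than raw) ranks are
conventions of this package and configurable, since only "dispersion of
normalized ranks" is standard. Signature genes absent from a matrix are
dropped with a warning and m recomputed, mirroring the incomplete gene
recovery of real microarray cohorts; fewer than two surviving genes is
an error.

The signature fixture is the 15-gene common pEMT program
(`src/pemtscope/data/pemt_signature.gmt`). No computation depends on
which symbols it contains — it is a label set of size 15.

## Deconvolution

Per sample, over the reference's marker genes g and cell types c:
minimize Σ_g w_g (b_g − Σ_c f_c R_gc)² subject to f_c ≥ 0 and
Σ_c f_c ≤ 1, with other_fraction = 1 − Σ_c f_c. Marker genes are assumed
unexpressed in the "other" (malignant) compartment — the identifiability
contract that lets the remainder absorb tumor content. The solver seeds
an SLSQP polish with a penalized NNLS solution (slack variable for the
simplex constraint, penalty row weight 10⁶ × data scale). The
convergence flag is a first-order certificate, not a solver status:
constraint violation < 1e-8 and projected-gradient norm < 1e-6 (scaled
by the squared data magnitude), because SLSQP can report line-search
stalls on the simplex boundary at points that satisfy the KKT conditions
to machine precision. Gene weights default to 1 and rescaling all
weights by a constant provably leaves the minimizer unchanged. Optional
mRNA-content renormalization (f′_c ∝ f_c / content_c, "other" content
1) converts mRNA proportions to cell proportions and is off unless
contents are supplied. Real published reference profiles are external
resources and are not bundled; the synthetic generator provides
references for testing, and users supply their own TSV for real data.

The `square` pre-transform (squaring normalized microarray intensities)
and `exp2` (un-logging log2 data) are both provided; which of the two a
given microarray normalization calls for depends on how the data were
processed upstream, so the choice is explicit rather than guessed.

## Cohort refinement

1. Samples whose deconvolution did not converge are dropped.
2. Backward/forward stepwise selection of a Gaussian linear model
   score ~ cell-type fractions, criterion AIC = n·ln(RSS/n) + 2(k+1).
   The search starts from the full model, at each step evaluates every
   single-term deletion and addition, takes the lowest-AIC move (exact
   ties resolved toward the smaller model, then lexicographically), and
   stops at a local optimum. The "otherCells" column is excluded from
   the candidate set: it is the exact complement of the named fractions
   and would alias the intercept. Collinear candidates (design condition
   number > 1e10) are an error naming the offending pair.
3. Ward clustering (Ward.D2: variance-increase criterion on Euclidean
   distances, `scipy.cluster.hierarchy`; Ward.D available as a config
   switch, since "Ward distance" is ambiguous between the two) of
   samples on the selected fractions, cut into k = 2 clusters by
   default — the smallest cut that can isolate a contaminated cluster;
   k is configurable. Cluster labels are canonicalized by smallest
   member index so the partition is order-invariant.
4. Every cluster whose mean CAF fraction reaches the threshold (default
   0.483, configurable — a cohort-derived operating point, not a
   universal constant) is excluded entirely; if none qualifies nothing
   is excluded, so uncontaminated cohorts pass through unchanged.
5. The retained cohort is re-scored and Spearman correlations of each
   cell type's fraction with the score are reported before and after.

## Survival models

Cox proportional-hazards fits use lifelines (Efron tie handling).
The univariable screen flags a covariate as relevant when Wald p ≤ 0.05,
optionally also requiring HR > 1 ("risk-factor mode") — the directional
rule appropriate when the screen feeds a risk model; protective
covariates need the two-sided mode. The multivariable model jointly fits
the screened terms and reports per-term HR/CI/p plus partial-likelihood
AIC and concordance. 40/40 dichotomization uses type-7 quantiles; group
sizes equal the type-7 position counts ⌊1+(n−1)p⌋ even under boundary
ties, which are admitted in ascending sample-id order; with
lower = upper and odd n the middle sample goes to "low". All-equal
scores are a degenerate-quantile error. Kaplan–Meier medians are the
first time S(t) ≤ 0.5 and are flagged undefined (None) when never
reached; group comparisons use the (multivariate) logrank test.

## Permutation null (alpha error)

Per iteration: draw m genes uniformly without replacement from the
matrix's gene universe minus the signature, Singscore all samples
(computed directly from the precomputed rank matrix), and apply the
decision rule — continuous-score Cox Wald p ≤ 0.05 with HR > 1 by
default; two-sided Wald and 40/40-logrank rules are alternatives, and
the rule used is recorded in the result. The alpha error is the fraction
of positive decisions; everything reproduces from one seed.

A calibration subtlety, found empirically and worth knowing when
interpreting real-cohort alpha errors: on a composition-structured
cohort, every random gene set's score loads on the same few latent
factors (stromal fractions, tumor activity), because a gene's ranks
across samples follow its cell-type profile. Conditional on one cohort,
the chance association of those factors with survival shifts every
iteration's test statistic, overdispersing the null (≈0.10 two-sided at
n = 300 in simulation, against a nominal 0.05) even when survival is
generated independently of expression. This inflation is a property of
the procedure on structured tissue, not a bug; the package's calibration
test therefore uses a single-compartment (structureless) cohort, where
decisions are exchangeable and the empirical alpha matches the nominal
level to binomial Monte-Carlo error, and `scripts/acceptance.py` reports
the structured-cohort alpha separately.

## Differential expression

The built-in test is the two-sided Wilcoxon rank-sum per gene (high vs
low group), BH-adjusted across genes, with log2 fold changes of linear
group means under a pseudocount of 1. External algorithms enter through
the DEResult TSV schema (gene, log2fc, p, q, direction). The consensus
keeps genes significant at the q threshold in every table with one
agreed direction; direction-discordant genes are excluded even if
universally significant, and adding tables can only shrink the
consensus.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes, and
no more:

- **Fractions.** Dirichlet over {tumor, CAFs, immune, endothelial} with
  concentrations (3.0, 1.2, 1.2, 0.6): mean tumor content 50%, mean CAF
  content 20%, with substantial but unimodal between-sample variability.
  When CAF contamination is on (caf_signature_strength > 1), a fibrotic
  subpopulation (default 20% of samples) draws instead from a Dirichlet
  with the CAF concentration raised to 14 (CAF content typically
  0.55–0.85), producing the distinct CAF-dominant cluster that
  desmoplastic tumors form in real cohorts; a unimodal Dirichlet spreads
  CAF content continuously, so a k = 2 Ward cut either has no separable
  cluster to remove or, at heavier baseline spread, trips the threshold
  by chance in uncontaminated cohorts. Cohorts without contamination
  have no fibrotic subgroup, so refinement correctly excludes nobody.
- **Expression.** Bulk value = Σ_c fraction_c × profile_c(gene), with
  log-normal baseline profiles; signature genes are expressed in tumor
  cells (scaled by exp(activity_effect × activity), activity ~ N(0,1),
  activity_effect 1.0) and in CAFs (baseline × caf_signature_strength),
  and silent elsewhere; a dedicated block of deconvolution marker genes
  (10 per non-tumor type) is silent in tumor cells. Multiplicative
  log-normal noise, default sd 0.2 on the natural-log scale — within the
  replicate-variability range of bulk RNA-seq.
- **Survival.** Exponential event times with hazard
  baseline_hazard × exp(hazard_log_hr × activity); defaults
  baseline 0.02/month (median ~35 months at activity 0) and
  hazard_log_hr = log 2. Censoring is exponential with its rate
  calibrated by bisection so the expected censored fraction equals
  censor_rate (default 0.3), keeping the time scale continuous.
- **Seeding.** One seed feeds named substreams (profiles, fractions,
  activity, noise, survival), so changing e.g. the noise level leaves
  the drawn fractions untouched, and a fixed seed fixes every output.

What the generator does *not* model — and therefore what passing tests
do not certify for real data: probe-level microarray artifacts, HPV
status or other molecular subtypes, batch effects, correlated gene
modules beyond the cell-type factors, non-proportional hazards, and
informative censoring. The generator exists to verify that each
algorithm recovers known structure, not to imitate any particular
cohort.

## Numerical and interface conventions

Duplicate gene rows collapse by arithmetic mean on the input scale
(deterministic and order-independent); gene identifiers match
case-sensitively with no alias resolution (alias maps are external
resources); GMT lines need at least name, description and one gene;
clinical tables require time > 0 and event ∈ {0,1} and preserve
categorical level order of first appearance. Scores at rank ties use
average ranks, making scores continuous in the data. All tabular outputs
re-write as TSV; pipeline runs emit a JSON report that is byte-identical
across runs with the same config and seed.

## Problem sizes

The test suite and acceptance script run on simulated cohorts of
120–800 samples and 300–1,500 genes, with 2,000 permutation-null
iterations and 400 screen-calibration replicates — sizes at which every
recovery property is comfortably identified while the whole suite stays
fast on a single core.

## Known limitations

Because the score is bounded, cohorts in which the signature is strongly
expressed almost everywhere (e.g. heavy CAF contamination) push scores
toward the +0.5 ceiling; the compressed scale blunts a *linear*
continuous-score Cox fit even when the score's ordering remains strongly
prognostic, so the 40/40 dichotomized comparison is the more robust
survival readout in that regime.
The stepwise search guarantees only local AIC optimality (verified
against exhaustive best-subset search on small instances). The CAF
threshold and k are operating points inherited from one cohort's
dendrogram, not learned. The deconvolution assumes marker genes are
silent in malignant cells; violations bias fractions upward. The
alpha-error's nominal calibration holds for structureless expression;
on real tissue it quantifies the procedure's specificity including
composition effects, which is precisely what makes it informative.
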