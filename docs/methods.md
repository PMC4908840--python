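# Methods

## Analysis model

The pipeline treats each CpG probe's methylation fraction (β-value, in
[0, 1]) as the response of an ordinary least-squares regression, run probe by
probe:

* **Discovery** (case–control cohort): β ~ disease + age + sex + BMI, with
  disease ∈ {0, 1} pooling simple steatosis and NASH against controls. The
  family of unique probes belonging to one gene cluster is adjusted by the
  Benjamini–Hochberg step-up procedure; adjusted p < 0.05 is significant.
  Ties share the min-over-tail adjusted value; a probe annotated to several
  genes enters the family once and is reported once per gene.
* **Validation** (staged NAFLD-only cohort): β ~ stage + age + sex + BMI,
  where stage is the ordinal fibrosis stage {0, 1, 2} or steatosis grade
  {0, …, 3} treated as numeric. Raw p < 0.05 is significant — this is a
  targeted follow-up of a pre-selected probe set, so no further multiplicity
  control is applied. Covariates absent from a cohort's metadata are dropped
  with a logged record of the set actually used.

A probe is **validated** when significant in both cohorts with agreeing
coefficient signs (the consistency filter defaults to the fibrosis scan,
configurable to steatosis); the shared sign defines its direction
(hyper-/hypomethylated with disease severity). Missing data are handled by
listwise deletion, and the per-model n is reported in every result row.

Stage labels are harmonised across cohorts: fibrosis "insignificant" / 0 /
0.5 → 0, "mild" / 1 → 1, "advanced" / 2 → 2; steatosis "<5 %" → 0,
"5–33 %" → 1, "34–66 %" → 2, ">66 %" → 3. Both maps accept numeric codes and
string labels and are idempotent on their outputs.

## Gene-level statistics

For each gene, `n_total` counts its TSS1500 probes (|distance to TSS| ≤
1500 bp, inclusive — matching the array vendor's TSS1500 naming — and no SNP
overlap), and validated sites are split by direction. Per direction the
module reports:

* `pct_sig` = round(100·k/n), half away from zero;
* the binomial overrepresentation tail P(X ≥ k), X ~ Binomial(n, p₀ = 0.05),
  i.e. the chance of at least k significant sites if every site were
  independently significant at the nominal rate. It is evaluated through the
  regularised incomplete beta function (scipy's binomial survival function),
  accurate deep into the tail (~1e-20), and reported unadjusted;
* a strength category computed from the *combined* validated count across
  directions (the categorisation describes how much of the promoter changed,
  not in which direction): category 1 for ≥ 7 sites with ≥ 50 % changed,
  category 2 for 3–6 sites with ≥ 50 % or ≥ 7 sites with 30–50 %, category 3
  otherwise. Boundary conventions: exactly 50 % goes to the higher category;
  exactly 30 % to category 2; 3–6 sites with 30–50 % changed fall in
  category 3 (the conservative reading of an under-specified corner). All
  category comparisons use integer arithmetic, so boundaries are exact.

The per-direction binomial count deliberately conditions on direction while
`n_total` does not: the question is whether the promoter accumulates more
consistently hyper- (or hypo-) methylated sites than chance would allow
among all of its TSS1500 sites.

Gene-level methylation of a sample is the arithmetic mean β over the
validated sites of one direction — averaging over significant sites only,
which defines a surrogate marker concentrated on the disease-responsive part
of the promoter — then transformed to the M-value scale M = log2(β/(1−β)).
Averaging precedes the transform. β values at the boundaries are clamped to
[1e-6, 1−1e-6] before the logit.

## Methylation–expression association

In the matched cohort, each gene × direction M-value profile is related to
expression four ways: a robust linear model adjusting for fibrosis stage, the
same model with a fibrosis × expression interaction term (the reported
coefficient and p belong to the expression main effect; the interaction term
is emitted as auxiliary output, since which term the headline p should
reference is genuinely ambiguous), and uncorrected Pearson correlations in
the NAFLD and control subgroups. Significance is p < 0.05 unadjusted in all
four — this stage is descriptive follow-up on already-validated genes.

The robust estimator is a redescending M-estimator: Tukey bisquare with
tuning constant 4.685 (≈ 95 % efficiency at the Gaussian), solved by
iteratively reweighted least squares started from a monotone Huber fit so
the redescending weights cannot latch onto a bad local solution.
Convergence is declared on the parameter change (tolerance 1e-6, cap 300
iterations) because the objective of a redescending norm can creep long
after the slope has stabilised; hitting the cap raises an error carrying the
iteration diagnostics. A constant-weight (OLS) path is available and the
test suite pins the robust fit to it on clean data. An MM-type
high-breakdown estimator would be the closest classical relative; the
bisquare-with-Huber-start construction was chosen because it is standard,
available in statsmodels, and the package's accuracy claims rest on
synthetic recovery experiments run with this exact estimator, not on
re-matching any particular published coefficient.

Model orientation: the default regresses the M-value on expression plus
fibrosis (methylation as response). The reversed orientation — expression on
methylation — is available via `orientation="expr"`, and is the one used in
recovery experiments, because a generative coupling slope γ (expression
change per unit gene-level M) lives on that side. Slope sign and
significance are essentially orientation-invariant; magnitude is not, and
the orientation used is recorded in the run manifest.

Expression matrices with several transcript rows per gene symbol are
collapsed by their mean, with the affected gene count logged: genes probed
by many transcript identifiers can yield unspecific expression signal, and
the log makes that visible.

The neighbour scan re-runs the adjusted robust model of a source gene's
methylation against the expression of up to k = 5 genes on either side
(nearest TSS first, positional rather than strand-aware); rows carry the
expression gene in `gene` and the methylation source in `neighbor_of`.

In the final report, *inverse* means a significant negative
methylation–expression slope and *parallel* a significant positive one,
independent of the methylation direction — so a hypomethylated gene whose
methylation correlates positively with its transcription is a *parallel*
association.

## Synthetic cohorts

The generator emulates the three-cohort design the analysis assumes:
a discovery cohort of 74 (45 controls, 14 SS + 15 NASH), a validation cohort
of 54 staged NAFLD patients (fibrosis ≈ 59 % mild / 41 % advanced, steatosis
spread over all four grades; diagnosis subtype recorded as unknown), and a
matched cohort of 50 (30 controls, 20 NAFLD) carrying expression.

Methylation follows a logit-normal model: logit β = probe baseline
(N(0, 1)) + b·(disease + fibrosis) + covariate effects + gene-level noise +
probe-level noise. Because the M-value transform is the logit up to log
base, planted effects are linear on the analysis scale. Choices and
defaults:

* **Disease effect b = 0.2 logits** for affected probes (default half of
  each gene's 8 TSS1500 probes; 75 % hypermethylated). At mid-range
  baselines this is a 3–6 % β shift — the magnitude the analysis is meant
  to detect. The fibrosis term adds b per stage, so an advanced-stage
  contrast is roughly twice the case–control contrast, consistent with
  stage-dependent shifts being the stronger signal. Steatosis carries no
  effect by default (the stage variable that drives methylation is
  fibrosis).
* **Noise**: a shared per-gene per-sample component (sd 0.4) plus
  probe-level noise (sd 0.3), both on the logit scale. The shared component
  models promoter co-methylation — CpGs of one promoter move together
  across individuals — and is what makes gene-level aggregation behave the
  way it does on arrays. Total per-probe sd 0.5 ≈ 0.12 in β units at β =
  0.5. The study's source arrays do not report per-probe variances; these
  are defaults, not estimates.
* **Covariates**: age N(50, 12) years, BMI N(40, 10) kg/m², ~72 % female,
  with small methylation effects (0.004/logit per year and per BMI unit,
  0.05 for male sex). Demographics match the published cohort tables in
  distribution without copying any per-sample data.
* **Decoys**: every gene also receives probes outside the TSS window and
  SNP-flagged probes inside it, always effect-free, so the annotation
  filter is exercised end to end.
* **Expression**: x = μ_g + γ_g·M̄ + δ_g·fibrosis + N(0, 0.5), where M̄ is
  the gene-level M-value — the M transform of the mean β over the gene's
  affected probes, i.e. exactly the statistic the analysis computes
  (average first, transform second). Defining the coupling on the analysis
  statistic makes the planted slope γ the estimand of the association
  stage; defining it on the mean of per-probe M-values instead would bias
  recovered slopes upward by a Jensen gap of roughly 10 %. Defaults:
  γ = −0.5 for a random 40 % of genes (methylation represses transcription),
  δ = −0.3, μ_g ~ N(8, 1) on a log2-intensity-like scale. Cross-gene
  couplings can be planted to give the neighbour scan a true positive.

All randomness flows from numpy Generators: one seed reproduces every
matrix bitwise, the probe/gene truth can be pinned separately
(`truth_seed`) so sampling variation can be studied at fixed truth, and the
ground-truth ledger (per-probe direction and effect, per-gene γ) is emitted
alongside the matrices.

What the generator does **not** model: array chemistry (probe-type bias,
dye bias, detection p-values, batch), cell-type composition, realistic
bimodal genome-wide β distributions, linkage between neighbouring genes'
expression, or missing values (unless configured). Passing tests therefore
demonstrate that the statistical chain is correct and calibrated under its
stated assumptions — not that those assumptions hold on any particular real
array dataset.

## Benchmark problem sizes

The seeded experiments in `methlink.evaluation` (also run by
`scripts/acceptance.py`) use: 20 replicates of 200 null probes at n = 74
for calibration; 20 replicates of 10 genes × 8 probes (half planted at 0.5
logits) across the 74/54 discovery–validation chain for sensitivity; and
20 replicates × 10 coupled genes at n = 50 per planted γ for slope
recovery, with the median taken over the pooled replicate × gene estimates.
These sizes put the Monte-Carlo error of each reported rate well below the
margins being checked while keeping the whole benchmark in the
tens-of-seconds range.

## Known limitations

* The study-scale real-data results (how many of the 83 genes are
  differentially methylated in the deposited cohorts, and their
  coefficients) require the original array data and are out of scope; the
  package's correctness claims are the exact gene-level statistics, oracle
  equivalences and synthetic recovery described above.
* OLS on β-values is the analysis's own convention; it ignores the
  mean–variance relationship of proportions. The scans inherit this
  deliberately rather than switching to beta regression.
* The binomial overrepresentation test assumes sites are independent under
  the null; co-methylation makes it anti-conservative as a literal
  probability, which is why it is reported as a ranking/evidence statistic
  without multiplicity adjustment.
* Neighbour resolution is positional by TSS distance and ignores strand and
  overlapping transcripts.
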