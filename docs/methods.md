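# Methods

`glycoreg` implements a two-phase workflow for discovering glycosylation
genes (glycogenes) that are specific to basal-like triple-negative breast
cancer (TNBC) relative to other breast cancers (non-TNBC) and normal
tissue, and for attributing their dysregulation to copy-number alteration
(CNA), DNA methylation (DM) or transcription-factor (TF) activity. This
note records the models, the defaults and their rationale, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Phase A: candidate discovery

A gene becomes a candidate when it passes at least one of three evidence
criteria and carries an anabolic or catabolic pathway annotation
(criterion 4): `final = (c1 ∪ c2 ∪ c3) ∩ {anabolic/catabolic}`. The
union-then-filter combination is a package design choice: the exact set
algebra behind such multi-criteria filters is underdetermined, so we fix
one and document it rather than guess.

### Criterion 1: moderated differential expression

Per dataset, each gene is tested in two contrasts (TNBC vs non-TNBC and
TNBC vs normal) with an empirical-Bayes moderated t. Per-gene pooled
variances `s_g^2` (residual df `d_g`) are shrunk toward a prior `s0^2`
with prior df `d0`:

    s̃_g^2 = (d0·s0^2 + d_g·s_g^2) / (d0 + d_g),
    t̃_g  = log2FC_g / (s̃_g · sqrt(1/n1 + 1/n2)),  df = d0 + d_g.

`d0` and `s0^2` are estimated by the method of moments on `log s_g^2`
using the digamma/trigamma moments of the scaled-F sampling distribution
(trigamma inverted by Newton iteration). This is the standard
limma-style estimator; the test suite verifies agreement with
Bioconductor limma to ~1e-14 on a fixture, and reduction to the ordinary
pooled t when `d0 = 0`. p-values are BH-adjusted within contrast.

Genes significant (FDR < 0.05) in both contrasts with one direction, in
every dataset, form the common set; its top 50% (⌈n/2⌉) by mean
|moderated t| across contrasts and datasets is the criterion-1 list. The
ranking statistic behind a "top 50%" cut is underdetermined, so the
package fixes mean |moderated t| with deterministic ceiling/tie rules
(smaller mean FDR, then lexicographic symbol).

### Criterion 2: ensemble gene-set enrichment

Two base methods per set, contrast and dataset:

* exact hypergeometric over-representation of the FDR-significant gene
  list (`P(X ≥ k)`), and
* a two-sided rank-sum test of member-gene moderated-t statistics versus
  non-members (exact null by enumeration for ≤ 10 members without ties,
  normal approximation with tie correction otherwise).

The ensemble rank is the mean of per-method ranks; the combined p-value
is Fisher's method, BH-adjusted across sets within each contrast and
dataset. A set's direction is the sign of its members' mean moderated t.
Large multi-method GSEA ensembles exist; this package deliberately ships
two exactly-testable base methods, which preserve the idea (method-bias
reduction via rank aggregation) at desk scale — the combiner accepts any
number of per-method tables, so further methods plug in. Sets must be
significant with one direction in both contrasts of every dataset;
member genes whose own DE direction matches the set direction in every
dataset form the criterion-2 list.

### Criterion 3: graph-regularized sparse logistic models

Genes sharing at least one enriched set are joined in a co-membership
graph with degree-normalized Laplacian `L`. TNBC vs non-TNBC status is
modelled by

    min_{b0, β}  (1/n) Σ_i log(1 + exp(−y_i (b0 + x_i β)))
                 + λ1‖β‖₁ + λ2 βᵀLβ,

solved by FISTA (proximal gradient with Nesterov acceleration, function-
value restart, step size from the spectral bound
`σ_max(X)²/(4n) + 2λ2·λ_max(L)`). `λ2 = 0` recovers plain L1 logistic
regression, which the tests verify against an independent saga solver to
≤ 1e-4 per coefficient. The Laplacian term encourages connected
(biologically related) genes toward similar coefficients; standard L1
solvers do not natively offer this penalty, so the objective is solved
explicitly here.

Ten models per dataset are fitted on stratified 80/20 resamples.
`λ1` is chosen per model by internal 3-fold stratified CV over a
log-spaced path below the data-derived `λ_max`, with the 1-SE rule
(sparsest pair within one standard error of the best mean accuracy);
`λ2` comes from the small grid {0, 1}. Held-out sensitivity/specificity
use probability threshold 0.5. A model whose every gene coefficient is
zero is an intercept-only non-classifier; its held-out metrics are
reported as NaN rather than as the degenerate constant prediction. Genes
selected (nonzero coefficient) at least once in at least two datasets
pass the criterion — a single superset rule covering both the
all-datasets and the two-datasets tier.

## Phase B: regulatory attribution

### CNA / DM correlation and δCor

Spearman correlations between expression and each cis layer are computed
for all breast cancers and within TNBC and non-TNBC (pairwise-complete
observations, average ranks for ties, ≥ 3 pairs required; constant
vectors yield missing values with a warning). Magnitudes are classified
as strong (≥ 0.450), moderate (0.300–0.449), weak (0.100–0.299) or
low/no (< 0.100). Because methylation silences transcription, DM
regulation additionally requires ρ < 0; the sign-consistency flag
records this (and ρ > 0 for CNA) while magnitude classes are reported
for both signs. Differential regulation per gene is

    δCor = | Cor(g, reg)_TNBC − Cor(g, reg)_non-TNBC |  ∈ [0, 2],

and per gene group (pathway or all genes) the TNBC and non-TNBC
correlation distributions are compared with a two-sided Mann–Whitney
rank-sum test (exact null for combined n ≤ 12 without ties), BH-adjusted
across groupings within each regulator. "Mann–Whitney" and "Wilcoxon
rank-sum" name the same unpaired test; it is the default, and a paired
signed-rank variant is exposed via `paired=True`.

### TF–glycogene networks by stability selection

ChIP peaks within the half-open window `[TSS − 2000, TSS + 2000)`
(≥ 1 bp overlap; strand recorded but not shifting the window) define
each gene's candidate TFs. Within each group, the gene's expression is
regressed on its bound TFs' expression with the gene's CNA and DM as
unpenalized covariates — implemented by Frisch–Waugh residualization of
the response and the TF columns on `[1, CNA, DM]`, which is exactly
equivalent to leaving the covariates unpenalized in the joint lasso
(`penalize_covariates=True` appends them as ordinary columns instead).
Each of 100 repetitions draws an 80% subsample without replacement,
standardizes, and fits a lasso whose penalty is chosen by internal
3-fold CV with the 1-SE rule; a TF's selection frequency is the fraction
of repetitions with a nonzero coefficient.

The retention threshold is chosen from {0.1, …, 0.9} to maximize 5-fold
CV R² of an OLS refit on the retained TFs; exact ties (identical
retained sets) keep the larger, sparser threshold. When even the best
threshold's CV R² is ≤ 0 the TF model predicts worse than the intercept
out of sample and the gene is excluded from that group's network — this
null guard is what keeps differential networks clean when a gene has TF
structure in one group only. Group networks are bipartite TF→gene edge
sets; the TNBC-specific network is the plain set difference
TNBC − non-TNBC (frequency differences are ignored by default — the
subtraction is on edge sets; a δ-frequency mode exists but is not the
default). TFs with ≥ 4 differential targets are reported as master
regulators, ranked by target count then name.

## Synthetic cohorts

`simulate_cohorts` draws a configurable number of cohorts (default 3,
mimicking one TCGA-like and two METABRIC-like datasets) with shared
planted truth and independent noise:

    expr(g,s) = μ_g + Δ_g·1[s ∈ TNBC] + α_g·cna(g,s) + β_g·dm(g,s)
                + Σ_t w(t,g,group)·tf(t,s) + ε,   ε ~ N(0, noise_sd²)

with μ_g ~ N(8, 1) (log2 scale), CNA as Normal copy ratios
(sd 0.5, +0.5 TNBC shift for CNA-driven genes), DM as
logistic-transformed Gaussians (always in (0, 1)), β_g < 0 enforced for
DM-driven genes, and iid standard-normal TF expression (an optional
correlation knob exists but defaults off). Defaults: 120 genes, 25 TFs,
150 samples per group per cohort, 10% DE genes at |log2FC| = 2,
noise_sd = 1 — sample sizes and effect sizes in the range of the real
cohorts the workflow was built for. Disjoint gene blocks carry the DE,
pathway, CNA, DM and TF effects so recovery can be scored unambiguously.
`make_binding_peaks` places one 100-bp peak inside the ±2 kb promoter
window of every true edge's target and adds decoys both inside other
promoters (non-functional binding) and midway between promoters
(intergenic).

What a green recovery test establishes: under Gaussian noise,
independent samples and exactly planted effects, each stage finds what
was planted at the stated operating point. What it does not establish:
robustness to batch effects, probe-level artifacts, correlated TF
programs, copy-number segmentation structure, non-Gaussian expression
distributions, or cohort heterogeneity — none of which are simulated.
Cohort-level results from real TCGA/METABRIC/CistromeDB analyses depend
on those datasets and are not reproduced by the simulator.

## Numerical and scale choices

* All readers are strict: duplicate identifiers, ragged rows, inverted
  intervals and unknown strands or groups are hard errors naming the
  offending record; missing expression is NaN, excluded pairwise in
  correlations; genes > 20% missing per dataset are dropped with a
  warning.
* FISTA: tol 1e-8 on relative objective change (1e-6 inside CV loops),
  objective checked every 10 iterations with restart on increase.
* Seeds: every stochastic stage takes an explicit seed; cohort c of a
  simulation uses `default_rng([seed, c])`, and per-gene stability fits
  offset the user seed by the gene index.
* Recovery tests use the effect sizes and per-group sample sizes stated
  with each property (Δ=2 with n=100/group for DE; pathway effect +1.5;
  TF weight 1 with noise 0.5 and n=150/group) but scale unpinned
  dimensions (number of seeds per loop, genes in end-to-end runs) down
  so the full suite stays within a desktop-CPU budget; thresholds were
  fixed before the tests were first run.

## Known limitations

* The classifier is binary (TNBC vs non-TNBC); a three-class variant
  (including normal) is noted as an extension, not implemented.
* Networks are inferred over candidate glycogenes only; no
  full-transcriptome mode.
* The enrichment ensemble has two base methods; the combiner is
  pluggable but no further methods ship.
* No survival analysis, PAM50 subtyping, probe collapsing or data
  download clients: group labels and gene-level matrices are inputs.
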