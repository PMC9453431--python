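# Methods

This note documents the statistical models, the defaults and why they are
set where they are, the synthetic-data generator's scope, and the numerical
choices that were genuinely open.

## Study design and synthetic data

The pipeline assumes a concentration series with a 0 µM vehicle control and
replicated pools per concentration. The generator's defaults are the
emulated study's conditions: a 0.4× geometric dilution series from 50 µM
over 7 levels (0, 0.205, 0.512, 1.28, 3.2, 8, 20, 50 µM; 0.205 is 50·0.4⁶
rounded to 3 significant figures), 4 replicate pools per level (32
samples), and a morphology screen of n = 36 animals per concentration.

Counts are negative binomial with `variance = µ + α·µ²`. Per-gene
dispersions α are drawn log-uniform on [0.005, 0.5] (the typical bulk
RNA-seq range) and baseline means log-uniform on [10, 5000]. The log2 fold
change of gene *g* at concentration *d* follows a Hill curve
`emax·dⁿ/(ec50ⁿ+dⁿ)`. Four classes structure the 2,000-gene default
budget (chosen so the full test suite stays desk-scale; the generator
scales to genome size):

| class | n | emax (log2FC) | half-max (µM) | Hill n | role |
|---|---|---|---|---|---|
| `ahr_module` | 100 | +3…10 | 10–25 | 1.5–3 | co-regulated responsive module |
| `sensitive` | 100 | ±1.5…4 | 0.3–1.5 | 1–2 | low-threshold responders |
| `high_only` | 100 | ±2…6 | 25–60 | 3–6 | teratogenic-range responders |
| `null` | 1,700 | 0 | — | — | calibration background |

The module parameters are set so that the module's expression benchmark
concentrations cluster near the phenotype benchmark (see below), which is
the scientific situation the anchoring analysis is designed to detect.
Within-module co-expression is induced by one latent normal deviate per
module per sample, added on the log2 scale; its variance is
`ρ/(1−ρ) · v̄`, with `v̄` the module-average NB log-variance, so the
pairwise within-module log-expression correlation is ≈ ρ (default 0.6).
This emulates a shared upstream regulator cheaply; it does not model a full
covariance structure, plate effects, batch effects, or gene-length biases,
so passing tests demonstrate recovery of planted co-regulation, not
robustness to those real-data complications.

Teratogenicity outcomes are Binomial(n, P(d)) with
`P(d) = bg + (1−bg)/(1+(EC50/d)^h)`, defaults EC50 = 16.5 µM, h = 2,
bg = 0. The slope default is what ties the generator to both printed
anchors: with h = 2 the concentration adding 10% risk is
16.5·(0.1/0.9)^(1/2) = 5.5 µM. One pooled "any_effect" endpoint is
simulated; per-plate overdispersion is not modeled (no variance estimate is
available to parameterize it).

All draws go through `numpy` Generators seeded from explicit integers;
identical (config, seed) reproduce bit-identical datasets.

## Phenotype dose-response

The 3-parameter binomial log-logistic model is fitted by maximum
likelihood (L-BFGS-B over background ∈ [0, 0.2], log EC50, log slope, with
a start grid over EC50). Background is bounded at 0.2 because screening
backgrounds are small; it can be fixed at the observed control incidence.
Data with constant incidence raise a non-identifiability error. The EC50
interval is a 95% profile-likelihood interval (deviance cutoff
χ²₁(0.95)/2, bisection on each side).

The benchmark concentration uses the **added-risk** convention:
`P(d) − P(0) = BMR` with BMR = 0.10 by default, solved in closed form
(`d = EC50/((1−bg)/BMR − 1)^{1/h}`), with a bisection twin used as an
independent numerical oracle. The BMDL is a direct profile-likelihood lower
bound on the BMC, obtained by reparameterising EC50 in terms of the BMC and
profiling out background and slope at the same χ²₁(0.95)/2 cutoff (the
two-sided-95% convention used for the EC50 CI). The fit report records the
risk convention.

## Differential expression

Genes with zero counts in ≥ 25% of samples are removed; gene ids that
collide case-insensitively are averaged under the lowercased id. Size
factors are median-of-ratios against the geometric-mean pseudo-reference,
computed over genes expressed in every sample. "Samples" is the unit of the
25% rule (8 of 32 in the default design).

Each non-control concentration is tested against the full control group
with an NB GLM (log link, log-size-factor offset) fitted by a vectorized
IRLS; the Wald statistic is the treatment coefficient over its observed-
information SE, rescaled to log2. Dispersions are estimated per gene by
maximizing the **Cox–Reid adjusted** profile likelihood on a log grid
(cell means plugged in per dose group); without the adjustment the n = 4
per-group design underestimates dispersion and the Wald test is
anticonservative. A parametric trend `α(µ) = a₀ + a₁/µ` is fitted across
genes and gene-wise values are shrunk toward it in log space with an
**empirical-Bayes weight**: the sampling variance of a log dispersion
(≈ trigamma((m−k)/2)) against the observed residual scatter around the
trend. When true dispersions scatter widely around the trend — as when
dispersion is unrelated to the mean — shrinkage automatically weakens; a
fixed 50/50 blend was tried first and biased high-dispersion genes low
enough to inflate the far tail of the null distribution. Dispersion
outliers more than 2 robust SDs above the trend stay unshrunk. The Wald
statistic is referred to a **t distribution with m − k degrees of freedom**
(samples minus dose groups, the residual df of the dispersion fit) rather
than a normal; under null simulations this calibrates both the 5% level
(measured 0.040–0.048) and the far tail (P(p < 10⁻⁴) ≈ 10⁻⁴), which a
normal reference misses by an order of magnitude at this sample size.
BH adjustment is applied within each concentration's gene family — the
reporting unit is per-concentration DEG counts — not pooled across
concentrations. This is a transparent re-implementation of the
DESeq2-style workflow; it does not reproduce DESeq2 numerics (no LFC
shrinkage, no Cook's outlier replacement, no independent filtering).

The DEG partition splits the union of per-concentration DEG sets into
non-teratogenic-only, overlap, and teratogenic-only, with the teratogenic
concentration set supplied by the user (default {20, 50} µM).

## Williams-gated benchmark concentration modeling

Genes are screened for a monotone trend with a two-sided Williams-type
test. The isotonic estimate at the top dose is computed by the closed-form
identity "max over u of the pooled mean of groups u..K" (the PAVA solution
at the last level), which makes the statistic a pair of matrix products
and lets a 2,000-gene × 1,000-permutation calibration run in about a
second. Significance comes from permutation of sample labels (default
10,000 permutations; add-one estimator; two-sided p = 2·min(p_up, p_down)
capped at 1) rather than Williams' 1971 tables — exact under
exchangeability and free of table interpolation.

Passing genes are fitted by least squares (Gaussian ML, constant variance)
to ten families: linear, poly2–4, power `γ+βd^δ` (δ ∈ [1,18]), hill
`γ+νdⁿ/(kⁿ+dⁿ)` (n ∈ [1,18]), exp2 `a·e^{±bd}`, exp3 `a·e^{±(bd)^c}`,
exp4 `a(c−(c−1)e^{−bd})`, exp5 `a(c−(c−1)e^{−(bd)^g}`) — the BMDExpress
continuous set completed with poly4. Power-type exponents are bounded at 1
to avoid infinite slope at zero. AIC = 2k − 2·loglik with k counting the
variance; ties break by family order (simpler first). Goodness of fit is
the lack-of-fit F-test against the cell-means model. A winning Hill fit
with k below one-third of the lowest positive dose is flagged and replaced
by the next-best model with gof p > 0.05, or returned flagged if none
qualifies.

The BMC solves `|f(d) − f(0)| = 1.349·SD` on [0, max dose] by a log-spaced
bracketing grid plus Brent refinement; a BMC above the top tested
concentration removes the gene. The BMR factor 1.349 is the usual
1-control-SD-equivalent of a 10% tail shift under normality. The **SD
reference is the pooled within-group (pure-error) SD** under the constant-
variance assumption, not the selected model's residual SD: the latter is
selection-biased low (the AIC winner is partly the fit that chased the
noise), which propagates into low BMCs. BMDL/BMDU come from a parametric
bootstrap (default 2,000 draws at the config default; tests and the
pipeline use fewer via an explicit argument): responses are resimulated
from the fitted curve at the pooled SD, model selection is re-run over the
families within ΔAIC ≤ 10 of the winner, each draw's BMC uses that draw's
own pooled SD, and the percentile bounds are bias-corrected (BC: quantile
levels shifted by twice the normal quantile of the fraction of draws below
the point estimate) and clipped to bracket the point estimate. Plain
single-family percentile intervals were measured at ~68% coverage in a
known-truth sweep; the selection-aware, BC variant reaches ~90% at the
8 × 4 design. This remains a numerical difference from BMDS's
profile-likelihood BMDL. Gene-set summaries report the median (and mean)
BMC/BMDL/BMDU over members with a defined, in-range BMC.

## Co-expression network

Fold changes are computed per replicate — including control replicates —
as log2((x + pc)/(control mean + pc)) on normalized counts (pc = 1 by
default). The top genes by coefficient of variation (default 8,000; tests
use matrix-sized values) enter inference. CV is computed on linear-scale
ratios 2^fc: log-scale fold changes have near-zero means that make CV
unstable. For each target gene a random forest (default 500 trees, √p
candidate features per split) regresses the target on all other genes;
normalized variance-reduction importances are the directed incoming edge
weights (summing to 1 per target, 0 for zero-variance targets). Trees use
the full sample set (no bagging): the only randomness is the per-split
feature draw, which makes the weights exactly invariant to a joint
permutation of samples and deterministic under the config seed. Edges are
kept if strictly above the cutoff (default 0.0086, the published
operating point at the 8,000-gene scale — at other scales it is a free
parameter); isolated nodes are reported separately. Modules come from
Clauset–Newman–Moore greedy modularity on the undirected projection with
reciprocal weights summed; module ids are relabelled by size then
lexicographic member for determinism. Degree counts distinct neighbours
ignoring direction; betweenness is computed on the unweighted undirected
projection, normalized by (n−1)(n−2)/2. Edge counts among module genes use
ordered pairs, n(n−1) — the convention consistent with a 178-gene module
having 31,506 edges — and the directed weights are thresholded as such.

A caveat measured during development: with ~32 samples, null importances
do not spread as 1/p for large p (the max stabilises near 0.055 regardless
of p); the "no regressor dominates" property holds when samples comfortably
exceed candidate features.

## Leave-one-concentration-out perturbation

For a chosen module, the network is re-inferred once per non-control
concentration with that concentration's replicate columns removed, holding
the seed and gene set fixed so ratio variation reflects the data removal,
not ensemble randomness. The control is never removed (it is the
fold-change reference), hence 7 leave-outs in the default design. All
ordered within-module pair weights are extracted without thresholding.
Ratios full/reduced are +∞ when the reduced weight is 0 and the full
weight positive, and 1 when both are 0 — zero weights are reported as a
class, not clamped, because clamping would manufacture large ratios.
An edge is *consistently higher* when its ratio exceeds 1 in every column
(pairs with undefined cells qualify on their defined cells but are
flagged), and *progressively lost* when, additionally, the ratios increase
strictly with the left-out concentration's rank (Kendall τ = 1 over the 7
ordered columns; a `tau_threshold` argument relaxes this, since no numeric
criterion is canonical).

## Anchoring and enrichment

Overlap-DEG profiles (per-concentration mean log2FC) are clustered with
Ward linkage on Euclidean distance; the cut is user-specified (default
k = 6), and labels are ordered by cluster-mean response for determinism.
Gene-set over-representation is the one-sided hypergeometric upper tail
against user-supplied GMT sets restricted to the analysis background, BH
across terms — term databases are data, not code. The anchor report puts a
module's median (and mean — the two differ under skew, so both are
printed) expression BMC next to the phenotype BMC, reports their ratio,
and whether the phenotype BMC falls inside the module's [BMDL, BMDU].

## Pipeline, seeding, formats

Stages run dge → trend/BMC → network → LOCO → phenotype → anchoring. Every
stage derives its substream seed as SHA-256(global seed, stage name) mod
2³¹, so inserting a stage never perturbs another's stream; a rerun with
the same config is bit-identical (verified by output hashing in the
manifest). Tabular outputs are TSV with `#`-prefixed metadata headers
(config hash, seed); networks also export GraphML and SIF for Cytoscape.
The config hash covers analysis parameters only, not file paths.

## Problem sizes in the test suite

Calibration suites use 2,000 null genes (1,000 permutations for the
Williams test); network recovery uses 100–300 genes with 25–100 trees;
LOCO enrichment pools a 2×2 table over 5 seeds at 30 genes × 60 trees;
phenotype parameter recovery uses 50–120 simulated screens; bootstrap
coverage uses 30 seeded sweeps at 80 draws. These are the package's
desk-scale defaults for verification; every knob scales up through the
config objects.

## Known limitations

- The DGE stage approximates, not reproduces, DESeq2; printed DEG counts
  from the original experiment require the deposited raw data.
- BMDL/BMDU are bootstrap percentiles, not BMDS profile bounds; coverage
  is ~90%, not exact.
- Median-of-ratios normalization assumes most genes unregulated; synthetic
  configs with a majority of responders show composition bias (visible as
  spurious trends in null genes).
- The LOCO "progressive loss" criterion (τ = 1) is strict; with noisy
  weights few edges qualify at small scale.
- The generator does not simulate reads, alignment, plate effects, or
  per-animal longitudinal outcomes.
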