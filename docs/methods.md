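# Methods

## The scoring problem

A risk model for newly diagnosed multiple myeloma emits one continuous score
per patient (higher = higher risk), possibly with a binary high-risk call.
"High risk" is defined as disease progression or death before 18 months from
diagnosis, on progression-free survival (PFS). Evaluation must cope with
right censoring, with the arbitrariness of any single time threshold, and
with pooling cohorts of very different size and assay platform. The package
scores models the way a blinded multi-cohort challenge does, and then mines
cross-cohort univariate gene effects with the same machinery.

## High-risk labels and evaluability

At threshold t, a patient is labeled high-risk (1) if they progressed or died
before t, low-risk (0) if followed past t (event or censored), and
*not evaluable* if censored before t: such a patient carries no information
about the binary outcome at t and is excluded at that threshold. No
imputation or censoring-distribution weighting is attempted (inverse-
probability-weighted time-dependent ROC estimators are deliberately out of
scope); exclusion is the simplest defensible rule and is applied
consistently everywhere a high-risk count or label is needed.

## iAUC, wiAUC, wBAC

The per-threshold metric is the Mann–Whitney AUC over evaluable patients
(midranks; ties count ½). The primary metric integrates it over a sliding
threshold grid: weekly steps from 12 to 24 months, centered on 18, with one
week = 7/30.4375 months (53 thresholds; the month↔week convention is
configurable). The iAUC is the unweighted arithmetic mean of the defined
per-threshold AUCs — on a uniform grid this differs from a trapezoid rule
only in endpoint weights, which is negligible; undefined thresholds (an
empty outcome class) are skipped and counted. The iAUC is invariant under
any strictly monotone transform of the scores.

Per-cohort iAUCs combine into wiAUC with weights n², where n is the cohort's
count of evaluable high-risk patients at the 18-month center. Squared-count
weighting lets large studies weigh more without letting the largest one
dominate outright; counting at the center threshold is one fixed definition
reused everywhere (weights, Stouffer weights, dichotomization prevalence).
Balanced accuracy (sensitivity + specificity)/2 is computed at the center
threshold from supplied binary calls, or from scores dichotomized at the
observed high-risk prevalence (ties at the cut broken by patient id); the
same n² weighting gives wBAC. An integrated-BAC reading across the grid is
not the default because the label prevalence — and hence the meaning of a
fixed call set — changes with the threshold.

## Bootstrap, Bayes factor, ranking

Model uncertainty is assessed by a paired bootstrap: patients are resampled
with replacement within each cohort, with one shared index draw across all
models per replicate, so per-replicate differences between models reflect the
models and not resampling noise. A replicate with zero high-risk weight in
every cohort is redrawn (capped at 100 retries). The Bayes factor K of the
top model over a contender is the paired win ratio
\#{top > other}/\#{top < other} over B = 1000 replicates, with exact per-draw
ties split evenly between the two counts — so K(x, x) = 1 and
K(a, b)·K(b, a) = 1 without ties. Models with K < 3 (strict) are statistical
ties of the top; among the tied set the highest wBAC takes final rank 1, the
rest follow in wiAUC order, and residual ties break by model id, making the
leaderboard fully deterministic.

## Cox fitting

The partial likelihood is maximized by Newton–Raphson with step-halving on
features standardized to zero mean and unit variance (coefficients are
reported per SD with the standardization constants carried in the model, so
predictions are invariant to affine feature rescaling). Breslow tie handling
is the default — it is exactly specified, fast, and invariant under patient
duplication — with Efron behind a flag. Convergence is declared at a relative
log-likelihood change below 1e-9 (cap 100 iterations); a singular information
matrix, iteration-cap exhaustion, or standardized coefficients exceeding 25
(monotone likelihood / perfect separation) raise an explicit error with
diagnostics rather than returning a huge finite estimate. ISS enters as
numeric 1–3 (the parsimonious encoding that keeps the four-feature model at
four parameters); expression features are standardized within each cohort
before pooling, since pooling microarray-like and RNA-seq-like cohorts is
only coherent after within-cohort scaling — patient ranking within a cohort
is unaffected by construction.

## Concordance, z, meta-z

Harrell's C is computed over comparable pairs — the earlier time must be an
event; tied event times are not comparable; a patient censored at another's
event time is taken to survive longer — oriented so that risk-increasing
values give C > 0.5. The effect size is z = (C − ½)/SE(C), with SE from the
Hájek-projection (Noether-type) linearization of the ratio statistic:
Var(C) = Σᵢuᵢ²/N² where uᵢ sums the pair residuals (sᵢⱼ − C) over the
comparable pairs containing subject i. This asymptotic estimate was chosen
over bootstrap or jackknife for speed across thousands of genes; the test
suite validates it three ways (null Monte-Carlo z SD within [0.9, 1.1] at
n = 250–300, delete-one jackknife agreement on a small fixture, and
brute-force pair enumeration for C itself). Per-cohort z values combine by
Stouffer's method, meta-z = Σwᵢzᵢ/√(Σwᵢ²), with weights equal to the
per-cohort high-risk count at 18 months (PFS-defined, even when C is
computed on OS) or all ones; genes are ranked by meta-z descending with ties
broken by gene id. Expression is normalized within cohort before C — z-score
by default (monotone per gene, so C is unchanged but the scale is fixed for
reuse), with rank and column-quantile modes available since the choice of
normalization is a genuine degree of freedom in cross-platform rankings.

The genome-wide batch kernel evaluates all genes against one cohort's shared
comparable-pair mask in float32 (float64 for the single-vector API, which
matches exhaustive enumeration to 1e-12); the float32 error (~1e-4) is far
below anything that could reorder a ranking.

## The synthetic generator

The generator emulates an eight-study resource: default cohort sizes
(147, 559, 636, 282, 241, 215, 74, 293), ISS probabilities (0.30, 0.30,
0.40), age ~ N(65, 10²) years clipped to [25, 95], t(4;14) prevalence 0.15.
Expression is normal on the log scale with per-gene means N(8, 1.5²) and SDs
U(0.5, 1.5) drawn once per challenge, plus a per-cohort per-gene location
shift N(0, 0.3²) standing in for batch/platform differences. The designated
MMSET-like gene is shifted +2 log-units in translocation carriers; in
non-carriers it shares a latent factor with the PHF19-like gene tuned to a
population correlation of 0.42. Progression time follows a Weibull
proportional-hazards law (scale 30 months, shape 1.2; marginal median PFS
≈ 14–19 months across cohorts, inside the 11–26-month span the cohort
profile targets) with linear predictor
0.25·(age−65)/10 + 0.35·(ISS−2) + Σ βg·(standardized expression), default
planted effects 0.7/SD on the PHF19-like gene and 0.3/SD on the MMSET-like
gene. Overall survival is progression time plus an independent Exp(12
months) increment, so PFS events always outnumber OS events. Censoring is
uniform on (0, c_max) with c_max solved by root-finding so the expected
censored fraction equals the 20% target (the realized fraction is calibrated
to ±0.05 at n ≥ 500). All draws descend from one master seed through
per-cohort `SeedSequence` spawn keys, so cohorts are independent,
order-insensitive, and bit-reproducible.

What the generator does *not* model: RNA-seq count noise or separate
platform dialects (a single continuous log scale), copy-number or
translocation calling, batch-correction artifacts, missing clinical data,
informative censoring, or treatment effects. Tests passing on this testbed
therefore demonstrate that the *machinery* is correct and calibrated — not
that any particular gene is prognostic in real patients.

## Problem sizes in the tests

The acceptance-style tests run the machinery at the scale the properties
are stated at: null calibration and planted-gene recovery use 4 cohorts ×
250 patients × 1000 genes over 20 seeds; model-ordering uses 20 replicate
challenges of 6 × 250 patients with 50 genes and B = 200 bootstrap draws;
the acceptance script runs the full default profile (2447 patients, 1000
genes, B = 1000). The Monte-Carlo acceptance checks read their thresholds
(e.g. "first in ≥ 19/20 seeds") as exact counts at the stated replication;
single-number calibration bands (wiAUC of random scores within 0.5 ± 0.03)
are checked on the mean across the stated seeds, with a wider per-seed guard,
since one seed's wiAUC at these cohort sizes has sampling SD ≈ 0.02.

## Known limitations

- The Noether variance slightly disagrees with the jackknife at very small n
  (≈15–20% at n = 10); both are asymptotic devices and converge quickly.
- BAC at the center threshold depends on the dichotomization rule when
  models supply no binary calls; the prevalence-matched rule is one
  documented choice, not the only one.
- The evaluation excludes censored-before-threshold patients rather than
  reweighting survivors, so per-threshold AUCs are estimated on a
  threshold-dependent subpopulation; under heavy early censoring this can
  bias AUCs relative to IPCW-style estimators.
- Signature content is user-supplied: published myeloma signatures (70- and
  92-gene lists) are represented by generic scoring rules, not by their
  original coefficients.
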