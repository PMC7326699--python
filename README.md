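# mmrisk

Benchmarking machinery for prognostic models of high-risk multiple myeloma,
built around a fully synthetic multi-cohort testbed. The package answers a
practical question in biostatistics: when many groups submit survival-risk
models for newly diagnosed myeloma patients, how do you score them fairly
across heterogeneous expression cohorts, declare statistical ties, and mine
the models' shared signal for individual prognostic genes?

It provides four pieces, each usable on its own:

1. **Synthetic cohorts** (`mmrisk.simulate`) — multi-study survival +
   expression data from a Weibull proportional-hazards generator with planted
   prognostic genes, ISS/age effects, a t(4;14)-driven *MMSET*-like expression
   shift, and a *PHF19*-like gene coupled to it only in translocation-negative
   patients. Every downstream stage is testable against this known truth
   without any external download.
2. **Risk models** (`mmrisk.signatures`, `mmrisk.cox`) — an age/ISS clinical
   baseline, generic gene-signature scorers (mean-difference or weighted-sum
   over user-supplied gene lists), signature+clinical extensions, and the
   parsimonious four-feature Cox model (age, ISS, *PHF19*, *MMSET*), all on a
   hand-rolled Newton–Raphson partial-likelihood fitter with Breslow ties.
3. **Challenge scoring** (`mmrisk.evaluate`) — high-risk labeling
   (progression or death before 18 months), Mann–Whitney AUC on a weekly
   sliding 12–24-month threshold grid, integrated AUC (iAUC), cross-cohort
   weighting by the squared high-risk patient count (wiAUC / wBAC), paired
   bootstrap, Bayes-factor tie detection (K < 3 = statistical tie), and
   deterministic leaderboard ranking with wBAC as the tie-breaker.
4. **Gene meta-ranking** (`mmrisk.metarank`) — per-cohort Harrell concordance
   index per gene, standardized effect size z = (C − ½)/SE(C) with a
   Noether-type U-statistic variance, weighted Stouffer combination
   meta-z = Σwᵢzᵢ/√(Σwᵢ²), genome-wide ranking, and the t(4;14)
   subgroup-correlation analysis.

`mmrisk.pipeline` ties the stages into one reproducible, leakage-guarded run
(train on training cohorts, score on held-out cohorts only), with a `mmrisk`
CLI (`simulate`, `score`, `rank-genes`, `run`).

## Worked example

The numbered scripts under `analysis/` walk the full study on the default
eight-cohort synthetic challenge (cohort sizes 74–636, ISS ≈ 30/30/40%,
median PFS 13.6–18.8 months, ~20% censoring; four cohorts train, four are
held out). Running

```bash
python analysis/03_score_challenge.py --seed 1
```

prints the leaderboard

```
 final_rank     model_id    wiauc     wbac  bayes_factor_vs_top  tied_with_top
          1 four_feature 0.779314 0.688664             1.000000           True
          2     baseline 0.619258 0.584143                  inf          False
          3        noise 0.525732 0.521020                  inf          False
```

The four-feature Cox model (age, ISS, *PHF19*, *MMSET*) reaches wiAUC 0.779
on the 823 held-out patients versus 0.619 for age+ISS alone — the planted
expression signal is real and recoverable — while the pure-noise competitor
sits at chance and is excluded from the tied set by its infinite Bayes
factor. `analysis/04_rank_genes.py` then reproduces the gene-mining result:

```
PHF19 (planted log HR 0.7/SD) ranks 1 of 1000 on PFS (meta-z 25.9) and 1 on
OS; MMSET (0.3/SD, plus its t(4;14) shift and PHF19 coupling) ranks 2.
```

and `analysis/05_subgroup_correlation.py` recovers the planted subgroup
pattern (cohort C02, n = 636): *MMSET*–*PHF19* r = 0.427 in
t(4;14)-negative patients versus r = 0.041 in carriers.

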