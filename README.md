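# rarephen

Two-stage statistical testing for **rare-event categorical phenotypes** in
small treatment cohorts — the setting of high-throughput mouse knockout
screens, where each line contributes roughly seven knockout males and seven
females, hundreds of binary traits ("abnormal" / "as expected") are scored
against a large shared wild-type pool, and wild-type abnormality rates are
typically well below 1%.

The package answers two questions per line × zygosity × trait data set:

1. **Stage 1 — is there a genotype effect?**  Default test: the exact
   one-sided Cochran–Mantel–Haenszel test stratified by sex with mid-*P*
   correction (MH_mid).  Conditional on all margins, the total knockout
   event count *T* follows the convolution of two central hypergeometric
   laws and `p_mid = P(T > t_obs) + ½·P(T = t_obs)`.
2. **Stage 2 — does the effect differ between the sexes?**  Default test
   (run only on stage-1 significant sets): Firth bias-reduced logistic
   regression on the knockout animals alone (LR_KO), a penalized
   likelihood-ratio test of `Y ~ sex` against a constant model.  The Firth
   penalty `l*(β) = l(β) + ½ log det I(β)` keeps estimates finite under the
   complete separation that rare events routinely produce; the constrained
   fit keeps the full model's penalty and the statistic is referred to
   χ²(1).

Because the tests are discrete, many small tables cannot reach significance
at all.  Before testing, the pipeline computes **α\*** — the smallest
*P*-value attainable given the fixed margins — and drops hypotheses with
α\* above the threshold.  The decision uses margins only, never outcomes,
so it shrinks the multiple-testing family without biasing FDR control.
FDR is then controlled per stage either globally (Benjamini–Hochberg) or
on average across gene × zygosity families (Benjamini–Bogomolov two-step).
Effect sizes are reported as differences in abnormality proportions with
Newcombe method-10 intervals (square-and-add of Wilson score bounds) —
odds ratios are useless here because zero cells are the norm.

Also included: the other candidate tests (Fisher per sex with doubled
minimum, FE_mid, Firth LR_G / LR_I, Zelen's exact homogeneity test,
knockout-only mid-*P* Fisher), a Firth-LRT batch-variation screen for
control data, and a simulation suite (global-null type-I error, stage-2
error under a pure main effect, and power grids) that doubles as the
fixture generator.

## Worked example

Generate a small synthetic screen (4 lines × 5 traits; the first line
carries a +0.6 abnormality-probability effect in males only) and analyse
it with the recommended configuration (α\* filters, restriction of stage 2
to stage-1 hits, BH at 5% / 20%):

```sh
rarephen make-fixtures --seed 1 --out fix.tsv
rarephen analyze --input fix.tsv --approach 6 --output report.tsv
```

The log accounts for every data set at every step:

```
rarephen: n_input = 20
rarephen: n_filtered_stage1 = 2      # alpha* >= 0.05: can never be significant
rarephen: n_tested_stage1 = 18
rarephen: n_called_stage1 = 5        # the five dimorphic-line traits
rarephen: n_candidates_stage2 = 5
rarephen: n_tested_stage2 = 5
rarephen: n_called_stage2 = 5
```

The report carries, per data set, both stages' p-values, α\*, BH-adjusted
p-values, calls, and effects.  For the called rows:

```
        dataset_id     stage1_p  stage2_p  stage2_p_adj  ko_diff_estimate  ko_diff_lower  ko_diff_upper
line00:hom:trait00 3.357815e-08  0.022993      0.022993          0.571429       0.093337       0.841780
line00:hom:trait01 6.247288e-12  0.006197      0.010329          0.714286       0.212464       0.917781
line00:hom:trait04 1.893431e-05  0.001215      0.006073          0.857143       0.344649       0.974320
```

`ko_diff_estimate = 0.571` means male knockouts were 57 percentage points
more often abnormal than female knockouts (e.g. 4/7 vs 0/7), with the 95%
Newcombe interval [0.09, 0.84].

The attainability grid explains why a fixed *P* < 0.0001 rule can never
call sexual dimorphism with seven knockouts per sex — even complete
penetrance in one sex only reaches 0.00013:

```sh
$ rarephen alpha-star --n-male 7 --n-female 7
penetrance_pct  n_per_sex  abnormalities  alpha_star
14.3            7          1              0.44059
28.6            7          2              0.18407
42.9            7          3              0.06974
57.1            7          4              0.02299
71.4            7          5              0.00620
85.7            7          6              0.00121
100.0           7          7              0.00013
```

Simulation subcommands: `simulate-null`, `simulate-stage2-error`,
`simulate-power` (all seeded, deterministic), plus `batch-screen` for
control batch variation.

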