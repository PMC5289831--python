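# Methods

This note documents the statistical models implemented in `rarephen`, the
conventions chosen where several were defensible, what the synthetic-data
generator does and does not emulate, and known limitations.

## Setting and data model

The unit of analysis is one wild-type-vs-knockout comparison on one binary
trait, summarized as a 2×2×2 table (sex × group × outcome).  All tests are
functions of these eight counts; per-animal input is aggregated on read.
Control animals are pooled across collection batches: the batch screen
(below) is provided to verify that assumption on a given control set, and
the package otherwise treats batch-to-batch and litter variation as
negligible for categorical traits.

## Stage-1 tests (genotype effect)

* **FE / FE_mid** — per-sex one-sided Fisher's exact test (alternative:
  knockout rate higher), the smaller of the two p-values doubled and capped
  at 1.  The mid-*P* variant replaces the observed atom's mass by half of
  it: `p_mid = P(T > t) + ½ P(T = t)`.
* **MH_mid** — exact conditional stratified Mantel–Haenszel: given all
  margins, the total knockout event count is the convolution of the two
  per-sex central hypergeometric laws; one-sided upper tail, mid-*P* by
  default.  The exact conditional form (rather than the asymptotic
  chi-square) is required because mid-*P* is defined on the discrete
  support.
* **LR_G** — Firth penalized LRT of `Y ~ sex` against
  `Y ~ genotype + sex + genotype:sex` (df = 2).

Stage-1 tests are one-sided toward more abnormalities in knockouts — the
safe direction when screening rare traits for an increase in "abnormal";
a two-sided flag exists on the Fisher tests.

## Stage-2 tests (sexual dimorphism)

* **LR_KO** (default) — Firth penalized LRT of `Y ~ sex` vs constant on
  knockout animals only (df = 1).  It retains power when wild-type events
  are absent, which is the common case.
* **LR_I** — Firth penalized LRT of `Y ~ sex + genotype` vs
  `+ genotype:sex` (df = 1).
* **Zelen** — exact test of odds-ratio homogeneity: conditional on all
  margins and on the total knockout event count *T*, the male knockout
  count has law `f(a₁) ∝ h_M(a₁)·h_F(T−a₁)`; two-sided by the
  point-probability method, mid-*P* by default.
* **FE_KO** — two-sided mid-*P* Fisher on the knockout-only sex × outcome
  table.

When wild-type events are absent, Zelen's conditional support collapses to
a single point (p = 1 always) and LR_I's smallest achievable p exceeds
0.05, so neither can ever detect an interaction in that regime — a
structural property the test suite verifies exactly.

## Firth engine conventions

The penalized log-likelihood is `l*(β) = l(β) + ½ log det I(β)` with
`I(β) = X'WX`, maximized by Newton iterations with step-halving from
β = 0; convergence requires the penalized score and the step both ≤ 1e-8,
with at most 50 iterations.  Aggregated (weighted-row) designs are
supported and match expanded per-observation fits.

For the LRT, the constrained fit fixes the tested coefficients at zero but
**keeps the full design's penalty** (constrained columns still enter the
Fisher information).  This convention was calibrated against the published
minimum attainable stage-2 p-values for 7+7 cohorts and reproduces all
seven (0.44059, 0.18407, 0.0697, 0.02299, 0.0062, 0.00121, 0.00013); a
`separate-null` mode (each model penalized by its own information) is
available but non-default.  Two consequences of the shared-penalty
convention are handled explicitly: the statistic can be marginally
negative (truncated to 0, p = 1), and it is not exactly zero on completely
uninformative data (e.g. all outcomes 0), only negligibly small.
Non-converged fits yield p = 1 with a flag rather than aborting a batch.
Coding: female and wild-type are reference levels; sex, genotype and their
product enter as 0/1 indicators.  LRT p-values are invariant to which sex
is coded 1 (tested).

## Attainability (α*) filtering

For a discrete test, α* is the minimum p over all tables sharing the
observed margins.  For MH_mid this is the tail value at the most extreme
attainable total; it is computed from the convolved conditional law.  For
LR_KO, α* depends on (n_male, n_female, total knockout abnormalities) and
is found by enumerating every allocation of the abnormal count between the
sexes — not just the extreme split, which need not be optimal for unequal
cohort sizes.  A single attainable allocation gives α* = 1 by convention.
Filtering compares α* to a threshold (default 0.05 at both stages; the
stage-2 threshold mirrors stage 1 as a design choice) and never consults
observed allocations, which preserves the validity of downstream FDR
control.  Degenerate-support conventions: one-sided tests report p = 1
(standard) / 0.5 (mid); the two-sided knockout-only tests report p = 1.
Such data sets are removed by the filter in any full pipeline run, so the
convention never influences calls.

## Multiplicity

BH is the standard step-up procedure (adjusted p-values via the monotone
cummin transform).  The within-family procedure controls an average FDR
over gene × zygosity families: step 1 runs BH at level q within every
family and counts the R families with ≥ 1 rejection; step 2 re-runs
within-family BH at level R·q/m inside the selected families only.
Families with no step-1 rejection are never re-tested.  Ties in p-values
are broken by dataset id for reporting stability; the rejection sets are
unaffected.  Stage-2 FDR is computed over the stage-2 candidate set only,
and jointly across lines (a per-screen scope is a configuration choice).

## Effect sizes

Differences in abnormality proportions with Newcombe method-10 intervals:
with per-group Wilson score bounds (l₁,u₁), (l₂,u₂) and d = p̂₁ − p̂₂,

    lower = d − √((p̂₁−l₁)² + (u₂−p̂₂)²),  upper = d + √((u₁−p̂₁)² + (p̂₂−l₂)²).

The sex-averaged genotype effect averages the two per-sex KO−WT
differences and takes the conservative hull (min lower, max upper) of the
per-sex intervals.  The stage-2 effect is the male−female difference among
knockouts.  z is the normal quantile at (1+level)/2, level 0.95 by
default.  No selective-inference inflation of intervals is applied;
reports flag that selection occurred instead.

## Numerical choices

Hypergeometric probabilities are computed in log space (log-gamma) and
normalized; tails are accumulated from the smaller side; conditional laws
are checked to sum to 1 within 1e-12.  Two-sided point-probability tails
include outcomes within relative tolerance 1e-10 of the observed
probability, a floating-point-stable tie rule.  Count-level test results
are memoized, which is what makes the resampling studies fast: a
simulation touches only as many distinct margin vectors as the data allow.

## Simulation framework

`gen_control` emulates a two-year weekly screen: 104 cohorts of 7 animals
per sex (728 per sex per trait), outcomes drawn independently per
animal/trait/sex from per-trait abnormality rates.  The default rate panel
is 100 rates log-spaced over 1e-5–0.05, matching the observed rare-event
range of real control data (82% of real traits sit below 1%); the real
screens' empirical rate sets are not redistributable, so a deterministic
panel spanning the same range stands in for them.

* **Global-null study** — 7+7 animals are relabeled knockout without
  replacement each iteration (outcomes kept, so the null holds exactly);
  by default the same animals are relabeled across all traits, mirroring a
  real cohort assayed on every trait (an independent-draw variant is a
  flag).  Rejection fractions are tallied per method × threshold × trait
  and overall.
* **Stage-2 error with a genotype effect** — knockouts of both sexes get
  abnormality probability min(1, baseline + effect): a pure main effect,
  so stage-2 rejections are false calls.  Effects are additive on the
  probability scale (an odds-scale reading is impossible for the grid's
  large effects against baseline 0.05); knockout outcomes are drawn fresh
  at the shifted rate while the sampled animals leave the wild-type pool.
* **Power grids** — one pre-registered sex (male by default; results are
  sex-symmetric) receives baseline + main + interaction, the other
  baseline + main.  All methods are evaluated on the same draws, so
  power comparisons (e.g. FE_mid ≥ FE, the stage-1 filter only reducing
  stage-2 power) are paired and exact where the rejection regions nest.

Study sizes: the reference design uses 15,000 iterations; the package's
tests and acceptance runs use 500–1,000 iterations with fixed seeds, which
resolves rejection fractions to a Monte-Carlo SE of ~0.5 percentage points
— sufficient for the conservatism and ordering checks made of them.  All
randomness derives from one integer seed; per-cell substreams are spawned
deterministically, so equal seeds give byte-identical tables.

What the generator does **not** emulate: batch, litter and cage structure
(outcomes are exchangeable within trait × sex), correlation between traits
beyond the shared resampling draw, drifting control rates over time, and
missingness.  Passing simulations therefore demonstrate correctness of the
statistical machinery under the stated design, not robustness to those
real-data features.

## Pipeline and configuration

The recommended configuration (default) is: MH_mid with α* filter at 0.05
→ BH at 5% → restrict stage 2 to stage-1 hits → LR_KO α* filter → LR_KO →
BH at 20%.  Ten numbered approach presets reproduce the filter/FDR-scope/
level matrix used to compare strategies; a legacy mode replaces FDR
control with a fixed threshold (historically 1e-4), under which no 7+7
data set can ever be called dimorphic since the minimum attainable stage-2
p is 0.000126.  Every input data set appears in the report exactly once
with an explicit disposition (filtered / tested / called / error), and the
filter accounting is logged.

## Batch screen

For control data with ≥ 2 batches, each trait gets a Firth penalized LRT
of `Y ~ sex + batch` vs `Y ~ sex` (df = batches − 1), BH-adjusted at 5%.
Zero-event traits are reported with p = 1 and flagged uninformative.

## Known limitations

Two strata (sexes) only; no profile-likelihood or Wald intervals for Firth
coefficients; no odds-ratio effect measures (deliberate: rare events); no
online FDR for accumulating screens; no random effects for batch/litter;
stage-2 validity after stage-1 selection relies on the conditional
structure of the recommended MH_mid → knockout-only pairing and was
checked by simulation for the others, not proven.
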