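# Methods

## Statistical model

The pooling layer assumes a fixed-effects meta-analytic model: every
study estimates one common standardized mean difference δ, and study
`j`'s estimate `d_j` is normal around δ with known sampling variance
`v_j = se_j²`. Inverse-variance weights `w_j = 1/v_j` give the pooled
estimate `θ̂ = Σ w_j d_j / Σ w_j` with standard error `(Σ w_j)^{-1/2}`
and a normal-quantile confidence interval (default level 0.95, the
convention for meta-analytic displays). Between-study heterogeneity
(random effects, Q/I²/τ²) is deliberately out of scope; the pooling
entry point carries a `method` tag so a random-effects extension is
additive rather than a signature change.

A `StudyEffect` may be constructed from exactly one of `se`, `variance`
or raw `weight` — real effect-size tables vary — and the others are
derived.

## CRT SMD sampling variance

Studies are modelled as two-arm cluster-randomized trials with equal
cluster size `n`, arm totals `N_T`, `N_C` (`N = N_T + N_C`) and
intraclass correlation ρ. For the SMD standardized by the total
(within- plus between-cluster) variance, the large-sample variance is

    v = (N_T + N_C)/(N_T · N_C) · (1 + (n − 1)ρ) + δ²/(2h),

    h = B²/A,  B = (N − 2) − 2(n − 1)ρ,
    A = (N − 2)(1 − ρ)² + n(N − 2n)ρ² + 2(N − 2n)ρ(1 − ρ).

The first term is the usual two-sample mean-difference variance times
the design effect `1 + (n − 1)ρ`; `h` is the effective degrees of
freedom of the variance estimate. At ρ = 0 the expression reduces
exactly to the non-clustered SMD variance
`(N_T + N_C)/(N_T N_C) + δ²/(2(N − 2))`, which is pinned as a
regression test at 1e-12, and the variance is non-decreasing in ρ over
the parameter grids we test. Inputs are validated: ρ ∈ [0, 1), cluster
size dividing each arm total (no silent rounding), and `B > 0` so the
degrees of freedom stay positive.

## Data generator

`simulate_meta` emulates meta-analyses of education CRTs:

1. (clusters per arm `m`, students per cluster `n`) are drawn from a
   correlated bivariate lognormal, rounded half-up, floored at 2 and 2
   — the floor keeps every CRT variance finite. Defaults: log-means
   `log 10` and `log 22` (median ≈ 10 clusters/arm, ≈ 22
   students/cluster), log-sd 0.5 on both margins, log-scale
   correlation 0.2. These were chosen once as typical of published
   education trials (cluster counts in the single digits to a few
   dozen, classroom-sized clusters, right-skewed with order-of-
   magnitude spread); they are configuration, not estimates.
2. `se_j` is the square root of the CRT variance at the configured ρ.
   The intraclass correlation is a **required** parameter — it drives
   every standard error and defensible values vary by outcome — and
   the package's own scripts use ρ = 0.2, a typical value reported for
   academic-achievement outcomes.
3. `d_j ~ N(δ, se_j²)` with δ = 0.15 by default, a small effect on the
   education scale. Effects are unbiased by construction, so the grand
   mean of pooled estimates over replicate datasets recovers δ and the
   nominal CI coverage is attained — both verified at 2000 replicates
   against Monte-Carlo error.

One seeded generator per call draws sizes first, then effects, so the
size draws can be reproduced independently. Equal arm sizes and one
effect per study are assumed throughout.

What the generator does *not* emulate: between-study heterogeneity
(τ² = 0), unequal arms, unequal cluster sizes within a study,
non-normal effect distributions, publication bias, or covariates.
Passing tests therefore certify the machinery under a correctly
specified fixed-effects world, not robustness to real-data violations.

## MARC layout choices

Where the visual design was genuinely open, the package fixes it as
follows:

- Dot **area** (not radius) is proportional to relative weight —
  perceptual magnitude judgments track area; the largest study gets a
  fixed 300 pt² so plots are comparable across k.
- Summary cloud: G = 50 dots by default, placed at the `i/(G+1)`
  quantiles of the pooled sampling distribution **truncated to the
  CI**. Truncation guarantees every dot lies inside the interval (the
  spread of dots is exactly the interval) while keeping density
  maximal at the estimate; a symmetric CI yields a dot multiset
  symmetric about the estimate to floating-point precision. Vertical
  offsets come from a deterministic greedy beeswarm packing (place
  each dot, in order of distance from the median, at the smallest
  non-overlapping offset; ties break upward).
- v2 panes: study pane range `[0, 1.15 × max relative weight]`
  (15% headroom), pane height ratio 1:3 (summary:studies). The cloud's
  coordinates never depend on the study pane, which is the point of
  v2.
- Color classes by sign of the SMD only — colorblind-safe red for
  decreases, blue for increases, neutral grey at exactly zero.
- Ties in weight rank are broken by input order; hover text defaults
  to SMD at 2 decimals and relative weight at one decimal percent
  (both configurable).
- Because a study's label can let a viewer match the same dataset
  across chart types, `relabel_studies` offers a seeded permutation of
  study IDs.

Forest and bar layouts are intentionally conventional (squares with CI
whiskers and a summary diamond spanning the pooled CI exactly; bars of
length |SMD| with a student-count hover) so they can serve as
comparators. Forest/bar heights grow one row per study; the MARC
y-axis is continuous, and layout metadata records this difference.

## Experiment toolkit

The 16 treatment combinations (4 visualization types × k ∈ {10, 20,
50, 100}) are confounded into 4 blocks of 4. Coding both factors as
GF(4) elements, pattern λ assigns combination (a, b) to block
`a + λ·b` (field addition = XOR). Every non-zero λ is a unit of the
field, so each block contains each visualization type exactly once and
each k exactly once, and λ = 1, 2, 3 give three distinct partitions.
Custom patterns may be plugged in; the block invariants (partition of
all 16; every visualization once per block) are always validated.
Participants are dealt round-robin over a seeded permutation of the 12
survey blocks (imbalance ≤ 1 for any n), with per-participant
presentation order randomized. At n = 160 this affords 10 complete
replicates of the 16-run design, counting one replicate per 16
participants.

Scoring: items Q1–Q7 score 0/1 (maximum 7); Q8 is exploratory and
never counted. The slider item Q5 on [−0.5, 0.5] is correct within a
tolerance of ±0.05 (one slider tick; configurable); out-of-range or
non-numeric slider answers are flagged invalid and scored 0.
Participants failing the attention check or finishing in under 3
minutes are excluded with explicit reasons.

Analysis delegates standard machinery: the two-factor ANOVA with
interaction uses statsmodels OLS with Type II sums of squares (suited
to the mild imbalance the confounding induces). Tukey–Kramer pairwise
comparisons over the 6 visualization pairs are computed in-package
from the interaction model's residual mean square — reporting the raw
mean difference, the standardized difference `diff/√MSE`, the
studentized-range p-value and simultaneous CIs — and are cross-checked
in tests against `pairwise_tukeyhsd` and, in the two-group case,
against the exact pooled-t identity `q = √2·|t|`. Because the
interaction model is the cell-means model, the residual mean square is
also computed directly from cell means; simulation loops use this fast
path with a precomputed critical value (the studentized-range integral
is the cost), and a test pins the two paths to identical output. Under
a zero-effect simulation the family-wise error of the procedure sits
at the nominal 5% within Monte-Carlo error (1000 replicates).

Page durations are analyzed with a two-level linear mixed model:
random intercept per participant, fixed effects for visualization type
(dummy coded against a configurable reference), the centered number of
studies, and their interactions; with centering, the intercept is the
reference visualization's mean duration at the average k. Singular
fits (random-intercept variance at the boundary) are flagged, never
dropped; in the zero-between-person-variance limit the fixed effects
match the ordinary-regression oracle.

The respondent simulator draws each answer correct independently with
a per-visualization probability and generates durations from exactly
the mixed model above, so parameter-recovery tests (e.g. a +30 s
effect recovered within its CI in ≥ 90% of replicates at n = 200) test
the estimator under its own generating model.

## Problem sizes and numerical choices

Test and script problem sizes are chosen to make Monte-Carlo bounds
meaningful at interactive runtimes: 2000 replicate meta-analyses for
unbiasedness and coverage (3 MC standard errors ≈ 0.003 on the mean),
1000 replicates for Tukey calibration (±0.021 at 3 MC SEs), 1000
random datasets for the 1e-12 oracle-agreement sweep, and 10,000 draws
for lognormal moment checks. Exact identities (weights, pooling,
ρ = 0 reduction, layout geometry) are asserted at 1e-9–1e-12;
comparisons against iterative fits (mixed models) use looser
tolerances reflecting optimizer precision. All randomness flows from
explicit integer seeds; there is no hidden global RNG state.

## Known limitations

- Fixed-effects only; no heterogeneity estimation or generation.
- One effect size per study; no moderator or subgroup structure.
- The interactive renderer emits a hand-rolled SVG + tooltip document;
  it is deliberately minimal (hover only — no zoom/pan/legend
  toggling).
- The bar plot conveys weight only through its student-count hover,
  which is the very weakness the MARC design addresses — it is
  included as a faithful comparator, not a recommendation.
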