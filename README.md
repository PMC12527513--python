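# marcplot

Meta-analyses are read not only by statisticians but by teachers,
clinicians and policy-makers, and the standard display — the forest
plot — leans on conventions (squares sized by weight, CI whiskers,
a summary diamond) that non-researchers routinely misread: the widest
confidence interval draws the most attention to exactly the study that
deserves the least. `marcplot` implements the **Meta-Analytic Rain
Cloud (MARC) plot**, an alternative encoding designed for broad
audiences, together with the computation layer needed to drive it and
to evaluate it experimentally.

The package provides:

- **Fixed-effects meta-analysis core** for standardized mean
  differences (SMDs): inverse-variance weights `w_j = 1/se_j²`, pooled
  estimate `θ̂ = Σ w_j d_j / Σ w_j` with `se(θ̂) = (Σ w_j)^{-1/2}`, and
  the sampling variance of an SMD from a **cluster-randomized trial**
  (CRT), whose mean-difference term is inflated by the design effect
  `1 + (n − 1)ρ` for cluster size `n` and intraclass correlation `ρ`.
- **MARC layouts, v1 and v2.** Each study is a dot at
  (SMD, relative weight); dot *area* also encodes relative weight, so
  precise studies sit higher and larger. The pooled effect is drawn as
  a "cloud": a beeswarm of dots at deterministic quantiles of its
  sampling distribution truncated to the confidence interval — a
  frequency-format uncertainty display. v1 puts the cloud on the same
  axis at y = 1.0 (the combined weight); v2 moves it to its own pane so
  that with many studies the small relative weights still spread out
  instead of pooling at the axis.
- **Reference renderers** for the conventional forest plot and the
  horizontal bar plot, with the same layout/render separation.
- **Static (PNG/SVG) and interactive (self-contained HTML with hover
  text) rendering.** Every number in an output file is computed in the
  layout step; renderers only map to pixels.
- **A CRT meta-dataset simulator**: correlated lognormal draws of
  (clusters per arm, students per cluster), CRT standard errors, and
  unbiased normal effect draws `d_j ~ N(δ, v_j)`.
- **A survey-experiment toolkit**: a 4 × 4 confounded factorial design
  generator (visualization type × number of studies, 16 runs aliased
  into 4 blocks under 3 confounding patterns → 12 survey blocks, every
  visualization type once per block), questionnaire scoring (seven 0/1
  items, a slider item with tolerance, exclusion rules), two-factor
  ANOVA with Tukey pairwise comparisons, and a two-level mixed model
  for page durations.

## Worked example

```python
from marcplot import (SimulationConfig, simulate_meta, pool_fixed,
                      marc_layout, render)

cfg = SimulationConfig(k=20, delta=0.15, rho=0.2, seed=42)
ds = simulate_meta(cfg)
pooled = pool_fixed(ds)
print(f"k = {ds.k} studies")
print(f"pooled SMD = {pooled.estimate:.3f} (se {pooled.se:.3f}), "
      f"95% CI [{pooled.ci_low:.3f}, {pooled.ci_high:.3f}]")

layout = marc_layout(ds, pooled, version="v2")
print(f"study pane y-range: [0, {layout.panes[1].y_range[1]:.3f}]")
render(layout, "marc_v2_k20.html")
```

prints

```
k = 20 studies
pooled SMD = 0.163 (se 0.047), 95% CI [0.070, 0.255]
study pane y-range: [0, 0.182]
```

Twenty simulated cluster-randomized trials around a true SMD of 0.15
pool to 0.163 with a CI excluding zero. In the v2 layout the study pane
tops out at 1.15 × the largest relative weight (here 0.182), so the
dots use the full pane instead of crowding near zero; the summary cloud
lives in its own pane above. The HTML file is self-contained — hovering
a dot shows the study ID, its SMD and its relative weight.

The same workflow is available from the shell:

```bash
marcplot simulate --k 20 --rho 0.2 --delta 0.15 --seed 42 --out data.csv
marcplot plot --input data.csv --type marc2 --format html --out marc.html
marcplot design --n 160 --seed 1 --out design.csv
```

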