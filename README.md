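# exclosure

Alpha- and beta-diversity analysis for **paired mammal-exclosure
experiments** — the design in which fenced plots that exclude
medium-to-large herbivores are paired with open control plots and the
seedling/sapling community in each is resurveyed for years.  The package
asks the two questions such experiments are built to answer:

* does excluding herbivores change **local (alpha) diversity** over time —
  richness, Shannon entropy, inverse Simpson — relative to paired controls?
* do exclusion plots become **more similar to one another** (biotic
  homogenization): does multiple-site beta diversity decline under
  exclusion while it holds or rises in controls?

It is written for community ecologists analysing exclosure (or comparable
paired-treatment) survey data, and for methodologists who want a tested,
scriptable implementation of the abundance-based multiple-site
dissimilarity partition with uncertainty.

## What it computes

**Hellinger transformation.** Every metric is computed after the row-wise
map `x_ij -> sqrt(x_ij / Σ_j x_ij)`, which down-weights hyperdominant taxa
and makes abundances compatible with linear methods (a raw-count variant is
available via `transformed=False`).

**Multiple-site Bray–Curtis partition.** For plots *j*, *k* with shared
abundance `A = Σ_s min(x_js, x_ks)` and unique abundances `B`, `C`, sums
over all unordered plot pairs give

```
total    = (Σmin(B,C) + Σmax(B,C)) / (2ΣA + Σmin(B,C) + Σmax(B,C))
balanced = Σmin(B,C) / (ΣA + Σmin(B,C))          # balanced variation
gradient = total − balanced                       # abundance gradients
```

Balanced variation is the abundance analogue of species turnover (species
swap dominance between plots); the abundance gradient is the analogue of
nestedness (one plot a uniformly poorer version of another).  On 0/1 data
the partition reduces exactly to the incidence-based Sørensen /
Simpson-turnover / nestedness family.

**Jackknife uncertainty.** Multiple-site statistics get plot-level
leave-one-out SEs from pseudo-values `p_i = nθ − (n−1)θ_{−i}` and
approximate normal CIs centred on the full-sample estimate.

**Trend models.** Per site and metric:

```
y_ij = β0 + β1·month_ij + β2·exclusion_ij + β3·month_ij·exclusion_ij + b_i + ε_ij
```

with a pair random intercept `b_i ~ N(0, σ²_pairs)` for plot-level alpha
metrics (REML, Wald-normal inference) and plain OLS for the
treatment-level beta summaries.  The interaction **β3** — the difference
in per-month trend between exclusion and control — is the effect size.
Partition components are interpreted only when the total dissimilarity has
a significant interaction (strict p < 0.05).

**Cross-site contrasts.** Site pairs are compared by z-tests on β3
differences, with per-site SEs reconstructed from the reported CIs
(`se = width / (2·1.959964)`), rendered as forest plots.

**Synthetic surveys.** A seeded generator (`simulate_survey`,
`scenario_preset`) reproduces the design — 4 sites × 15 plot pairs × 18
survey occasions over 13 years, site pools of 170–229 taxa, hyperdominant
release, site-specific missing occasions — so the entire pipeline runs and
is tested with no external data.

## Worked example

```python
import exclosure as ex

survey = ex.simulate_survey(ex.scenario_preset("homogenization", seed=42))
alpha  = ex.alpha_table(survey)
beta   = ex.beta_summaries(survey, jackknife=False)

site = "ITA"
fit_rich = ex.fit_alpha_model(alpha[alpha.site == site], "richness")
fit_beta = ex.fit_beta_model(beta[beta.site == site], "total")
print(f"richness interaction {fit_rich.interaction:+.4f}/month  p={fit_rich.p_interaction:.3g}")
print(f"beta     interaction {fit_beta.interaction:+.5f}/month  p={fit_beta.p_interaction:.3g}")
```

prints

```
richness interaction +0.1061/month  p=3.49e-24
beta     interaction -0.00119/month  p=1.33e-12
```

Richness climbs about 0.11 species/month faster in exclusion plots than in
their paired controls, while the multiple-site dissimilarity among
exclusion plots falls about 0.0012/month relative to controls (from 0.60
to 0.37 over 156 months in this run): local diversity up, spatial
heterogeneity down — the signature of biotic homogenization under
defaunation.  The `examples/` scripts walk through each stage
(simulation, alpha, beta + jackknife, models, contrasts, full pipeline),
and the `exclosure` CLI exposes the same stages as subcommands
(`simulate`, `validate`, `alpha`, `beta`, `models`, `contrasts`,
`run-all`).

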