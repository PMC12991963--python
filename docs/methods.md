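# Methods

This note documents the statistical procedures the package implements, the
generative model behind its synthetic surveys, the numerical conventions,
and the design choices made where more than one defensible option existed.

## Analysis pipeline

### Transformation and alpha diversity

All diversity metrics are computed after the Hellinger transformation
`x_ij -> sqrt(x_ij / Σ_j x_ij)`, applied row-wise to each site × occasion
plot-by-species matrix. Rows with a positive total come out with unit
Euclidean norm; all-zero rows (empty plots) map to all-zero rows by
convention and are flagged, never silently dropped.

Richness is the count of species with positive raw abundance and is
therefore transform-invariant. Shannon entropy `−Σ p ln p` (natural log)
and inverse Simpson `1/Σ p²` are computed by default on the transformed
rows renormalized to proportions `p_i = h_i / Σ h_i`; because squaring the
square root halves the weight of dominance, these values differ from the
raw-count indices. Both paths are provided (`transformed=` flag); the
transformed path is the default because the transformation is specified to
precede *every* metric. Empty plots get richness 0, Shannon 0, inverse
Simpson missing with a `degenerate` flag.

### Beta diversity partition

The abundance-based Bray–Curtis dissimilarity among all plots of one
treatment at one site and occasion is computed in its multiple-site form,
accumulating over all unordered plot pairs (j, k) the shared abundance
`A = Σ_s min(x_js, x_ks)` and the unique abundances `B`, `C`:

    total    = (Σmin(B,C) + Σmax(B,C)) / (2ΣA + Σmin(B,C) + Σmax(B,C))
    balanced = Σmin(B,C) / (ΣA + Σmin(B,C))
    gradient = total − balanced

Properties maintained and tested: additivity to 1e−12; exact reduction to
the pairwise formula at n = 2; exact agreement with the incidence-based
Sørensen / Simpson-turnover / nestedness family on 0/1 matrices;
invariance to plot/species permutation and to all-zero species columns.
Empty plots are excluded per occasion (with a log entry) rather than
erroring, because empty seedling plots occur early in regeneration; fewer
than two usable plots yields a flagged missing summary. The Hellinger
transformation is applied to the full site × occasion matrix before
splitting by treatment; the transform is row-wise, so the split order is
immaterial (asserted in tests).

### Jackknife

Uncertainty for multiple-site statistics uses plot-level leave-one-out
pseudo-values `p_i = nθ − (n−1)θ_{−i}`, with
`se = sqrt(Σ(p_i − p̄)² / (n(n−1)))` and CI `θ ± z_{(1+level)/2}·se`. The
CI is centred on the full-sample estimate with a normal multiplier; the
bias-corrected pseudo-value mean is reported alongside and can be used as
the centre via an option. A minimum of three plots is enforced so every
leave-one-out subset remains a valid multiple-site computation.

### Trend models

Per site and metric the model is

    y_ij = β0 + β1·month + β2·exclusion + β3·month·exclusion + b_i + ε_ij

with control as baseline and months on their raw 0-origin scale (no
centering), so β0 and β2 describe conditions at experiment start. For
plot-level alpha metrics the pair random intercept `b_i ~ N(0, σ²_pairs)`
is included and the model is REML-fitted (statsmodels MixedLM, BFGS) with
Wald normal-approximation SEs, CIs and p-values. Beta summaries exist only
at treatment level (one value per treatment × occasion), so they get
ordinary least squares with the same fixed-effect structure; fits are
unweighted by default (a jackknife-inverse-variance option exists but is
off, since the summaries are modelled plainly). Missing occasions are
handled by omission — unbalanced designs are accepted. Singular or
non-converged fits return a flagged `ModelFit` (`converged=False`), never
a silent failure.

Balanced variation and abundance gradients are interpreted only when the
total dissimilarity shows a significant treatment-by-time interaction;
the gate is strict (`p3 < 0.05`, boundary non-interpretable), and gated
components are flagged but still reported. No multiple-testing correction
is applied anywhere, matching the single-test-per-site reporting the
design calls for.

### Cross-site contrasts

Site pairs are compared on β3: `diff = β3_x − β3_y`,
`se_diff = sqrt(se_x² + se_y²)`, `z = diff/se_diff`, two-sided normal p.
Per-site SEs are reconstructed from each fit's interaction CI
(`se = width / (2·z_level)`) — the meta-analytic convention when only
intervals are reported — with a `se_source='wald'` option; the two agree
exactly for normal CIs (asserted). No multiplicity adjustment across the
site pairs. Note the contrasts share fits (each site enters several
pairs), so they are not mutually independent.

## Synthetic survey generator

The generator emulates a paired-exclosure experiment at its real scale:
4 sites × 15 plot pairs × 2 treatments, 18 survey occasions on a 0–156
month grid (6-monthly for ~8 years, then two annual-phase surveys), site
species pools of 170–229 taxa, and one site missing occasions 54, 60, 66
and 156 — so the pipeline must tolerate unbalanced designs.

Expected count of species *s* in plot *p* at month *t*:

    λ = exp( sad_s + a_{p,s}·shrink_p(t) + t·β_time
             + 1[exclusion]·t·(δ_rich + 1[hyper]·δ_release) )

* `sad_s ~ N(sad_meanlog, sad_sdlog²)` — log-normal species abundance
  distribution per site; the `n_hyperdominant` species with the largest
  draws are the hyperdominants (palm/bamboo/fern analogues).
* `a_{p,s}` — plot-specific log-affinities creating baseline beta
  diversity, decomposed into a pair-shared and a plot-specific component
  (`affinity_pair_corr` is the pair-level variance share). Paired plots
  sit a few metres apart and share microhabitat, so a substantial shared
  component is realistic — and it is what gives the pair random intercept
  in the alpha model a real counterpart.
* `shrink_p(t) = (1 − convergence_rate)^t` for exclusion plots, 1 for
  controls: geometric shrinkage of affinities toward the site mean, the
  simplest process producing compositional convergence (homogenization).
* `β_time` — slow background colonization trend shared by both treatments;
  `δ_rich` — extra per-month log-abundance trend under exclusion (raises
  detected richness); `δ_release` — additional release trend applied only
  to hyperdominants.
* Counts are negative binomial with size `dispersion` (Poisson in the
  limit `dispersion=None`); log-means are capped at ln(10⁶) so extreme
  release settings cannot overflow. A plot's count is the aggregate over
  its sampled subplots.

Key defaults, with units: `sad_meanlog = −2.0`, `sad_sdlog = 1.5`
(log-individuals per plot per survey; gives ~75 individuals and ~25–40
detected species per plot at pools of 170–229), `affinity_sd = 0.8`
(log-units; baseline multiple-site Bray–Curtis ≈ 0.55–0.65 among 15
plots), `affinity_pair_corr = 0.6`, `dispersion = 8` (moderate
overdispersion), `beta_time_richness = 0.002`/month. The
`homogenization` preset uses `delta_richness = 0.004`,
`hyper_release_rate = 0.012` and `convergence_rate = 0.012` per month:
over 156 months these produce a richness interaction of roughly +0.1
species/month and a decline of exclusion-plot beta diversity from ~0.6 to
~0.37 — the qualitative alpha-up/beta-down pattern at a magnitude
comparable to what long-term exclosures report. The `null` preset sets
all three effect parameters to zero; `release_only` keeps only the
hyperdominant release.

What the generator does **not** emulate: spatial coordinates or distance
decay, mammal movement and selective-herbivory mechanisms, seed dispersal,
temporal autocorrelation of sampling noise beyond the persistent plot
affinities, masting/reproductive pulses, and observer error in species
identification. Passing tests therefore demonstrate that the estimators
recover the effects *this* generative family encodes — they cannot certify
behaviour under, e.g., strongly autocorrelated or zero-inflated field
noise.

## Numerical conventions and degenerate inputs

* Identical communities return exact (not approximate) zero dissimilarity;
  two all-empty communities are an error (undefined), while empty plots
  within a larger group are dropped with a log entry.
* When `A + min(B,C) = 0` (completely disjoint support) the balanced
  component is defined as 1, the limit value.
* Ties at the gating boundary (`p3 = 0.05`) are non-interpretable.
* `se_from_ci` rejects degenerate intervals (high ≤ low).
* Exactly noiseless (zero-residual) data is a degenerate input for REML:
  the variance profile is flat at the boundary and the intercept inherits
  ~1e−5 numerical error even though slope, treatment and interaction are
  recovered exactly; tests document this.
* Long-format tables store only positive counts; zeros are implicit and
  restored when matrices are built against the site plot roster, so a plot
  that is empty at one occasion still appears (flagged) in every table.
* Sites are processed independently and in lexicographic order; identical
  input, config and seed give byte-identical outputs (the manifest
  timestamp aside).

## Problem sizes used in the test suite

Statistical properties are verified by simulation at these scales, chosen
to give stable Monte-Carlo estimates: partition exactness on 1,000 random
matrices (3–8 plots × 5–20 species) against a brute-force pair-enumeration
oracle; the incidence limit on 500 random 0/1 matrices; jackknife closed
forms on 100 datasets; type-I error of the interaction test on 2,000
null-scenario replicates (5 pairs, 8 occasions, 30 species), asserted
within [0.03, 0.07]; recovery of a known interaction (0.05/month) and CI
coverage on 500 model-generated replicates at study scale (15 pairs, 18
occasions); and direction recovery of the homogenization pattern on 200
full-scale replicates, asserted at ≥ 95%. Core quantities are additionally
cross-checked against the R `vegan` implementations (decostand, diversity,
vegdist) on a seeded fixture.

## Known limitations

* Mixed-model inference is Wald/normal; no Satterthwaite or Kenward–Roger
  degrees-of-freedom corrections, no autocorrelation structures, no GAMs.
  With ≤ 5 pairs and few occasions the interaction test runs slightly
  conservative (persistent plot effects inflate the residual estimate).
* The jackknife provides SEs and normal-approximation CIs only — no
  bootstrap or BCa intervals; for strongly skewed dissimilarity
  distributions at small n the CIs are approximate.
* Beta-diversity trend models treat treatment-level summaries as
  observations; their jackknife SEs are available as weights but the
  default (and tested) path is unweighted OLS.
* The hyperdominant set is fixed at simulation time (the top of the SAD),
  not dynamically determined.
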