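"""Multiple-site beta diversity, partitioned, with jackknife uncertainty.

For each site x survey month x treatment, the multiple-site Bray-Curtis
dissimilarity among all plots of that treatment summarizes how spatially
heterogeneous the community is.  It splits additively into balanced
variation (species swap dominance between plots) and abundance gradients
(uniform richer/poorer differences).  A plot-level leave-one-out jackknife
gives SEs and approximate 95% CIs.
"""

import exclosure as ex

survey = ex.simulate_survey(ex.scenario_preset("homogenization", seed=42))
beta = ex.beta_summaries(survey, transformed=True, jackknife=True)

site = "ITA"
sub = beta[(beta.site == site) & (beta.month.isin([0, 48, 108, 156]))]
cols = ["month", "treatment", "total", "balanced", "gradient", "se_total"]
print(f"{site}: multiple-site Bray-Curtis partition (selected months)\n")
print(sub[cols].round(3).to_string(index=False))

final = sub[sub.month == 156].set_index("treatment")["total"]
print(f"\nAt the final survey, exclusion-plot beta diversity ({final['exclusion']:.3f}) "
      f"sits well below control ({final['control']:.3f}):")
print("exclusion plots have converged — biotic homogenization.")
print("Additivity: total = balanced + gradient holds to machine precision.")
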