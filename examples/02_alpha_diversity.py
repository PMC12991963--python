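"""Plot-level alpha diversity through time.

Richness counts species present; Shannon and inverse Simpson are computed
on Hellinger-derived proportions (the transform precedes every metric).
Under the homogenization scenario all three rise faster in exclusion
plots: removing mammal herbivores releases recruitment.
"""

import exclosure as ex

survey = ex.simulate_survey(ex.scenario_preset("homogenization", seed=42))
alpha = ex.alpha_table(survey, transformed=True)

site = "ITA"
sub = alpha[alpha.site == site]
first, last = sub.month.min(), sub.month.max()
print(f"{site}: mean per-plot alpha diversity, month {first} vs month {last}\n")
for metric in ("richness", "shannon", "inv_simpson"):
    table = (sub[sub.month.isin([first, last])]
             .groupby(["month", "treatment"])[metric].mean().unstack())
    print(f"{metric}:")
    print(table.round(2).to_string(), "\n")

print("Exclusion plots end richer and more even than controls; the paired")
print("design means the treatment contrast is read within pairs over time.")
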