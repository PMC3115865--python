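"""Which factors shape genetic diversity?  All-subsets AIC model selection.

Builds the predictor table (distance to range margin, climate-space
marginality with the 85%-quantile groups, curated binary factors, the
expansion class with the ref+hol merge rule), then ranks every additive
predictor subset for arcsin-transformed H_E by AICc and Akaike weight.
"""

import numpy as np

import rangediv as rd

geno, haps, sites, truth = rd.simulate_metapopulation(
    rd.scenario_range_expansion(), seed=6
)
div = rd.diversity_table(geno, haps)
selfing = rd.selfing_table(geno, n_perm=199, rng=np.random.default_rng(0))
div["s"] = selfing["s_hat"]

pred = rd.predictor_table(sites, div=div, rng=np.random.default_rng(1))
data = pred.join(div, how="inner")
data["asin_H_E"] = np.arcsin(np.sqrt(data["H_E"].clip(0, 1)))

table = rd.all_subsets_selection(
    data["asin_H_E"], data,
    predictors=["lim_km", "marg", "bar", "bio", "size", "expansion"],
)
shown = table[table["displayed"]]
print(shown[["predictors", "df", "SS_res", "pct_var", "AIC", "weight"]].round(3))
print(
    f"\n{len(table)} candidate models fitted; rows shown carry > 5% Akaike"
    "\nweight. The expansion class should dominate: founder effects in the"
    "\nrecently colonized sites explain most of the diversity variance."
)
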