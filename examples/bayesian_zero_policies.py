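"""Bayesian source-Shannon inference under the three zero policies.

For each library size, one multinomial sample from the Scrabble source is
analyzed three ways: zeros excluded, zeros up to the true richness (27),
and extraneous zeros (50 modeled variants, 23 of which do not exist in
the source). Posterior means show the characteristic bias of each policy.
"""

from ampdiv import ZeroPolicy, scrabble_population, zero_policy_experiment

pop = scrabble_population()
policies = [
    ZeroPolicy("observed_only"),
    ZeroPolicy("pad_to_richness", richness=27),
    ZeroPolicy("pad_to_richness", richness=50),
]
df = zero_policy_experiment(
    pop, [50, 100, 200, 500, 1000], policies, n_draws=10_000, seed=7
)
wide = df.pivot(index="library_size", columns="policy", values="mean").round(3)
print("posterior mean of the source Shannon index (true value 3.03):")
print(wide.to_string())
print(
    "\nExcluding zeros underestimates the source index and extraneous zeros\n"
    "overestimate it, most severely at small library sizes; modeling exactly\n"
    "the source's 27 variants is consistent — its column approaches 3.03 as\n"
    "the library size grows, with no library-size normalization anywhere."
)
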