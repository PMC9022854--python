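"""Generate a synthetic GBD-shaped burden table with known ground truth.

Creates a 20-location, two-year panel in which a hidden per-location quality
variable q drives all six measures, and prints a sample of both tables.
Higher q means lower mortality-to-incidence and longer survival with the
disease, which is exactly the structure the index is designed to recover.
"""

import qcindex as qc

config = qc.SyntheticConfig(n_locations=20, years=[1990, 2019], seed=7)
latent = qc.simulate_latent(config)
measures = qc.simulate_measures(latent, config)

print("latent truth (one row per location-year-sex):")
print(latent.head(4).to_string(index=False))
print(f"\nmeasure table: {len(measures)} rows, "
      f"{measures['location'].nunique()} locations, "
      f"{sorted(measures['measure'].unique())}")
print("\nage-standardized rows for one stratum:")
one = measures[
    (measures.location == "L000")
    & (measures.sex == "both")
    & (measures.age_group == "age-standardized")
]
print(one[["year", "measure", "value"]].to_string(index=False))
# The rates are per 100,000; DALY = YLL + YLD holds exactly in every row.
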