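"""Simulate a two-site survey campaign and summarise stand structure.

Generates the default grazed + restored campaign (4 plots per site,
calibrated to the study's site means), then prints mean ± SD densities per
hectare by life stage and functional group.  Densities scale each plot's
counts by its sampling frame (adults 400 m², saplings 200 m², seedlings
five 4 m² quadrats); snags appear as their own reporting classes.
"""

from beniforest import simulate_survey, site_stage_summary

ds = simulate_survey(seed=1)
print(f"simulated {len(ds.stems)} stems, {len(ds.observations)} wildlife observations\n")

table = site_stage_summary(ds).table
cols = ["site_id", "stage", "group", "mean_density_per_ha", "sd_density",
        "pct_of_stage_total"]
print(table[cols].round(1).to_string(index=False))
print("\npct_of_stage_total sums to ~100 within each (site, stage); compare the "
      "grazed vs restored motacú sapling rows: the restored site should carry "
      "roughly 2.5x the motacú sapling density.")
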