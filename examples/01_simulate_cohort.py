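"""Simulate a septic shock serum cohort and inspect its glycome structure.

Builds the default study-shaped cohort (29 survivors, 8 nonsurvivors, daily
serum sampling from ICU admission) with per-sample N-glycome profiles, then
prints the day-1 Lewis-fucosylation feature by outcome group.
"""

from glycoshock import (
    CohortSpec,
    EffectSpec,
    default_catalog,
    feature_table,
    generate_cohort,
    generate_glycome_profiles,
)

catalog = default_catalog()
cohort = generate_cohort(CohortSpec(seed=1))
profiles, manifest = generate_glycome_profiles(cohort, catalog, EffectSpec(), seed=2)

print(f"cohort: {cohort['patient_id'].nunique()} patients, {len(cohort)} serum samples")
print(f"catalog: {len(catalog)} N-glycan structures, Lewis-type: {catalog.lewis_ids()}")

day1 = cohort[cohort["icu_day"] == 1]
features = feature_table(profiles.loc[day1["sample_id"]], catalog)
lewis = features["pct_lewis_fuc"]
for outcome in ("nonsurvivor", "survivor"):
    vals = lewis[day1.set_index("sample_id")["outcome"] == outcome]
    print(f"day-1 Lewis fucosylation, {outcome}s: "
          f"{vals.mean():.2f}% of the glycome (n={len(vals)})")

# The nonsurvivor group sits near 5.4% vs ~3.2% in survivors on admission:
# antennary (Lewis) fucosylation is the feature separating the groups.
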