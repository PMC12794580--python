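"""Day-1 group statistics: Mann-Whitney tests and per-glycan ROC curves.

Asks whether the Lewis-fucosylated glycans separate nonsurvivors from
survivors in serum drawn at ICU admission, using the one-tailed Mann-Whitney
U test and rank-based ROC AUC with nonsurvivor as the positive class.
"""

from glycoshock import (
    CohortSpec,
    EffectSpec,
    default_catalog,
    feature_table,
    generate_cohort,
    generate_glycome_profiles,
    mann_whitney_u,
    roc_auc,
)

catalog = default_catalog()
cohort = generate_cohort(CohortSpec(seed=5))
profiles, _ = generate_glycome_profiles(cohort, catalog, EffectSpec(), seed=6)

day1 = cohort[cohort["icu_day"] == 1]
pos = (day1["outcome"] == "nonsurvivor").to_numpy()

features = feature_table(profiles.loc[day1["sample_id"]], catalog)
for name, values in [
    ("Lewis fucosylation (%)", features["pct_lewis_fuc"].to_numpy()),
    ("glycan 22a", profiles["22a"].loc[day1["sample_id"]].to_numpy()),
    ("glycan 23a", profiles["23a"].loc[day1["sample_id"]].to_numpy()),
]:
    res = mann_whitney_u(values[pos], values[~pos], alternative="greater")
    roc = roc_auc(values, pos.astype(int))
    print(f"{name:24s} U={res.statistic:5.1f}  one-tailed p={res.p_value:.2e}  "
          f"AUC={roc.auc:.3f}")

# Small p-values and AUC near 1 mean a day-1 measurement of these glycans
# ranks nonsurvivors above survivors almost perfectly in this synthetic
# cohort, where the configured effect matches the study's day-1/2 band.
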