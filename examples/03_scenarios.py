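"""Compare the five food-system scenarios on one synthetic dataset.

S2a halves food loss and waste and shifts 10% of refined grains to whole
grains; S2b additionally cuts red-meat intake by 45% and repurposes the
freed feed; S3a/S3b test national/provincial self-sufficiency without
trade, non-food uses or animal-based foods.
"""

import pandas as pd

from nutrinet import SyntheticConfig, generate_dataset, run_pipeline

data = generate_dataset(SyntheticConfig(seed=11, n_years=1, n_provinces=4))
year = data.years[-1]

rows = []
for scenario in ["S1", "S2a", "S2b", "S3a", "S3b"]:
    results = run_pipeline(data, scenario, years=[year])
    ear = results[results["reference"].isin(["EAR", "AI", "EER"])]
    rows.append(
        {
            "scenario": scenario,
            "regions": results["region"].nunique(),
            "mean_coverage": ear["coverage"].mean(),
            "n_low": ear[ear["band"] == "low"]["nutrient"].nunique(),
            "mean_diversity": ear["diversity"].mean(),
        }
    )

table = pd.DataFrame(rows)
print(table.to_string(index=False, float_format=lambda v: f"{v:6.2f}"))
print()
print("Mean coverage rises from S1 to S2a (less loss, more whole grain) and")
print("again under self-sufficiency (S3a), where feed and non-food uses are")
print("redirected to consumption; S3b shows the per-province spread without")
print("inter-provincial trade (n_low counts nutrients in the low band in")
print("at least one region).")
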