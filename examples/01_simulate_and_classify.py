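"""Simulate a subject and classify every taxon into its longitudinal regime.

Builds a 200-day synthetic gut community with known regime labels,
rarefies it to even depth, computes the 12-feature longitudinal vector
per ASV and compares the predicted regimes with the planted truth.
"""

import pandas as pd

from microdyn import (
    AnalysisConfig,
    SyntheticSpec,
    classify_regime,
    feature_table,
    rarefy_counts,
    simulate_subject,
)

config = AnalysisConfig()
table, truth = simulate_subject(SyntheticSpec(rng_seed=0))
print(f"simulated {table.data.shape[0]} days x {table.data.shape[1]} ASVs")

rarefied, report = rarefy_counts(table, depth=5000, seed=1)
print(f"rarefied to 5,000 reads/day ({len(report.dropped_days)} days dropped)")

rows = []
for vector in feature_table(rarefied, config):
    label = classify_regime(vector, config)
    rows.append(
        {
            "asv": vector.asv_id,
            "truth": truth.loc[vector.asv_id, "regime"],
            "predicted": label.label,
        }
    )
frame = pd.DataFrame(rows)
confusion = pd.crosstab(frame["truth"], frame["predicted"])
print("\nconfusion matrix (rows = planted regime, columns = predicted):")
print(confusion)
accuracy = (frame["truth"] == frame["predicted"]).mean()
print(f"\noverall agreement: {accuracy:.2f}")
print(
    "Diagonal mass shows each planted dynamic (stationary AR, random walk,\n"
    "gated/windowed presence, bursts, sparse iid) being re-identified from\n"
    "its flatness, Ljung-Box, prevalence and ADF/KPSS thresholds alone."
)
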