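"""Detect planted seasonality and score its Fourier reconstruction.

The synthetic subject carries a coherent 7.5-day rhythm.  This script
shows the rhythm surfacing among the top community-level Fourier modes
and traces the seasonal reconstruction score as more modes are added.
"""

import numpy as np

from microdyn import (
    SyntheticSpec,
    community_seasonality,
    diversity_series,
    rarefy_counts,
    score_curve,
    simulate_subject,
)
from microdyn.ts_stats import detrend_linear

spec = SyntheticSpec(rng_seed=1)
table, _ = simulate_subject(spec)
rarefied, _ = rarefy_counts(table, depth=5000, seed=2)
series = diversity_series(rarefied, "shannon")

profile = community_seasonality(series.values, n_days=150, n_modes=5)
print(f"planted period: {spec.seasonal_periods[0]} days")
print("top-5 detected periods (days):", np.round(profile.periods[:5], 2))
print(f"5-mode seasonal reconstruction score: {profile.score:.3f}")

prepared = detrend_linear(series.values[:150])
curve = score_curve(prepared, max_modes=10)
print("\nscore vs number of modes kept:")
for n, s in enumerate(curve, start=1):
    print(f"  N={n:2d}: {s:.3f}")
print(
    "\nThe score is the Spearman correlation between the series and its\n"
    "inverse-FFT reconstruction; values at or above 0.5 mark a seasonal\n"
    "call, and the planted period appearing in the top modes confirms\n"
    "the rhythm is a community-scale feature, not single-taxon noise."
)
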