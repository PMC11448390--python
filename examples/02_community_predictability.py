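"""Whole-community predictability diagnostics of alpha diversity.

Computes the Shannon-diversity trajectory of a rarefied synthetic
subject and runs the test battery: linear trend, Ljung-Box
autocorrelation, ADF/KPSS stationarity, spectral flatness and
GARCH(1,1) volatility.
"""

import numpy as np

from microdyn import (
    SyntheticSpec,
    diversity_series,
    garch_volatility,
    linear_trend,
    ljung_box,
    rarefy_counts,
    simulate_subject,
    spectral_flatness,
    stationarity_tests,
)

table, _ = simulate_subject(SyntheticSpec(rng_seed=0))
rarefied, _ = rarefy_counts(table, depth=5000, seed=1)
series = diversity_series(rarefied, "shannon")
y = series.values
print(f"Shannon diversity over {len(y)} days: mean {y.mean():.2f} bits, "
      f"sd {y.std():.2f}")

slope, _ = linear_trend(y)
print(f"trend slope (per standardized time unit): {slope:+.4f}")

p_values = ljung_box(y, lags=70)
print(f"Ljung-Box: min p over 70 lags = {p_values.min():.2e} "
      f"({'autocorrelated' if p_values.min() < 0.05 else 'no autocorrelation'})")

verdict = stationarity_tests(y)
print(f"ADF p = {verdict.adf_p:.3g}, KPSS p = {verdict.kpss_p:.3g} "
      f"-> {verdict.call}")

flatness = spectral_flatness(y[:150], detrend=True)
print(f"spectral flatness (first 150 days, detrended): {flatness:.3f} "
      f"({'noise-like' if flatness >= 0.4 else 'structured'})")

garch = garch_volatility(y)
print(f"GARCH(1,1) volatility (mean conditional variance): "
      f"{garch.volatility:.4f}")
print(
    "\nA structured (non-flat) spectrum plus rejected Ljung-Box nulls mean\n"
    "the community trajectory depends on its own past - it is predictable,\n"
    "not white noise."
)
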