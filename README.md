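# microdyn

Statistical analysis of **dense longitudinal microbiome time series** —
daily 16S feature tables spanning months to years of one subject's gut
(or any body-site) community.

Cross-sectional microbiome studies answer *who is there*; a dense time
series can answer *how they behave*.  `microdyn` takes a daily ASV
count table and asks, at two scales:

* **Community scale** — is the trajectory of alpha diversity (Shannon
  index `SD = -Σ p_i log₂ p_i`, Faith's phylogenetic diversity
  `PD = Σ_j I_j · branchlen_j`) white noise, or structured and
  predictable?  Diagnostics: OLS trend, ACF/PACF, the Ljung–Box test
  at every lag up to 70, ADF + KPSS unit-root tests, spectral flatness
  (geometric/arithmetic mean ratio of framed power spectra), and
  GARCH(1,1) volatility.  Seasonality is read off the FFT and
  validated by the **seasonal reconstruction score** — the Spearman
  correlation between a series and its inverse-FFT reconstruction from
  its N largest-amplitude modes.  Forecasting uses a grid-searched
  ARIMAX whose exogenous regressor is the top-N Fourier wave of the
  training window, extended periodically over the horizon.

* **Taxon scale** — every ASV trajectory is summarized by a 12-feature
  longitudinal vector (mean, SD, prevalence, trend, Ljung–Box p,
  flatness, ADF p, KPSS p, dominant period, seasonal score, PC1/PC2
  ordination loadings) and classified into one of six **longitudinal
  regimes** by fixed thresholds:

  | regime | flatness | Ljung–Box p | prevalence | ADF p | KPSS p |
  |---|---|---|---|---|---|
  | white noise | ≥ 0.4 | > 0.05 (all lags) | — | — | — |
  | rare | < 0.4 | < 0.05 | < 0.1 | — | — |
  | stable prevalent | < 0.4 | < 0.05 | > 0.9 | < 0.05 | > 0.05 |
  | unstable prevalent | < 0.4 | < 0.05 | > 0.9 | > 0.05 | < 0.05 |
  | stable temporal | < 0.4 | < 0.05 | 0.1–0.9 | < 0.05 | > 0.05 |
  | unstable temporal | < 0.4 | < 0.05 | 0.1–0.9 | > 0.05 | < 0.05 |

  Taxon–taxon association is measured on CLR-transformed counts by the
  proportionality statistic `ρ(x, y) = 1 − Var(x−y)/(Var(x)+Var(y))`;
  thresholding `|ρ|` (default 0.6) yields a co-occurrence graph whose
  connected components, "cloud" of unconnected singletons, and
  PC1+PC2-loading profiles describe which taxa move together and which
  drive community variability.

Preprocessing follows the field's standard longitudinal protocol:
missing days are filled by shape-preserving PCHIP interpolation (keeps
counts non-negative and monotone), and counts are rarefied without
replacement to an even depth before diversity and per-taxon statistics.

A first-class **synthetic-subject generator** plants all six regimes
(plus seasonal tones and correlated blocks) with ground-truth labels,
so the entire pipeline is testable end-to-end without any downloads.

## Worked example

```python
from microdyn import (AnalysisConfig, SyntheticSpec, simulate_subject,
                      rarefy_counts, feature_table, classify_regime)

config = AnalysisConfig()                     # all thresholds live here
table, truth = simulate_subject(SyntheticSpec(rng_seed=0))
rarefied, _ = rarefy_counts(table, depth=5000, seed=1)
for v in feature_table(rarefied, config)[:3]:
    print(v.asv_id, classify_regime(v, config).label,
          f"prevalence={v.prevalence:.2f} flatness={v.flatness:.2f}")
```

prints

```
ASV_0000 stable_prevalent prevalence=1.00 flatness=0.25
ASV_0001 stable_prevalent prevalence=1.00 flatness=0.18
ASV_0002 unstable_prevalent prevalence=1.00 flatness=0.26
```

— always-present taxa with tonal (non-flat) spectra land in the
prevalent regimes, split into stable vs unstable by the joint
ADF/KPSS verdict (the third taxon's seeded trajectory reads as a unit
root here).  Running the full
script `examples/01_simulate_and_classify.py` prints the 6×6 confusion
matrix between planted and recovered regimes (agreement ≈ 0.7–0.85
per run).  The other `examples/` scripts walk through community
predictability testing, seasonality scoring, ARIMAX forecasting
(`examples/04`: test MAPE 5.1% vs 11.9% for a predict-the-mean
baseline) and co-occurrence graph analysis.

## Command line

Every stage is also a subcommand of the `microdyn` CLI, each writing
TSV/JSON outputs plus a manifest (config snapshot, input hashes, seed):

```bash
microdyn simulate   --out table.tsv --truth truth.tsv --seed 1
microdyn preprocess --table table.tsv --out rarefied.tsv --rarefaction-depth 5000
microdyn community  --table rarefied.tsv --metric shannon --out-prefix comm
microdyn features   --table rarefied.tsv --ordination-table table.tsv --out feats.tsv
microdyn regimes    --features feats.tsv --out labels.tsv
microdyn graph      --table table.tsv --out-prefix graph
microdyn forecast   --series comm_diversity.tsv --out forecast.json --train-days 100
```

## Documentation

`docs/methods.md` describes the statistical model, every tunable
parameter with its default and rationale, what the synthetic generator
does and does not emulate, and known limitations.
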