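# Methods

This note documents the statistical procedures implemented in
`microdyn`, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Input model and preprocessing

The universal input is a daily ASV count table for one subject: rows
are integer days since the first sample, columns are ASV identifiers,
cells are read counts.  Missing days (unsampled or failed samples) are
absent rows, preserved on read.

**Interpolation.** Gaps are filled per-ASV with piecewise cubic
Hermite interpolation (PCHIP).  Between non-negative knots PCHIP
cannot undershoot below the smaller knot and preserves monotone runs,
which suits spiky count data where a natural cubic spline would ring.
Rows are not re-closed after interpolation — counts, not compositions,
are interpolated.  Interpolated days are flagged on the table.

**Rarefaction.** Each day's reads are subsampled *without replacement*
(multivariate hypergeometric) to a common depth.  Non-integer
interpolated counts are rounded half-to-even first, since subsampling
requires integers.  Days whose total falls below the depth are dropped
and reported rather than resampled with replacement; if the drops
re-open gaps, downstream operations run on the gapped series — data
are never fabricated twice.  The depth default is 18,000 reads, a
typical 16S per-sample depth; it is a config knob
(`AnalysisConfig.rarefaction_depth`) because the right value is
dataset-specific (rarefaction-curve inspection is the usual guide).

**CLR.** The centered log-ratio transform uses a pseudocount of 1 by
default: `clr(x)_j = ln(x_j + 1) − mean_k ln(x_k + 1)`.  Rows sum to
zero; Euclidean distance between CLR rows is the Aitchison distance.

## Community-scale diagnostics

Alpha diversity is computed per day on the rarefied table: Shannon's
index in bits (base-2 logarithm — the convention of the QIIME
ecosystem; base *e* is available and the base is recorded in outputs)
and Faith's PD as the total branch length spanned by the present tips
of a rooted input tree, each branch counted once.

The trajectory is then characterized by:

* **Trend** — OLS slope against a standardized (zero-mean,
  unit-variance) time axis, so slopes compare across series lengths.
* **Autocorrelation** — sample ACF/PACF with the large-sample
  `±z/√n` band, and the Ljung–Box portmanteau test at every lag
  1..70.  The 70-lag default (`lb_lags`) spans two months of daily
  samples, long enough to expose weekly and monthly rhythms; series
  shorter than 71 points use length−1 lags.
* **Stationarity** — ADF (unit-root null, AIC lag selection) and KPSS
  (stationarity null, level-stationary variant by default;
  `kpss_regression="ct"` switches to trend-stationarity).  The joint
  call is *stationary* only when ADF rejects and KPSS does not,
  *nonstationary* for the reverse pattern, *ambiguous* otherwise —
  no input reaches an unlabeled state.
* **Spectral flatness** — the series is linearly detrended, cut into
  Hann-windowed frames of length ⌊n/2⌋ hopped by half a frame; each
  frame's power spectrum is summarized by geometric mean / arithmetic
  mean and the score is the frame average.  White noise scores near
  `exp(ψ(1)) ≈ 0.56`; a pure tone scores near 0.  A relative floor of
  `1e-12 × max(power)` bounds `log 0` while keeping the score
  scale-invariant.  Community-level flatness is evaluated on the first
  150 days so subjects of different spans are comparable.
* **White-noise call** — a series is white noise when the Ljung–Box
  p-value exceeds α at *every* lag **and** flatness ≥ 0.4
  (`flatness_threshold`).  The all-lags requirement is a family-wise
  condition over ~70 dependent tests: calibration shows even pure iid
  Gaussian series pass it only ~72% of the time at n = 150–200.  The
  rule therefore under-calls true noise by design; the property tests
  pin this measured rate rather than a nominal 1−α.
* **Volatility** — a GARCH(1,1) model fitted by Gaussian maximum
  likelihood (Nelder–Mead over (ω, α, β) with stationarity constraints
  α+β < 1, three starts); volatility is the mean fitted conditional
  variance.  Non-convergence yields a flagged NaN, never an exception,
  so batch runs over thousands of taxa cannot abort.

## Seasonality

Before spectral analysis a series is stationarized according to the
joint ADF/KPSS outcome: the trend-stationary pattern (KPSS rejects,
ADF rejects) is linearly detrended; every other pattern — including
the doubly-stationary one — is first-differenced.  The fourth cell
(ADF fails, KPSS fails to reject) is not distinguished in the
procedure's source description; differencing is applied there too,
consistent with every other non-detrend case.

Dominant seasonalities are the FFT bins (DC excluded) ranked by
amplitude; bin k of an n-point series is a period of n/k days, and
amplitude ties break toward longer periods, favoring interpretable
low-frequency seasonality.  The **seasonal reconstruction score** for
N modes is the Spearman correlation between the series and its inverse
FFT with all but the top-N bins zeroed (DC retained so keeping all
modes inverts exactly).  A taxon is *seasonal* when the 5-mode score
reaches 0.5 (`seasonal_modes`, `seasonal_score_threshold`).

Two null-distribution facts matter for interpretation.  First, the
score's null level is length-dependent: the top 5 of ~n/2 bins of pure
noise capture a variance share that shrinks with n, so the expected
null score falls from ≈ 0.48 at n = 150 to ≈ 0.33 at n = 400.  The 0.5
threshold separates cleanly (≥ 90% of null draws below it) from about
200 days on; at 150 days it is marginal.  Second, heavily tied series
(sparse integer counts) rank-correlate with their reconstructions more
strongly than continuous noise does, raising the null to just around
0.5; planted sparse-noise taxa score below 0.5 in ~80% of seeds, not
~99% as Gaussian noise would.

## Forecasting

Alpha diversity is forecast by ARIMA(p, d, q) with one exogenous
regressor: the seasonal wave obtained by keeping the top-N Fourier
modes of the linearly detrended training window and evaluating those
sinusoids at future t (periodic extension).  Orders and N are selected
by grid search — each cell is fitted on the training window minus a
held-out 20% tail and scored by MAPE on that tail, ties broken by
Wasserstein distance then by p+q — and the winner is refitted on the
full window.  The library's default grid is p ∈ 0..4, d ∈ {0,1},
q ∈ 0..10, N ∈ 1..6; the examples and tests use reduced grids sized to
their simulations.  Performance is reported as MAPE (zero-valued true
points excluded with a warning), the 1-D Wasserstein distance between
predicted and true value distributions, and both metrics per
consecutive 20-day window (`cv_window`).

A structural constraint of the FFT wave: it can only carry periods
n/k for integer k, so a rhythm of period T is representable exactly
only when the training length is a multiple of T.  Otherwise the
nearest bins drift out of phase over long horizons — the examples use
an 84-day training window (12 × 7-day cycles) for the 7-day
simulation for exactly this reason.  Multiplicative SARIMA seasonality
is deliberately out of scope: daily gut series carry several
incommensurate periods at once, which the additive wave handles
directly.

## Taxon-scale features and regimes

Each ASV's rarefied daily series yields a 12-feature vector: mean
abundance (reads/day), standard deviation, prevalence (fraction of
days with count > 0), trend slope, minimum Ljung–Box p over the lag
battery, spectral flatness, ADF p, KPSS p, dominant period and 5-mode
seasonal score (both on the stationarized series), and the taxon's
loadings on the first two ordination axes.  Any statistic that is
undefined on a degenerate series becomes NaN; the batch never aborts.

Classification applies the threshold table in a fixed order:

1. *white noise* — flatness ≥ 0.4 and all Ljung–Box p > α.  This
   check uses only the two noise features; the stationarity and
   prevalence values that co-occur with noise taxa empirically are
   treated as observations, not requirements — a strict conjunction
   would leave most noise taxa unlabeled.
2. otherwise the taxon must be autocorrelated and non-flat
   (flatness < 0.4 and min Ljung–Box p < α); the prevalence band then
   separates *rare* (< 0.1), *prevalent* (> 0.9) and *temporal*
   (between), with band edges `prevalence_low`/`prevalence_high`
   exposed in config.
3. prevalent and temporal taxa split into *stable* (ADF < α, KPSS > α)
   vs *unstable* (ADF > α, KPSS < α); the two remaining ADF×KPSS
   patterns are *unclassified*, never silently binned.

The classifier is a total, deterministic function; every label carries
a trace of the threshold comparisons that produced it.

## Ordination and loadings

Within-subject ordination is classical PCoA of the day-by-day
Aitchison distance matrix, computed on interpolated, non-rarefied
counts (CLR already removes depth effects).  Because the distance is
Euclidean in CLR space, the embedding coincides with PCA of the CLR
matrix up to axis sign — the test suite uses this identity as a
cross-oracle.  Axis signs are fixed by making the largest-magnitude
coordinate of each axis positive.  A taxon's loading on an axis is the
biplot projection — Pearson correlation between its CLR column and the
axis scores, scaled by √eigenvalue — and the scalar "PC1+PC2 loading"
used in region summaries is |l₁| + |l₂| (absolute values are summed:
the sign of a loading is arbitrary under axis reflection).  Constant
CLR columns get loading 0 with a flag.

## Proportionality graphs

Association between CLR trajectories is
`ρ(x, y) = 1 − Var(x−y)/(Var(x)+Var(y))` (population variances): 1 for
perfectly proportional pairs, −1 for mean-free anti-proportional
pairs, ≈ 0 under independence.  The pseudosimilarity matrix is |ρ|
with entries ≤ ρ_thr zeroed (strict inequality keeps an edge; default
ρ_thr = 0.6, a compromise between over-connected and fragmented
graphs).  Nonzero off-diagonal entries are graph edges; NaN entries
(zero-variance pairs) count as no edge and are tallied.

Regions are defined graph-theoretically: the k largest connected
components (default k = 3), a *cloud* of isolated nodes and components
smaller than `min_component_size` (default 3), and the rest.  A
spring-layout radius could draw the same picture, but layout is
stochastic; the graph-theoretic definition makes region assignment
independent of any layout seed.  The component-size cutoff separating
"tiny" from "real" components is not canonically fixed; 3 is the
smallest size that excludes trivial pairs, and it is configurable.

`hierarchical_partition` complements the graph view: complete-linkage
agglomeration of 1 − similarity distances with a flat cut (pass signed
ρ for distances up to 2, or |ρ| for distances up to 1, and choose the
cut height on the matching scale).

## The synthetic generator

`SyntheticSpec`/`simulate_subject` build a 200-day, 60-taxon subject
(ten per regime by default) emulating the shape of year-long daily 16S
series: a few prevalent taxa carry most reads; rare and noisy taxa
dominate the taxon count.  Constructions, all in log-abundance with
Poisson emission (log-normal mixed counts):

* stable prevalent — AR(1), φ = 0.78, innovation σ = 0.25 around a
  high mean.  An AR(1) spectrum has flatness 1 − φ², so φ = 0.78 puts
  stable taxa well below the 0.4 noise threshold while ADF still
  detects mean reversion at 200 days (larger φ starves ADF of power;
  smaller φ flattens the spectrum toward the noise threshold).
* unstable prevalent — driftless Gaussian random walk (σ = 0.06/day)
  with a wide safety clip that almost never binds; clipping or
  reflecting a walk tightly would re-introduce mean reversion and
  erase the unit root the regime is defined by.
* stable temporal — the AR(1) dynamic gated by a two-state Markov
  presence process (stay probability 0.88, mean run ≈ 8 days),
  targeting mid-band occupancy.
* unstable temporal — a colonization/extinction window: absent for a
  contiguous leading or trailing block (window fraction 0.3–0.75),
  random walk while present.  Day-by-day gating of a walk makes it
  test as stationary; a contiguous window preserves the unit-root
  signature.
* rare — zero baseline with 1–3 smooth bursts of 4–7 days (burst
  start probability 0.008/day, peak ≈ 150 reads); smooth bursts keep
  spectral energy at low frequencies so rare taxa are not mistaken
  for (spectrally flat) spike trains.
* white noise — iid Poisson(6) counts present on 30% of days; sparse,
  serially independent, spectrally flat.

The two prevalent regimes load on shared latent factors with
alternating signs, making each a block of proportional and
anti-proportional taxa — the planted structure co-occurrence graphs
recover.  Each block's expected daily total is normalized to a
constant; without this, block-level swings propagate through
rarefaction's re-closure into every other taxon's series and corrupt
their stationarity calls.  Three stable taxa additionally carry a
7.5-day sinusoid (amplitude 0.7 in log space, phases aligned within a
subject, signs alternating so the rhythm survives in relative
composition), and the stable-temporal taxa are modulated by the same
phase-aligned wave at amplitude 0.45 — a coherent rhythm on
un-normalized taxa is what makes the planted period visible in
community alpha diversity (a common multiplicative rhythm on a
normalized block is removed by closure).  The 7.5-day default period
is an exact FFT bin of the 150-day community analysis window.

What the generator does **not** emulate: taxonomic or phylogenetic
realism (the companion tree is random), overdispersion beyond
log-normal–Poisson, technical batch effects, varying sequencing depth
per day, compositional interactions beyond the two planted blocks, and
real perturbation events (travel, illness, antibiotics).  Passing the
recovery tests therefore shows the statistical machinery identifies
the dynamics it is defined on — not that real gut data are this clean.

## Calibration results pinned by the test suite

All stochastic tests are seeded and deterministic.  Values measured
once during design and pinned:

* flatness of detrended iid Gaussian noise (n = 150) exceeds 0.4 in
  > 99% of draws (5th percentile ≈ 0.49); a pure tone scores < 1e-4.
* the all-70-lags Ljung–Box pass rate for iid noise is ≈ 0.72; the
  joint white-noise call on iid Gaussian series is pinned at ≥ 0.65.
* Ljung–Box per-lag rejection at lag 10 under the null: 0.046–0.06,
  consistent with the nominal 0.05.
* macro-averaged regime recovery on the synthetic subject over 20
  seeds: ≈ 0.81 (per-class: rare ≈ 0.94, unstable temporal ≈ 0.93,
  stable prevalent ≈ 0.78, stable temporal ≈ 0.78, white noise ≈
  0.73, unstable prevalent ≈ 0.72 — the unstable classes are bounded
  by KPSS power and ADF size at n = 200, the noise class by the
  family-wise all-lags rule).
* forecast recovery (AR(1) φ = 0.6 + 7-day tone, 84-day training):
  the grid search selects d = 0 with a 7-day wave and beats the
  mean-only baseline in 20/20 seeds (MAPE ≈ 5% vs ≈ 11%).

## Known limitations

* KPSS p-values are interpolated from table bounds and clip at
  [0.01, 0.1]; verdicts near α inherit that granularity.
* The regime thresholds are fixed constants, not estimated; on real
  data their appropriateness should be checked per dataset
  (`AnalysisConfig` exposes all of them).
* GARCH volatility on short (< 100-day) series is noisy; the fit is
  flagged rather than regularized.
* The FFT seasonal wave cannot represent periods that are not integer
  divisors of the training length (see Forecasting above).
* Faith's PD requires every present taxon to be a tree tip; there is
  no automatic pruning or name-matching heuristic.
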