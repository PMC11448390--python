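"""Per-ASV longitudinal feature vectors and regime classification.

Each taxon's trajectory is summarized by twelve features spanning five
facets: general characteristics (mean abundance, standard deviation,
prevalence, trend), white-noise behavior (Ljung-Box p-values,
flatness), stationarity (ADF and KPSS p-values), seasonality (dominant
period, seasonal reconstruction score), and impact on community
variability (loadings on the first two ordination axes).

The vector is then mapped to one of six longitudinal regimes:

* white noise — flat spectrum and no autocorrelation at any lag;
* otherwise, for autocorrelated non-flat taxa, the prevalence band
  picks rare (< low), prevalent (> high) or temporal (in between), and
  prevalent/temporal split into stable (ADF rejects unit root, KPSS
  does not reject stationarity) vs unstable (the opposite pattern);
* anything that matches no rule is left unclassified with a trace of
  the thresholds that fired.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import AnalysisConfig
from .spectral import (
    fft_dominant_seasonalities,
    prepare_series,
    seasonal_reconstruction_score,
)
from .table import AbundanceSeriesTable
from .ts_stats import (
    linear_trend,
    ljung_box,
    spectral_flatness,
    stationarity_tests,
)

__all__ = [
    "LongitudinalFeatureVector",
    "RegimeLabel",
    "REGIMES",
    "build_feature_vector",
    "feature_table",
    "feature_correlation_matrix",
    "classify_regime",
    "regime_abundance_series",
]

FEATURE_NAMES = [
    "mean_abundance",
    "std_abundance",
    "prevalence",
    "trend",
    "lb_min_p",
    "flatness",
    "adf_p",
    "kpss_p",
    "dominant_period",
    "seasonal_score",
    "pc1_loading",
    "pc2_loading",
]

REGIMES = (
    "white_noise",
    "rare",
    "stable_prevalent",
    "unstable_prevalent",
    "stable_temporal",
    "unstable_temporal",
    "unclassified",
)


@dataclasses.dataclass
class LongitudinalFeatureVector:
    asv_id: str
    mean_abundance: float
    std_abundance: float
    prevalence: float
    trend: float
    lb_min_p: float
    lb_all_p_above_alpha: bool
    flatness: float
    adf_p: float
    kpss_p: float
    dominant_period: float
    seasonal_score: float
    pc1_loading: float
    pc2_loading: float

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in FEATURE_NAMES},
                         name=self.asv_id)


@dataclasses.dataclass
class RegimeLabel:
    label: str
    trace: list

    def __post_init__(self) -> None:
        if self.label not in REGIMES:
            raise ValueError(f"unknown regime {self.label!r}")
        if not self.trace:
            raise ValueError("rule trace must be non-empty")


def build_feature_vector(
    series: pd.Series | np.ndarray,
    asv_id: str,
    config: AnalysisConfig,
    loadings: tuple[float, float] = (float("nan"), float("nan")),
) -> LongitudinalFeatureVector:
    """Populate the 12-feature vector for one ASV trajectory.

    Any statistic whose computation fails on a degenerate series (e.g.
    all-zero, constant) becomes NaN rather than aborting the batch; the
    classifier later maps incomplete vectors to ``unclassified``.
    """
    y = np.asarray(series, dtype=float)
    nan = float("nan")
    mean = float(y.mean())
    std = float(y.std())
    prevalence = float((y > 0).mean())

    def _try(fn, default=nan):
        try:
            return fn()
        except Exception:
            return default

    trend = _try(lambda: linear_trend(y)[0])
    lags = min(config.lb_lags, len(y) - 1)
    lb_p = _try(lambda: ljung_box(y, lags), default=None)
    lb_min_p = float(np.min(lb_p)) if lb_p is not None else nan
    lb_all_above = bool(lb_p is not None and np.min(lb_p) > config.alpha)
    flatness = _try(lambda: spectral_flatness(y, detrend=True))
    verdict = _try(
        lambda: stationarity_tests(y, config.alpha, config.kpss_regression),
        default=None,
    )
    adf_p = verdict.adf_p if verdict is not None else nan
    kpss_p = verdict.kpss_p if verdict is not None else nan

    dominant_period, seasonal = nan, nan
    if verdict is not None:
        prepared = _try(lambda: prepare_series(y, verdict)[0], default=None)
        if prepared is not None and np.ptp(prepared) > 0 and len(prepared) >= 8:
            profile = _try(lambda: fft_dominant_seasonalities(prepared), default=None)
            if profile is not None:
                dominant_period = profile.dominant_period
            seasonal = _try(
                lambda: seasonal_reconstruction_score(prepared, config.seasonal_modes)
            )

    return LongitudinalFeatureVector(
        asv_id=asv_id,
        mean_abundance=mean,
        std_abundance=std,
        prevalence=prevalence,
        trend=trend,
        lb_min_p=lb_min_p,
        lb_all_p_above_alpha=lb_all_above,
        flatness=flatness,
        adf_p=adf_p,
        kpss_p=kpss_p,
        dominant_period=dominant_period,
        seasonal_score=seasonal,
        pc1_loading=float(loadings[0]),
        pc2_loading=float(loadings[1]),
    )


def feature_table(
    table: AbundanceSeriesTable,
    config: AnalysisConfig,
    loadings: pd.DataFrame | None = None,
) -> list[LongitudinalFeatureVector]:
    """Feature vectors for every ASV column of a (rarefied) table.

    ``loadings`` is the ASVs x (pc1, pc2) frame from the ordination
    module; pass None to leave the loading features NaN.
    """
    vectors = []
    for asv in table.asv_ids:
        if loadings is not None and asv in loadings.index:
            load = (float(loadings.loc[asv, "pc1"]), float(loadings.loc[asv, "pc2"]))
        else:
            load = (float("nan"), float("nan"))
        vectors.append(
            build_feature_vector(table.data[asv], asv, config, loadings=load)
        )
    return vectors


def vectors_to_frame(vectors) -> pd.DataFrame:
    return pd.DataFrame([v.as_series() for v in vectors])


def feature_correlation_matrix(vectors) -> pd.DataFrame:
    """12 x 12 Spearman correlation matrix across feature vectors
    (typically pooled over subjects).  NaN feature values are dropped
    pairwise; constant features yield NaN rows with a warning."""
    frame = vectors if isinstance(vectors, pd.DataFrame) else vectors_to_frame(vectors)
    if frame.shape[0] < 3:
        raise ValueError("need at least 3 feature vectors")
    cols = FEATURE_NAMES
    n = len(cols)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            a, b = frame[cols[i]], frame[cols[j]]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                continue
            if a[ok].nunique() == 1 or b[ok].nunique() == 1:
                if i == j:
                    mat[i, j] = 1.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = spearmanr(a[ok], b[ok]).statistic
            mat[i, j] = mat[j, i] = rho
    np.fill_diagonal(mat, 1.0)
    constant = [c for c in cols if frame[c].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"constant feature columns: {constant}", stacklevel=2)
    return pd.DataFrame(mat, index=cols, columns=cols)


def classify_regime(v: LongitudinalFeatureVector, config: AnalysisConfig) -> RegimeLabel:
    """Map a feature vector to its longitudinal regime.

    Total and deterministic: every vector gets exactly one of the seven
    labels, and the returned trace records each threshold comparison
    that drove the decision.
    """
    alpha = config.alpha
    trace = []

    core = [v.flatness, v.lb_min_p]
    if any(math.isnan(x) for x in core):
        trace.append("incomplete feature vector (flatness or Ljung-Box NaN)")
        return RegimeLabel("unclassified", trace)

    # (1) white noise: flat spectrum, no autocorrelation at any lag
    if v.flatness >= config.flatness_threshold and v.lb_all_p_above_alpha:
        trace.append(
            f"flatness {v.flatness:.3f} >= {config.flatness_threshold} "
            f"and all Ljung-Box p > {alpha}"
        )
        return RegimeLabel("white_noise", trace)

    # (2) non-noise gate: tonal spectrum AND autocorrelation somewhere
    if not (v.flatness < config.flatness_threshold and v.lb_min_p < alpha):
        trace.append(
            f"neither white noise nor autocorrelated-tonal "
            f"(flatness {v.flatness:.3f}, min LB p {v.lb_min_p:.3g})"
        )
        return RegimeLabel("unclassified", trace)
    trace.append(
        f"flatness {v.flatness:.3f} < {config.flatness_threshold} "
        f"and min Ljung-Box p {v.lb_min_p:.3g} < {alpha}"
    )

    # prevalence band
    if v.prevalence < config.prevalence_low:
        trace.append(f"prevalence {v.prevalence:.3f} < {config.prevalence_low}")
        return RegimeLabel("rare", trace)
    if v.prevalence > config.prevalence_high:
        band = "prevalent"
        trace.append(f"prevalence {v.prevalence:.3f} > {config.prevalence_high}")
    else:
        band = "temporal"
        trace.append(
            f"prevalence {v.prevalence:.3f} in "
            f"[{config.prevalence_low}, {config.prevalence_high}]"
        )

    # (3) stability split
    if math.isnan(v.adf_p) or math.isnan(v.kpss_p):
        trace.append("stationarity tests unavailable")
        return RegimeLabel("unclassified", trace)
    if v.adf_p < alpha and v.kpss_p > alpha:
        trace.append(f"ADF p {v.adf_p:.3g} < {alpha}, KPSS p {v.kpss_p:.3g} > {alpha}")
        return RegimeLabel(f"stable_{band}", trace)
    if v.adf_p > alpha and v.kpss_p < alpha:
        trace.append(f"ADF p {v.adf_p:.3g} > {alpha}, KPSS p {v.kpss_p:.3g} < {alpha}")
        return RegimeLabel(f"unstable_{band}", trace)
    trace.append(
        f"stationarity pattern matches no regime "
        f"(ADF p {v.adf_p:.3g}, KPSS p {v.kpss_p:.3g})"
    )
    return RegimeLabel("unclassified", trace)


def regime_abundance_series(
    table: AbundanceSeriesTable, labels: dict[str, str]
) -> pd.DataFrame:
    """Per-day relative abundance of each regime.

    Rows are days, columns regimes; each row sums to 1 unless the day's
    total count is zero (NaN row).
    """
    missing = set(table.asv_ids) - set(labels)
    if missing:
        raise ValueError(f"unlabeled ASVs: {sorted(missing)[:5]}")
    regimes = sorted(set(labels.values()))
    out = pd.DataFrame(0.0, index=table.data.index, columns=regimes)
    for asv in table.asv_ids:
        out[labels[asv]] += table.data[asv]
    totals = out.sum(axis=1)
    result = out.div(totals, axis=0)
    result[totals == 0] = np.nan
    return result
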