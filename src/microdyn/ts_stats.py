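"""Univariate time-series characterization.

This module answers the questions asked of every trajectory in the
pipeline — community-level alpha diversity and individual ASV series
alike:

* trend — OLS slope against a standardized time axis;
* serial dependence — sample ACF/PACF and the Ljung-Box portmanteau
  test at every lag up to a maximum (default 70);
* stationarity — ADF (unit-root null) and KPSS (stationarity null)
  combined into a joint verdict;
* noisiness — spectral flatness, the geometric-to-arithmetic mean
  ratio of framed power spectra (1 = white-noise-like, ~0 = tonal);
* volatility — mean conditional variance under a GARCH(1,1) model
  fitted by Gaussian maximum likelihood.

A series is called white noise when the Ljung-Box test fails to reject
at *every* lag and the flatness score reaches the configured threshold
(default 0.4).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize, signal
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import adfuller, kpss, pacf as sm_pacf

__all__ = [
    "linear_trend",
    "autocorrelation",
    "ljung_box",
    "stationarity_tests",
    "StationarityVerdict",
    "spectral_flatness",
    "white_noise_verdict",
    "WhiteNoiseVerdict",
    "garch_volatility",
    "GarchResult",
]


def linear_trend(series) -> tuple[float, np.ndarray]:
    """OLS slope of the series against standardized time.

    Time t = 0..n-1 is standardized to zero mean and unit variance
    before the fit, so slopes are comparable across series lengths.
    Returns the slope and the fitted trend line.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 points for a trend")
    if not np.isfinite(y).all():
        raise ValueError("series contains non-finite values")
    t = np.arange(len(y), dtype=float)
    t_std = (t - t.mean()) / t.std()
    slope, intercept = np.polyfit(t_std, y, 1)
    return float(slope), slope * t_std + intercept


def detrend_linear(series) -> np.ndarray:
    """Subtract the fitted linear trend (standardized-time OLS)."""
    y = np.asarray(series, dtype=float)
    _, fitted = linear_trend(y)
    return y - fitted


def autocorrelation(
    series, max_lag: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample ACF and PACF up to ``max_lag`` plus the large-sample
    confidence half-width ``z_{1-alpha/2}/sqrt(n)``."""
    y = np.asarray(series, dtype=float)
    if max_lag >= len(y):
        raise ValueError("max_lag must be smaller than the series length")
    acf_vals = sm_acf(y, nlags=max_lag, fft=True)
    pacf_vals = sm_pacf(y, nlags=min(max_lag, len(y) // 2 - 1), method="ywm")
    from scipy.stats import norm

    bound = float(norm.ppf(1 - alpha / 2) / np.sqrt(len(y)))
    return acf_vals, pacf_vals, bound


def ljung_box(series, lags: int) -> np.ndarray:
    """Ljung-Box p-value at each lag 1..lags.

    Small p-values indicate autocorrelation at (up to) that lag.
    """
    y = np.asarray(series, dtype=float)
    if len(y) <= lags:
        raise ValueError("series must be longer than the number of lags")
    if np.ptp(y) == 0:
        raise ValueError("constant series has undefined autocorrelation")
    result = acorr_ljungbox(y, lags=list(range(1, lags + 1)), return_df=True)
    return result["lb_pvalue"].to_numpy()


@dataclasses.dataclass
class StationarityVerdict:
    adf_p: float
    kpss_p: float
    alpha: float
    call: str  # "stationary" | "nonstationary" | "ambiguous"


def stationarity_tests(
    series, alpha: float = 0.05, kpss_regression: str = "c"
) -> StationarityVerdict:
    """Joint ADF + KPSS stationarity verdict.

    ADF's null is a unit root; KPSS's null is stationarity.  The series
    is called stationary only when ADF rejects *and* KPSS does not,
    nonstationary when the opposite pattern holds, and ambiguous when
    the two tests agree with each other (both reject or both fail).
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 points for unit-root tests")
    if not np.isfinite(y).all():
        raise ValueError("series contains non-finite values")
    if np.ptp(y) == 0:
        # A constant is trivially stationary; the tests themselves
        # degenerate, so short-circuit.
        return StationarityVerdict(0.0, 1.0, alpha, "stationary")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adf_p = float(adfuller(y, autolag="AIC")[1])
        kpss_p = float(kpss(y, regression=kpss_regression, nlags="auto")[1])
    if adf_p < alpha and kpss_p > alpha:
        call = "stationary"
    elif adf_p > alpha and kpss_p < alpha:
        call = "nonstationary"
    else:
        call = "ambiguous"
    return StationarityVerdict(adf_p, kpss_p, alpha, call)


def spectral_flatness(series, detrend: bool = True) -> float:
    """Frame-averaged spectral flatness score in [0, 1].

    The series is (optionally) linearly detrended, cut into Hann-
    windowed frames of length floor(n/2) hopped by half a frame, and
    each frame's power spectrum is summarized by its geometric mean
    divided by its arithmetic mean; the score is the mean over frames.
    White noise has a flat spectrum (score near exp(psi(1)) ~ 0.56);
    a pure tone concentrates power in one bin (score near 0).
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 8:
        raise ValueError("series too short for spectral analysis")
    if detrend:
        y = detrend_linear(y)
    if np.ptp(y) == 0:
        raise ValueError("constant (or fully detrended) series has no spectrum")
    win_len = len(y) // 2
    hop = max(1, win_len // 2)
    window = signal.windows.hann(win_len, sym=False)
    flatnesses = []
    for start in range(0, len(y) - win_len + 1, hop):
        frame = y[start : start + win_len] * window
        power = np.abs(np.fft.rfft(frame)) ** 2
        peak = power.max()
        if peak <= 0:
            continue
        # Relative floor keeps the score scale-invariant while bounding
        # log(0) for spectrally pure frames.
        power = np.maximum(power, peak * 1e-12)
        flatnesses.append(np.exp(np.mean(np.log(power))) / np.mean(power))
    if not flatnesses:
        raise ValueError("no usable frames (zero spectrum)")
    return float(np.mean(flatnesses))


@dataclasses.dataclass
class WhiteNoiseVerdict:
    lb_p_by_lag: np.ndarray
    flatness: float
    alpha: float
    flatness_threshold: float
    is_white_noise: bool


def white_noise_verdict(
    series,
    lags: int = 70,
    alpha: float = 0.05,
    flatness_threshold: float = 0.4,
) -> WhiteNoiseVerdict:
    """Joint white-noise call: no autocorrelation at any lag (Ljung-Box
    p > alpha for all lags) and flatness at or above the threshold.

    Series shorter than ``lags + 1`` points use the maximum feasible
    number of lags (length - 1).
    """
    y = np.asarray(series, dtype=float)
    usable_lags = min(lags, len(y) - 1)
    p_values = ljung_box(y, usable_lags)
    flat = spectral_flatness(y, detrend=True)
    is_wn = bool(p_values.min() > alpha and flat >= flatness_threshold)
    return WhiteNoiseVerdict(p_values, flat, alpha, flatness_threshold, is_wn)


@dataclasses.dataclass
class GarchResult:
    conditional_variance: np.ndarray
    volatility: float
    params: tuple  # (omega, alpha, beta)
    converged: bool


def _garch_cond_var(resid: np.ndarray, omega: float, a: float, b: float) -> np.ndarray:
    sigma2 = np.empty_like(resid)
    sigma2[0] = resid.var()
    for t in range(1, len(resid)):
        sigma2[t] = omega + a * resid[t - 1] ** 2 + b * sigma2[t - 1]
    return sigma2


def garch_volatility(series) -> GarchResult:
    """Fit a GARCH(1,1) model by Gaussian maximum likelihood and return
    the conditional-variance path and its mean (the series' volatility).

    sigma2_t = omega + alpha * r_{t-1}^2 + beta * sigma2_{t-1} on the
    mean-subtracted series r.  Non-convergence is flagged with a NaN
    volatility instead of raising, so batch runs never abort.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 50:
        raise ValueError("need at least 50 points to fit GARCH(1,1)")
    resid = y - y.mean()
    var0 = resid.var()
    if var0 <= 0:
        return GarchResult(np.zeros_like(resid), float("nan"), (0, 0, 0), False)

    def nll(theta):
        omega, a, b = theta
        if omega <= 0 or a < 0 or b < 0 or a + b >= 0.9999:
            return 1e12
        sigma2 = _garch_cond_var(resid, omega, a, b)
        if (sigma2 <= 0).any():
            return 1e12
        return 0.5 * np.sum(np.log(sigma2) + resid**2 / sigma2)

    best = None
    for a0, b0 in ((0.05, 0.90), (0.10, 0.50), (0.02, 0.02)):
        omega0 = var0 * max(1 - a0 - b0, 0.01)
        res = optimize.minimize(
            nll,
            x0=np.array([omega0, a0, b0]),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        return GarchResult(np.full_like(resid, np.nan), float("nan"), (0, 0, 0), False)
    omega, a, b = best.x
    sigma2 = _garch_cond_var(resid, omega, a, b)
    return GarchResult(sigma2, float(sigma2.mean()), (float(omega), float(a), float(b)), True)
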