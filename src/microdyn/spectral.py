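"""FFT seasonality detection and seasonal reconstruction scoring.

Dominant seasonalities of a (stationarized) series are the discrete
Fourier bins with the largest amplitudes; a bin k of an n-point series
corresponds to a period of n/k days.  Reconstructing the series from
only its top-N bins (inverse FFT with all other bins zeroed) and rank-
correlating the reconstruction with the input yields the *seasonal
reconstruction score*: near 1 for a genuinely periodic series, low for
aperiodic noise.  A series is called seasonal when the score with five
modes reaches 0.5.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import spearmanr

from .ts_stats import StationarityVerdict, detrend_linear

__all__ = [
    "prepare_series",
    "fft_dominant_seasonalities",
    "reconstruct_from_modes",
    "seasonal_reconstruction_score",
    "score_curve",
    "SeasonalityProfile",
]


def prepare_series(series, verdict: StationarityVerdict) -> tuple[np.ndarray, str]:
    """Stationarize a series before spectral analysis.

    The transformation is picked from the joint ADF/KPSS outcome:

    * KPSS rejects stationarity while ADF rejects the unit root
      (trend-stationary pattern) -> subtract the linear trend;
    * both tests point at stationarity -> first-difference;
    * otherwise (unit root present) -> first-difference.

    Returns the prepared series and the mode used ("detrend" |
    "difference").
    """
    y = np.asarray(series, dtype=float)
    kpss_rejects = verdict.kpss_p < verdict.alpha
    adf_rejects = verdict.adf_p < verdict.alpha
    if kpss_rejects and adf_rejects:
        return detrend_linear(y), "detrend"
    return np.diff(y), "difference"


@dataclasses.dataclass
class SeasonalityProfile:
    periods: np.ndarray  # days, sorted by descending amplitude
    amplitudes: np.ndarray
    n_modes_used: int = 0
    reconstruction: np.ndarray | None = None
    score: float = float("nan")

    @property
    def dominant_period(self) -> float:
        return float(self.periods[0]) if len(self.periods) else float("nan")


def fft_dominant_seasonalities(series) -> SeasonalityProfile:
    """Rank the Fourier bins of a prepared series by amplitude.

    The DC term is excluded; amplitude ties are broken toward longer
    periods (lower frequencies).
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 8:
        raise ValueError("series too short for FFT analysis")
    if np.ptp(y) == 0:
        raise ValueError("constant series has no seasonalities")
    n = len(y)
    spectrum = np.fft.rfft(y)
    k = np.arange(1, len(spectrum))  # skip DC
    amplitudes = np.abs(spectrum[1:])
    periods = n / k
    # descending amplitude; ties -> longer period (smaller k) first
    order = np.lexsort((k, -amplitudes))
    return SeasonalityProfile(periods=periods[order], amplitudes=amplitudes[order])


def reconstruct_from_modes(series, n_modes: int) -> np.ndarray:
    """Inverse FFT keeping only the ``n_modes`` largest-amplitude bins.

    The DC bin is always retained so the mean is preserved; keeping
    every available mode inverts the FFT exactly.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    spectrum = np.fft.rfft(y)
    available = len(spectrum) - 1
    if not (1 <= n_modes <= available):
        raise ValueError(f"n_modes must be in [1, {available}], got {n_modes}")
    amplitudes = np.abs(spectrum[1:])
    k = np.arange(1, len(spectrum))
    order = np.lexsort((k, -amplitudes))
    keep = np.zeros(len(spectrum), dtype=bool)
    keep[0] = True
    keep[1 + order[:n_modes]] = True
    filtered = np.where(keep, spectrum, 0.0)
    return np.fft.irfft(filtered, n=n)


def seasonal_reconstruction_score(series, n_modes: int) -> float:
    """Spearman correlation between a series and its top-``n_modes``
    Fourier reconstruction.  NaN when the reconstruction is constant
    (undefined rank correlation)."""
    y = np.asarray(series, dtype=float)
    recon = reconstruct_from_modes(y, n_modes)
    if np.ptp(recon) == 0 or np.ptp(y) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(y, recon).statistic
    return float(rho)


def score_curve(series, max_modes: int = 10) -> np.ndarray:
    """Seasonal reconstruction score at each N in 1..max_modes.

    The curve need not be monotone: adding a mode improves the L2
    reconstruction but can shuffle ranks.
    """
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")
    y = np.asarray(series, dtype=float)
    available = len(np.fft.rfft(y)) - 1
    upper = min(max_modes, available)
    return np.array(
        [seasonal_reconstruction_score(y, n) for n in range(1, upper + 1)]
    )


def community_seasonality(
    series, n_days: int = 150, n_modes: int = 5
) -> SeasonalityProfile:
    """Whole-community seasonality of an alpha-diversity trajectory.

    Truncates to the first ``n_days`` days, linearly detrends, ranks
    Fourier bins, and scores the top-``n_modes`` reconstruction.
    """
    y = np.asarray(series, dtype=float)[:n_days]
    prepared = detrend_linear(y)
    profile = fft_dominant_seasonalities(prepared)
    profile.n_modes_used = n_modes
    profile.reconstruction = reconstruct_from_modes(prepared, n_modes)
    profile.score = seasonal_reconstruction_score(prepared, n_modes)
    return profile
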