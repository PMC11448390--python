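"""Dynamic ARIMAX forecasting of alpha diversity.

The model is an ARIMA(p, d, q) whose single exogenous regressor is a
seasonal wave: the top-N Fourier modes of the (detrended) training
series, extended periodically over the forecast horizon.  Orders and N
are selected by grid search on a held-out tail of the training window,
scored by MAPE (ties broken by Wasserstein distance, then by p+q).
Plain SARIMA-style multiplicative seasonality is deliberately not used;
gut-microbiome series carry several incommensurate periods at once,
which the additive Fourier wave captures directly.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from statsmodels.tsa.arima.model import ARIMA

from .ts_stats import linear_trend

__all__ = [
    "fourier_exogenous_wave",
    "fit_forecast",
    "evaluate_forecast",
    "ForecastModelSpec",
    "ForecastResult",
    "default_grid",
]


@dataclasses.dataclass(frozen=True)
class ForecastModelSpec:
    p: int
    d: int
    q: int
    n_modes: int
    train_days: int = 80

    def __post_init__(self) -> None:
        if self.d not in (0, 1, 2):
            raise ValueError("d must be 0, 1 or 2")


@dataclasses.dataclass
class ForecastResult:
    fitted: np.ndarray
    predictions: np.ndarray
    mape: float
    wasserstein: float
    window_metrics: pd.DataFrame  # columns: window, mape, wasserstein


def default_grid() -> list[tuple[int, int, int, int]]:
    """Full search grid: p 0-4, d {0,1}, q 0-10, N 1-6 (covers the
    optima typically selected on year-long daily series)."""
    return list(itertools.product(range(5), (0, 1), range(11), range(1, 7)))


def fourier_exogenous_wave(train, n_modes: int, horizon: int) -> np.ndarray:
    """Seasonal wave over the training window plus a forecast horizon.

    The training series is linearly detrended, its top-``n_modes``
    Fourier bins are kept, and the corresponding sinusoids are
    evaluated at every t in 0..len(train)+horizon-1, which extends each
    mode periodically beyond the training window.  ``n_modes = 0``
    yields a zero wave.
    """
    y = np.asarray(train, dtype=float)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    n = len(y)
    t = np.arange(n + horizon, dtype=float)
    if n_modes == 0:
        return np.zeros(n + horizon)
    _, fitted = linear_trend(y)
    spectrum = np.fft.rfft(y - fitted)
    available = len(spectrum) - 1
    if n_modes > available:
        raise ValueError(f"n_modes must be <= {available}")
    amplitudes = np.abs(spectrum[1:])
    k_all = np.arange(1, len(spectrum))
    order = np.lexsort((k_all, -amplitudes))
    wave = np.zeros(n + horizon)
    nyquist = n // 2 if n % 2 == 0 else -1
    for k in k_all[order[:n_modes]]:
        coeff = spectrum[k]
        weight = 1.0 if k == nyquist else 2.0
        wave += (weight / n) * np.abs(coeff) * np.cos(
            2 * np.pi * k * t / n + np.angle(coeff)
        )
    return wave


def evaluate_forecast(
    true, predicted, window: int = 20
) -> tuple[float, float, pd.DataFrame]:
    """MAPE (percent), Wasserstein distance, and per-window metrics.

    Windows are consecutive non-overlapping blocks of ``window`` days
    (last partial block kept).  Days with a true value of zero are
    excluded from MAPE with a warning.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(t) != len(p):
        raise ValueError("true and predicted must have equal length")

    def _mape(a, b):
        nonzero = a != 0
        if not nonzero.all():
            warnings.warn("zero true values excluded from MAPE", stacklevel=3)
        if not nonzero.any():
            return float("nan")
        return float(np.mean(np.abs(a[nonzero] - b[nonzero]) / np.abs(a[nonzero])) * 100)

    rows = []
    for w, start in enumerate(range(0, len(t), window)):
        sl = slice(start, start + window)
        rows.append(
            {
                "window": w,
                "start_day": start,
                "mape": _mape(t[sl], p[sl]),
                "wasserstein": float(wasserstein_distance(t[sl], p[sl])),
            }
        )
    return _mape(t, p), float(wasserstein_distance(t, p)), pd.DataFrame(rows)


def _fit_arima(y, order, exog):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(y, order=order, exog=exog)
        return model.fit(method_kwargs={"maxiter": 200})


def fit_forecast(
    train,
    test,
    grid=None,
    validation_fraction: float = 0.2,
    cv_window: int = 20,
) -> tuple[ForecastModelSpec, ForecastResult]:
    """Grid-search an ARIMAX(p, d, q) + Fourier-wave model and forecast.

    Each grid cell is fitted on the training window minus a held-out
    tail (``validation_fraction`` of the window) and scored by MAPE on
    that tail; the winner is refitted on the full training window and
    used to predict the test horizon.  Non-convergent cells are skipped.
    """
    y_train = np.asarray(train, dtype=float)
    y_test = np.asarray(test, dtype=float)
    if len(y_train) < 30:
        raise ValueError("need at least 30 training days")
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("empty search grid")

    val_len = max(1, int(round(validation_fraction * len(y_train))))
    sub, val = y_train[:-val_len], y_train[-val_len:]

    scored = []
    for p, d, q, n_modes in grid:
        try:
            wave = fourier_exogenous_wave(sub, n_modes, val_len)
            fit = _fit_arima(sub, (p, d, q), wave[: len(sub)])
            pred = np.asarray(
                fit.forecast(steps=val_len, exog=wave[len(sub) :].reshape(-1, 1))
            )
            if not np.isfinite(pred).all():
                continue
            mape, wdist, _ = evaluate_forecast(val, pred, window=cv_window)
        except Exception:
            continue
        scored.append(((mape, wdist, p + q), (p, d, q, n_modes)))
    if not scored:
        raise RuntimeError("every grid cell failed to fit")
    scored.sort(key=lambda item: item[0])
    p, d, q, n_modes = scored[0][1]
    spec = ForecastModelSpec(p=p, d=d, q=q, n_modes=n_modes, train_days=len(y_train))

    horizon = len(y_test)
    wave = fourier_exogenous_wave(y_train, n_modes, horizon)
    fit = _fit_arima(y_train, (p, d, q), wave[: len(y_train)])
    if horizon:
        predictions = np.asarray(
            fit.forecast(steps=horizon, exog=wave[len(y_train) :].reshape(-1, 1))
        )
        mape, wdist, windows = evaluate_forecast(y_test, predictions, window=cv_window)
    else:
        predictions = np.array([])
        mape, wdist = float("nan"), float("nan")
        windows = pd.DataFrame(columns=["window", "start_day", "mape", "wasserstein"])
    result = ForecastResult(
        fitted=np.asarray(fit.fittedvalues),
        predictions=predictions,
        mape=mape,
        wasserstein=wdist,
        window_metrics=windows,
    )
    return spec, result
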