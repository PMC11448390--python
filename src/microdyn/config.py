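"""Global analysis configuration.

Every threshold used anywhere in the pipeline flows from a single
:class:`AnalysisConfig` instance so that no stage hardcodes a constant.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the longitudinal analysis pipeline.

    Attributes
    ----------
    rarefaction_depth : int
        Even sampling depth (reads per day) used for rarefaction.
    lb_lags : int
        Maximum lag of the Ljung-Box autocorrelation test battery.
    alpha : float
        Significance level shared by all hypothesis tests.
    flatness_threshold : float
        Spectral-flatness score above which a series is noise-like.
    seasonal_modes : int
        Number of dominant Fourier modes used for seasonal reconstruction.
    seasonal_score_threshold : float
        Seasonal reconstruction score at or above which a taxon is
        called seasonal.
    prevalence_low, prevalence_high : float
        Occupancy band edges separating rare / temporal / prevalent taxa.
    rho_threshold : float
        Proportionality cut-off for co-occurrence graph edges.
    clr_pseudocount : float
        Pseudocount added to counts before the centered log-ratio
        transform.
    train_days : int
        Length of the forecasting training window, in days.
    cv_window : int
        Width of the consecutive evaluation windows for forecast
        cross-validation, in days.
    rng_seed : int
        Seed for every stochastic stage (rarefaction, simulation).
    """

    rarefaction_depth: int = 18_000
    lb_lags: int = 70
    alpha: float = 0.05
    flatness_threshold: float = 0.4
    seasonal_modes: int = 5
    seasonal_score_threshold: float = 0.5
    prevalence_low: float = 0.1
    prevalence_high: float = 0.9
    rho_threshold: float = 0.6
    clr_pseudocount: float = 1.0
    train_days: int = 80
    cv_window: int = 20
    rng_seed: int = 0
    kpss_regression: str = "c"  # "c" = level-stationary null, "ct" = trend

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_low < self.prevalence_high < 1.0):
            raise ValueError(
                "prevalence band must satisfy 0 < low < high < 1, got "
                f"({self.prevalence_low}, {self.prevalence_high})"
            )
        if not (0.0 <= self.rho_threshold <= 1.0):
            raise ValueError("rho_threshold must lie in [0, 1]")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.kpss_regression not in ("c", "ct"):
            raise ValueError("kpss_regression must be 'c' or 'ct'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a flat YAML (or ``key: value``) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
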