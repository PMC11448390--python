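import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdyn import (
    AnalysisConfig,
    build_feature_vector,
    classify_regime,
    feature_correlation_matrix,
    feature_table,
    regime_abundance_series,
)
from microdyn.features import FEATURE_NAMES, REGIMES, LongitudinalFeatureVector


def make_vector(**overrides):
    base = dict(
        asv_id="x",
        mean_abundance=10.0,
        std_abundance=2.0,
        prevalence=0.5,
        trend=0.0,
        lb_min_p=0.001,
        lb_all_p_above_alpha=False,
        flatness=0.2,
        adf_p=0.01,
        kpss_p=0.2,
        dominant_period=7.0,
        seasonal_score=0.3,
        pc1_loading=0.1,
        pc2_loading=0.1,
    )
    base.update(overrides)
    return LongitudinalFeatureVector(**base)


class TestBuildFeatureVector:
    def test_all_zero_series_is_unclassifiable(self, config):
        v = build_feature_vector(np.zeros(100), "z", config)
        assert v.prevalence == 0.0
        assert math.isnan(v.flatness)
        assert classify_regime(v, config).label == "unclassified"

    def test_vector_has_twelve_features(self, config, rng):
        v = build_feature_vector(rng.poisson(50, 120), "a", config, loadings=(0.1, 0.2))
        frame = v.as_series()
        assert len(frame) == 12
        assert list(frame.index) == FEATURE_NAMES
        assert np.isfinite(frame.drop("seasonal_score").astype(float)).all()

    def test_degenerate_fields_become_nan_not_errors(self, config):
        # constant nonzero series: Ljung-Box and flatness are undefined
        v = build_feature_vector(np.full(100, 7.0), "c", config)
        assert v.prevalence == 1.0
        assert math.isnan(v.lb_min_p)
        assert math.isnan(v.flatness)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "fields,expected",
        [
            # the threshold-table rows for each regime
            (dict(flatness=0.6, lb_min_p=0.3, lb_all_p_above_alpha=True,
                  prevalence=0.05), "white_noise"),
            (dict(flatness=0.1, lb_min_p=0.001, prevalence=0.95,
                  adf_p=0.01, kpss_p=0.2), "stable_prevalent"),
            (dict(flatness=0.1, lb_min_p=0.001, prevalence=0.5,
                  adf_p=0.3, kpss_p=0.01), "unstable_temporal"),
            (dict(flatness=0.1, lb_min_p=0.001, prevalence=0.95,
                  adf_p=0.3, kpss_p=0.01), "unstable_prevalent"),
            (dict(flatness=0.1, lb_min_p=0.001, prevalence=0.5,
                  adf_p=0.01, kpss_p=0.2), "stable_temporal"),
            (dict(flatness=0.1, lb_min_p=0.001, prevalence=0.05), "rare"),
        ],
    )
    def test_threshold_rules(self, config, fields, expected):
        assert classify_regime(make_vector(**fields), config).label == expected

    def test_conflicting_stationarity_is_unclassified(self, config):
        v = make_vector(prevalence=0.95, adf_p=0.01, kpss_p=0.01)
        label = classify_regime(v, config)
        assert label.label == "unclassified"
        assert any("matches no regime" in t for t in label.trace)

    def test_nan_features_are_unclassified(self, config):
        v = make_vector(flatness=float("nan"))
        assert classify_regime(v, config).label == "unclassified"

    def test_deterministic(self, config):
        v = make_vector()
        assert (
            classify_regime(v, config).label == classify_regime(v, config).label
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        flatness=st.one_of(st.floats(0, 1), st.just(float("nan"))),
        lb_min_p=st.one_of(st.floats(0, 1), st.just(float("nan"))),
        prevalence=st.floats(0, 1),
        adf_p=st.floats(0, 1),
        kpss_p=st.floats(0, 1),
    )
    def test_total_function_over_feature_space(
        self, flatness, lb_min_p, prevalence, adf_p, kpss_p
    ):
        config = AnalysisConfig()
        v = make_vector(
            flatness=flatness,
            lb_min_p=lb_min_p,
            lb_all_p_above_alpha=bool(lb_min_p > 0.05)
            if not math.isnan(lb_min_p)
            else False,
            prevalence=prevalence,
            adf_p=adf_p,
            kpss_p=kpss_p,
        )
        label = classify_regime(v, config)
        assert label.label in REGIMES
        assert label.trace


class TestFeatureCorrelation:
    def test_unit_diagonal_and_symmetry(self, rarefied_subject, config):
        table, _ = rarefied_subject
        vectors = feature_table(table, config)
        mat = feature_correlation_matrix(vectors)
        assert mat.shape == (12, 12)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T, equal_nan=True)

    def test_expected_feature_couplings_on_synthetic_mix(
        self, rarefied_subject, config
    ):
        """Prevalent taxa carry high means and structured (non-flat)
        spectra, so prevalence correlates positively with mean
        abundance and negatively with flatness."""
        table, _ = rarefied_subject
        vectors = feature_table(table, config)
        mat = feature_correlation_matrix(vectors)
        assert mat.loc["prevalence", "mean_abundance"] > 0.5
        assert mat.loc["prevalence", "flatness"] < 0

    def test_too_few_vectors_rejected(self, config, rng):
        vectors = [
            build_feature_vector(rng.poisson(5, 60), "a", config)
        ]
        with pytest.raises(ValueError):
            feature_correlation_matrix(vectors)


class TestRegimeAbundance:
    def test_single_regime_is_unity(self, tiny_table):
        out = regime_abundance_series(
            tiny_table, {"A": "rare", "B": "rare"}
        )
        assert np.allclose(out["rare"].dropna(), 1.0)

    def test_two_equal_regimes_split_evenly(self):
        from microdyn import AbundanceSeriesTable

        df = pd.DataFrame({"A": [5, 5], "B": [5, 5]}, index=[0, 1])
        out = regime_abundance_series(
            AbundanceSeriesTable(df), {"A": "rare", "B": "white_noise"}
        )
        assert np.allclose(out.to_numpy(), 0.5)

    def test_rows_sum_to_one_when_day_nonzero(self, rarefied_subject, config):
        table, truth = rarefied_subject
        labels = dict(truth["regime"])
        out = regime_abundance_series(table, labels)
        sums = out.sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_zero_day_becomes_nan(self):
        from microdyn import AbundanceSeriesTable

        df = pd.DataFrame({"A": [5, 0], "B": [5, 0]}, index=[0, 1])
        out = regime_abundance_series(
            AbundanceSeriesTable(df), {"A": "rare", "B": "rare"}
        )
        assert out.iloc[1].isna().all()

    def test_unlabeled_asv_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="unlabeled"):
            regime_abundance_series(tiny_table, {"A": "rare"})

    def test_stable_regime_dominates_abundance(self, rarefied_subject):
        """Stable prevalent taxa are few but carry most of the reads."""
        table, truth = rarefied_subject
        out = regime_abundance_series(table, dict(truth["regime"]))
        dominant_days = (out.idxmax(axis=1) == "stable_prevalent").mean()
        assert dominant_days >= 0.8
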