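"""Correlation matrix, Mann-Whitney tests, feature preparation, logistic models."""

import math

import numpy as np
import pandas as pd
import pytest

from acticomplex import (
    ValidationError,
    compare_groups,
    format_report,
    logistic_models,
    mann_whitney_u,
    pearson_correlation_matrix,
    prepare_features,
)
from acticomplex.stats import GroupReport


def feature_table(rng, n_per_group=12, shift=0.0):
    """A synthetic feature table with a controllable group shift."""
    rows = []
    for g, label in ((0, "patient"), (1, "healthy")):
        for i in range(n_per_group):
            base = rng.normal(0, 1)
            rows.append(
                {
                    "subject_id": f"{label[0].upper()}{i:02d}",
                    "group": label,
                    "age": rng.normal(45, 10),
                    "sex": "male" if rng.random() < 0.5 else "female",
                    "avg": 0.05 + 0.01 * base + shift * g * 0.01,
                    "sd": 0.05 + 0.005 * rng.normal(),
                    "cov": 1.0 + 0.2 * rng.normal(),
                    "ac1": 0.5 + 0.1 * rng.normal(),
                    "corrdim": 2.0 + 0.3 * rng.normal() - shift * g,
                    "k_ar": 1 / (1 + math.exp(-(-1.5 + 0.3 * rng.normal() - shift * g))),
                    "k_ra": 1 / (1 + math.exp(-(-2.0 + 0.3 * rng.normal() + shift * g))),
                }
            )
    return pd.DataFrame(rows)


class TestPearson:
    def test_self_and_negated_correlation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"avg": x, "sd": -x, "cov": x**2})
        rho, p = pearson_correlation_matrix(df, columns=("avg", "sd", "cov"))
        assert rho.loc["avg", "avg"] == 1.0
        assert rho.loc["avg", "sd"] == pytest.approx(-1.0)

    def test_hand_computed_product_moment(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 8.0])
        df = pd.DataFrame({"avg": x, "sd": y})
        rho, p = pearson_correlation_matrix(df, columns=("avg", "sd"))
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert rho.loc["avg", "sd"] == pytest.approx(expected, rel=1e-12)

    def test_pairwise_complete_and_degenerate(self):
        df = pd.DataFrame(
            {
                "avg": [1.0, 2.0, 3.0, np.nan, 5.0],
                "sd": [2.0, 4.0, 6.0, 8.0, 10.0],
                "cov": [1.0, 1.0, 1.0, 1.0, 1.0],  # zero variance
            }
        )
        rho, p = pearson_correlation_matrix(df, columns=("avg", "sd", "cov"))
        assert rho.loc["avg", "sd"] == pytest.approx(1.0)
        assert np.isnan(rho.loc["avg", "cov"])


class TestMannWhitney:
    def test_fully_separated_exact_enumeration(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p == pytest.approx(2.0 / 6.0)

    def test_identical_samples_midrank_u(self):
        x = [1.0, 2.0, 3.0]
        res = mann_whitney_u(x, x)
        assert res.u == pytest.approx(len(x) * len(x) / 2.0)

    def test_complementarity_identity(self, rng):
        for _ in range(5):
            x = rng.normal(size=rng.integers(3, 8))
            y = rng.normal(size=rng.integers(3, 8))
            ux = mann_whitney_u(x, y).u
            uy = mann_whitney_u(y, x).u
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_exact_and_asymptotic_agree_moderately(self, rng):
        # n1 = n2 = 10 null data: the two branches should be within ~10%
        # (deep-tail p-values necessarily diverge more)
        for _ in range(10):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            p_exact = mann_whitney_u(x, y, method="exact").p
            p_asym = mann_whitney_u(x, y, method="asymptotic").p
            assert p_asym == pytest.approx(p_exact, rel=0.10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="nonempty"):
            mann_whitney_u([], [1.0])


class TestPrepareFeatures:
    def test_logit_midpoint_is_zero_and_constant_column_rejected(self, rng):
        assert np.log(0.5 / (1 - 0.5)) == 0.0  # the transform's symmetry point
        df = feature_table(rng)
        df["k_ar"] = 0.5  # constant transformed column cannot be z-scored
        with pytest.raises(ValidationError):
            prepare_features(df)

    def test_logit_and_zscore_columns(self, rng):
        df = feature_table(rng)
        prepared = prepare_features(df)
        t = prepared.table
        k = df.loc[t.index, "k_ar"]
        np.testing.assert_allclose(t["logit_k_ar"], np.log(k / (1 - k)))
        # z-scored columns have mean 0, SD 1 before trimming
        full_z = (df["logit_k_ar"] if "logit_k_ar" in df else np.log(df.k_ar / (1 - df.k_ar)))
        z = (full_z - full_z.mean()) / full_z.std(ddof=1)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_planted_outlier_removed(self, rng):
        df = feature_table(rng, n_per_group=10)
        logit = np.log(df["k_ar"] / (1 - df["k_ar"]))
        # plant a ~4 SD outlier on the logit scale
        target = logit.mean() + 4.5 * logit.std(ddof=1)
        df.loc[7, "k_ar"] = 1 / (1 + np.exp(-target))
        prepared = prepare_features(df)
        assert df.loc[7, "subject_id"] in prepared.removed["subject_id"].tolist()
        assert df.loc[7, "subject_id"] not in prepared.table["subject_id"].tolist()

    def test_k_outside_unit_interval_rejected(self, rng):
        df = feature_table(rng)
        df.loc[0, "k_ra"] = 1.0
        with pytest.raises(ValidationError, match="k_ra"):
            prepare_features(df)


class TestLogisticModels:
    @staticmethod
    def _two_by_two_frame():
        # contingency a=8 (healthy, exposed), b=2, c=3, d=7: OR = 56/6
        rows = []
        for group, x, count in (
            ("healthy", 1.0, 8),
            ("healthy", 0.0, 2),
            ("patient", 1.0, 3),
            ("patient", 0.0, 7),
        ):
            rows += [{"group": group, "x": x}] * count
        return pd.DataFrame(rows)

    def test_two_by_two_odds_ratio_closed_form(self):
        import statsmodels.api as sm

        df = self._two_by_two_frame()
        y = (df["group"] == "healthy").astype(float)
        res = sm.Logit(y, sm.add_constant(df[["x"]])).fit(disp=0)
        assert float(np.exp(res.params["x"])) == pytest.approx(56.0 / 6.0, abs=1e-6)

    def test_independent_predictor_or_one(self):
        import statsmodels.api as sm

        rows = []
        for group in ("healthy", "patient"):
            for x, count in ((1.0, 5), (0.0, 5)):
                rows += [{"group": group, "x": x}] * count
        df = pd.DataFrame(rows)
        y = (df["group"] == "healthy").astype(float)
        res = sm.Logit(y, sm.add_constant(df[["x"]])).fit(disp=0)
        assert float(np.exp(res.params["x"])) == pytest.approx(1.0, abs=1e-9)

    def test_aic_bic_match_hand_summed_likelihood(self, rng):
        df = feature_table(rng, n_per_group=15, shift=1.0)
        prepared = prepare_features(df)
        comparison = logistic_models(prepared)
        m1 = comparison.models[1]
        k = len(m1.covariates) + 1  # + intercept
        assert m1.aic == pytest.approx(2 * k - 2 * m1.log_likelihood, rel=1e-9)
        assert m1.bic == pytest.approx(k * np.log(m1.n_used) - 2 * m1.log_likelihood, rel=1e-9)

    def test_hand_summed_log_likelihood(self):
        import statsmodels.api as sm

        df = self._two_by_two_frame()
        y = (df["group"] == "healthy").astype(float).to_numpy()
        X = sm.add_constant(df[["x"]])
        res = sm.Logit(y, X).fit(disp=0)
        eta = X.to_numpy() @ res.params.to_numpy()
        p = 1 / (1 + np.exp(-eta))
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert res.llf == pytest.approx(ll, rel=1e-9)
        assert res.aic == pytest.approx(2 * 2 - 2 * ll, rel=1e-9)

    def test_aic_ordering_invariant_to_affine_rescaling(self, rng):
        df = feature_table(rng, n_per_group=15, shift=0.8)
        base = logistic_models(prepare_features(df))
        scaled = df.copy()
        scaled["avg"] = scaled["avg"] * 1000 + 5
        scaled["corrdim"] = scaled["corrdim"] / 7 - 3
        rescaled = logistic_models(prepare_features(scaled))
        order_a = sorted(base.models, key=lambda m: base.models[m].aic)
        order_b = sorted(rescaled.models, key=lambda m: rescaled.models[m].aic)
        assert order_a == order_b

    def test_separation_reported_not_raised(self, rng):
        df = feature_table(rng, n_per_group=10)
        df["corrdim"] = np.where(df["group"] == "healthy", 1.0, 3.0) + rng.normal(
            0, 1e-6, len(df)
        )
        comparison = logistic_models(prepare_features(df))
        m2 = comparison.models[2]
        assert m2.warnings  # separation or failed fit is reported in-band


class TestCompareGroups:
    def test_identical_groups_no_direction(self, rng):
        df = feature_table(rng, n_per_group=6)
        mirrored = df.copy()
        half = df[df["group"] == "patient"].copy()
        mirrored = pd.concat(
            [half.assign(group="healthy", subject_id=half.subject_id + "h"), half],
            ignore_index=True,
        )
        report = compare_groups(mirrored, fit_models=False)
        for c in report.comparisons:
            assert c.direction == "none"
            assert c.p == pytest.approx(1.0, abs=0.05)

    def test_shifted_groups_detected(self, rng):
        df = feature_table(rng, n_per_group=12, shift=1.5)
        report = compare_groups(df, fit_models=False)
        frame = report.comparison_frame()
        assert frame.loc["corrdim", "direction"] == "healthy_lower"
        assert frame.loc["corrdim", "p"] < 0.01

    def test_report_serializes_and_formats(self, rng):
        df = feature_table(rng, n_per_group=8, shift=1.0)
        report = compare_groups(df, fit_models=True)
        text = format_report(report)
        assert "Mann-Whitney" in text and "Model 2" in text
        payload = report.to_json()
        assert '"comparisons"' in payload

    def test_missing_group_rejected(self, rng):
        df = feature_table(rng)
        with pytest.raises(ValidationError, match="healthy"):
            compare_groups(df[df["group"] == "patient"], fit_models=False)
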