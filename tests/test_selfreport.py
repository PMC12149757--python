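"""Contrast scheme, design construction, and the mixed-regression sampler."""

import numpy as np
import pandas as pd
import pytest

from advisdt import (
    ContrastScheme,
    ProfileDistribution,
    RegressionSpec,
    build_design_matrix,
    fit_mixed_regression,
    selfreport_means,
    simulate_experiment,
)
from conftest import small_config

REDUCED = dict(chains=4, draws=1500, tune=500)


def step_records(n_per_cond=20, mus=(5, 5, 3, 3, 3), noise=0.0, seed=0,
                 item="trust"):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(2 * n_per_cond):
        cond = "distrust" if i % 2 else "information-only"
        for t, mu in zip(range(1, 6), mus):
            r = int(np.clip(round(mu + rng.normal(0, noise)), 1, 7))
            recs.append(dict(participant_id=f"p{i:03d}", condition=cond,
                             timepoint=t, item=item, rating=r))
    return pd.DataFrame(recs)


class TestContrastScheme:
    def test_printed_weight_layout(self):
        w = ContrastScheme().weights
        assert w[1].tolist() == [-1, -1, 2, 0, 0]  # weight 2 on time point 3
        assert np.allclose(w.sum(axis=1), 0.0)
        assert np.linalg.matrix_rank(w) == 4

    def test_row_overlap_is_a_property_of_the_matrix(self):
        """Rows 2 and 3 share time point 3: their dot product is 4, not 0."""
        w = ContrastScheme().weights
        gram = w @ w.T
        assert gram[1, 2] == 4.0
        off = gram[~np.eye(4, dtype=bool)]
        assert set(np.abs(off)) == {0.0, 4.0}

    def test_coding_round_trip_reproduces_weights(self):
        """Pseudo-inverting the design coding returns the printed weights."""
        scheme = ContrastScheme()
        recovered = np.linalg.pinv(scheme.coding())
        assert np.allclose(recovered, scheme.hypothesis_matrix(), atol=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to zero"):
            ContrastScheme(np.eye(4, 5))


class TestDesignMatrix:
    def test_coefficients_estimate_the_weighted_comparisons(self):
        """OLS on the design returns exactly weights @ cell means."""
        df = step_records(n_per_cond=2)
        X, y, _ = build_design_matrix(df)
        beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        est = dict(zip(X.columns, beta))
        mus = np.array([5, 5, 3, 3, 3], dtype=float)
        for k in range(4):
            expected = ContrastScheme().weights[k] @ mus
            assert est[f"contrast{k + 1}"] == pytest.approx(expected, abs=1e-9)
        assert est["Intercept"] == pytest.approx(mus.mean(), abs=1e-9)

    def test_contrast_columns_orthogonal_to_intercept(self):
        X, _, _ = build_design_matrix(step_records(n_per_cond=3))
        for k in range(1, 5):
            assert X[f"contrast{k}"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_missing_timepoint_names_participant(self):
        df = step_records(n_per_cond=2)
        df = df[~((df.participant_id == "p001") & (df.timepoint == 4))]
        with pytest.raises(ValueError, match="p001"):
            build_design_matrix(df)

    def test_label_swap_flips_condition_and_interactions_only(self):
        """With centered coding, recoding condition negates its columns."""
        df = step_records(n_per_cond=3, noise=0.7, seed=3)
        swapped = df.assign(condition=df.condition.map({
            "distrust": "information-only", "information-only": "distrust"}))
        prior_prec = np.eye(10) / 25.0

        def ridge(frame):
            X, y, _ = build_design_matrix(frame, condition_coding="centered")
            A = X.to_numpy()
            return X.columns, np.linalg.solve(A.T @ A + prior_prec, A.T @ y)

        cols, b0 = ridge(df)
        _, b1 = ridge(swapped)
        for j, name in enumerate(cols):
            sign = -1.0 if "Condition" in name else 1.0
            assert b1[j] == pytest.approx(sign * b0[j], abs=1e-9)


class TestMixedRegression:
    def test_constant_response_pins_intercept(self):
        df = step_records(n_per_cond=4, mus=(4, 4, 4, 4, 4))
        post = fit_mixed_regression(df, RegressionSpec(seed=1, **REDUCED))
        summ = post.summary().set_index("coefficient")
        assert summ.loc["Intercept", "Estimate"] == pytest.approx(4.0, abs=0.05)
        for name in post.coef_names[1:]:
            assert summ.loc[name, "Estimate"] == pytest.approx(0.0, abs=0.02)
            lo, hi = summ.loc[name, ["l-95% CI", "u-95% CI"]]
            assert lo < 0.05 and hi > -0.05

    def test_recovers_injected_step_change(self):
        """A time-3 drop loads on contrast 2; contrasts 1, 3, 4 stay at 0."""
        cfg = small_config(n_per_condition=40)
        dist = ProfileDistribution(error_shift_mean=0.8, error_shift_sd=0.2,
                                   selfreport_noise_sd=0.6)
        _, reports, _ = simulate_experiment(cfg, dist, rng_seed=6)
        post = fit_mixed_regression(reports, RegressionSpec(seed=2, **REDUCED))
        summ = post.summary().set_index("coefficient")
        lo, hi = summ.loc["contrast2", ["l-95% CI", "u-95% CI"]]
        assert hi < 0  # trust drops at time point 3
        for name in ("contrast1", "contrast3", "contrast4"):
            lo, hi = summ.loc[name, ["l-95% CI", "u-95% CI"]]
            assert lo < 0 < hi

    def test_sampler_matches_ols_under_diffuse_priors(self):
        df = step_records(n_per_cond=20, noise=0.8, seed=9)
        X, y, _ = build_design_matrix(df)
        beta_ols, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        post = fit_mixed_regression(df, RegressionSpec(seed=4, **REDUCED))
        est = post.summary().set_index("coefficient")["Estimate"]
        for j, name in enumerate(X.columns):
            assert est[name] == pytest.approx(beta_ols[j], abs=0.1)

    def test_summary_row_order_contract(self):
        df = step_records(n_per_cond=3)
        post = fit_mixed_regression(df, RegressionSpec(
            seed=5, chains=2, draws=300, tune=100))
        names = post.summary().coefficient.tolist()
        assert names[:2] == ["Intercept", "Condition"]
        assert names[2:6] == [f"contrast{k}" for k in range(1, 5)]
        assert names[6:10] == [f"Condition:contrast{k}" for k in range(1, 5)]
        assert names[10:] == ["sd(Intercept|participant)", "sigma"]

    def test_requires_both_conditions(self):
        df = step_records(n_per_cond=3)
        df = df[df.condition == "distrust"]
        with pytest.raises(ValueError, match="condition"):
            fit_mixed_regression(df, RegressionSpec(**REDUCED))


def test_selfreport_means_average_over_timepoints(tiny_dataset):
    _, reports, _ = tiny_dataset
    means = selfreport_means(reports, "trust")
    one = reports[(reports.item == "trust")
                  & (reports.participant_id == means.index[0])]
    assert means.iloc[0] == pytest.approx(one.rating.mean())
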