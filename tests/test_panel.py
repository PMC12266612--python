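"""Panel construction, two-way FE estimation, clustered errors, effects."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from hsq5d.constants import DIMENSIONS
from hsq5d.panel import (
    build_panel,
    censor_dependent,
    fit_fe,
    marginal_effect,
    stepwise_r2,
)
from hsq5d.synthetic import GeneratorConfig, draw_dimension_scores, generate_panel


def _long_scores(doctor, weeks, value=0.1):
    return pd.DataFrame(
        [
            (doctor, w, dim, value)
            for w in weeks
            for dim in DIMENSIONS
        ],
        columns=["doctor_id", "week", "dimension", "score"],
    )


def _toy_panel(n_doctors=8, n_weeks=6, seed=0, noise=1.0):
    """Small panel with known coefficients on two dimensions."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_doctors):
        mu = rng.normal()
        for w in range(n_weeks):
            x = rng.normal(size=len(DIMENSIONS))
            y = 1.0 + 2.0 * x[0] - 1.0 * x[1] + mu + 0.3 * w + noise * rng.normal()
            rows.append((f"d{d}", w, y, *x))
    return pd.DataFrame(rows, columns=["doctor_id", "week", "demand", *DIMENSIONS])


class TestBuildPanel:
    def test_lag_alignment(self):
        scores = _long_scores("d1", [1, 2, 3])
        demand = pd.DataFrame(
            {"doctor_id": "d1", "week": [2, 3, 4], "demand": [1.0, 2.0, 3.0]}
        )
        panel = build_panel(scores, demand)
        assert list(panel["week"]) == [2, 3, 4]  # week-3 scores exist, so t=4 kept

    def test_missing_lag_week_drops_row(self):
        scores = _long_scores("d1", [1, 3])
        demand = pd.DataFrame(
            {"doctor_id": "d1", "week": [2, 3, 4], "demand": [1.0, 2.0, 3.0]}
        )
        panel = build_panel(scores, demand)
        assert list(panel["week"]) == [2, 4]

    def test_carry_forward_fills_gap(self):
        scores = _long_scores("d1", [1, 3])
        demand = pd.DataFrame(
            {"doctor_id": "d1", "week": [2, 3, 4], "demand": [1.0, 2.0, 3.0]}
        )
        panel = build_panel(scores, demand, missing_policy="carry_forward")
        assert list(panel["week"]) == [2, 3, 4]
        week3 = panel.loc[panel["week"] == 3, list(DIMENSIONS)].to_numpy()
        assert np.allclose(week3, 0.1)  # carried from week 1

    def test_count_controls_log1p(self):
        scores = _long_scores("d1", [1, 2]).pipe(
            lambda df: pd.concat([df, _long_scores("d2", [1, 2])])
        )
        demand = pd.DataFrame(
            {"doctor_id": ["d1", "d2"], "week": [2, 2], "demand": [1.0, 2.0]}
        )
        controls = pd.DataFrame({"doctor_id": ["d1", "d2"], "votes": [0, 99]})
        panel = build_panel(scores, demand, controls)
        assert panel.loc[panel["doctor_id"] == "d1", "log_votes"].iloc[0] == 0.0
        assert panel.loc[panel["doctor_id"] == "d2", "log_votes"].iloc[0] == pytest.approx(
            np.log(100)
        )

    def test_duplicate_demand_keys_rejected(self):
        scores = _long_scores("d1", [1])
        demand = pd.DataFrame(
            {"doctor_id": ["d1", "d1"], "week": [2, 2], "demand": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_panel(scores, demand)

    def test_row_count_matches_join_oracle(self):
        """Generated 50x10 panel joins to the same row set as an
        independent merge over explicitly lagged keys."""
        cfg = GeneratorConfig(n_doctors=50, n_weeks=10)
        scores = draw_dimension_scores(cfg, seed=5)
        demand, _, _ = generate_panel(cfg, scores, seed=6)
        panel = build_panel(scores, demand)
        have_scores = {
            (d, w) for (d, w), g in scores.groupby(["doctor_id", "week"])
            if g["score"].notna().all() and len(g) == len(DIMENSIONS)
        }
        expected = {
            (d, w) for d, w in zip(demand["doctor_id"], demand["week"])
            if (d, w - 1) in have_scores
        }
        assert set(zip(panel["doctor_id"], panel["week"])) == expected


class TestFitFe:
    def test_exact_recovery_without_noise(self):
        """Y built exactly from the two-way model is recovered to 1e-8."""
        panel = _toy_panel(noise=0.0)
        res = fit_fe(panel, mode="twoway_fe")
        assert res.params["expertise"] == pytest.approx(2.0, abs=1e-8)
        assert res.params["process"] == pytest.approx(-1.0, abs=1e-8)
        for dim in DIMENSIONS[2:]:
            assert res.params[dim] == pytest.approx(0.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_row_permutation_invariance(self):
        panel = _toy_panel(seed=2)
        shuffled = panel.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a, b = fit_fe(panel), fit_fe(shuffled)
        assert np.allclose(a.params, b.params)
        assert np.allclose(a.se, b.se)

    def test_matches_dummy_ols_and_cr1_oracle(self):
        """Within estimation equals a hand-rolled dummy-variable OLS, and
        the clustered SEs equal the CR1 sandwich computed from scratch."""
        panel = _toy_panel(n_doctors=20, n_weeks=6, seed=3)
        res = fit_fe(panel, mode="twoway_fe")

        X = np.column_stack(
            [panel[list(DIMENSIONS)].to_numpy()]
            + [pd.get_dummies(panel["doctor_id"], dtype=float).to_numpy()]
            + [pd.get_dummies(panel["week"], drop_first=True, dtype=float).to_numpy()]
        )
        y = panel["demand"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        k = len(DIMENSIONS)
        assert np.allclose(res.params.to_numpy(), beta[:k], atol=1e-8)

        resid = y - X @ beta
        XtX_inv = np.linalg.pinv(X.T @ X)
        meat = np.zeros((X.shape[1], X.shape[1]))
        for g in panel["doctor_id"].unique():
            idx = (panel["doctor_id"] == g).to_numpy()
            s = X[idx].T @ resid[idx]
            meat += np.outer(s, s)
        G, n, K = 20, len(panel), X.shape[1]
        cov = (G / (G - 1)) * ((n - 1) / (n - K)) * XtX_inv @ meat @ XtX_inv
        assert np.allclose(res.se.to_numpy(), np.sqrt(np.diag(cov))[:k], atol=1e-8)

    def test_matches_statsmodels_cluster_ols(self):
        """Cross-check against statsmodels OLS with explicit fixed-effect
        dummies and doctor-clustered covariance."""
        panel = _toy_panel(n_doctors=10, n_weeks=5, seed=4)
        res = fit_fe(panel, mode="twoway_fe")
        formula = "demand ~ " + " + ".join(DIMENSIONS) + " + C(doctor_id) + C(week)"
        sm_fit = smf.ols(formula, data=panel).fit(
            cov_type="cluster", cov_kwds={"groups": panel["doctor_id"]}
        )
        for dim in DIMENSIONS:
            assert res.params[dim] == pytest.approx(sm_fit.params[dim], abs=1e-8)
            assert res.se[dim] == pytest.approx(sm_fit.bse[dim], abs=1e-8)

    def test_time_invariant_controls_dropped_in_twoway(self):
        panel = _toy_panel()
        panel["chronic"] = (panel["doctor_id"].str[1:].astype(int) % 2).astype(float)
        res = fit_fe(panel, mode="twoway_fe")
        assert "chronic" in res.dropped
        assert "chronic" not in res.params.index

    def test_pooled_weekfe_keeps_time_invariant_controls(self):
        panel = _toy_panel()
        panel["chronic"] = (panel["doctor_id"].str[1:].astype(int) % 2).astype(float)
        res = fit_fe(panel, mode="pooled_weekfe")
        assert "chronic" in res.params.index
        assert "const" in res.params.index

    def test_rank_deficient_design_names_columns(self):
        panel = _toy_panel()
        panel["dup"] = panel["expertise"]
        with pytest.raises(ValueError, match="dup"):
            fit_fe(panel, mode="twoway_fe", regressors=list(DIMENSIONS) + ["dup"])

    def test_clustered_se_shrink_with_cluster_count(self):
        """On homoskedastic data the clustered SE scales like 1/sqrt(G)."""
        se = {}
        for G in (10, 40):
            reps = [
                fit_fe(_toy_panel(n_doctors=G, n_weeks=6, seed=s)).se["expertise"]
                for s in range(5)
            ]
            se[G] = np.mean(reps)
        ratio = se[40] / se[10]
        assert 0.3 < ratio < 0.7  # ideal 0.5


class TestMarginalEffect:
    def test_published_expertise_arithmetic(self):
        me = marginal_effect(1.1189, 0.0252, "expertise")
        assert me.log_effect == pytest.approx(0.0282, abs=5e-4)
        assert 100 * me.percent_effect == pytest.approx(2.9, abs=0.05)

    def test_published_process_arithmetic(self):
        me = marginal_effect(5.5977, 0.0210, "process")
        assert me.log_effect == pytest.approx(0.12, abs=5e-3)
        assert 100 * me.percent_effect == pytest.approx(12.5, abs=0.05)

    def test_null_effect(self):
        assert marginal_effect(0.0, 0.5).percent_effect == 0.0

    def test_small_effect_limit(self):
        """exp(gamma*sigma) - 1 ~ gamma*sigma within 1% for small products."""
        for gs in (1e-4, 1e-3, 5e-3, 9e-3):
            me = marginal_effect(gs, 1.0)
            assert me.percent_effect == pytest.approx(gs, rel=0.01)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            marginal_effect(1.0, -0.1)


class TestStepwiseR2:
    def test_sequence_monotone_and_length(self):
        panel = _toy_panel(seed=5)
        panel["chronic"] = 0.5  # constant control is dropped in twoway mode
        panel = panel.drop(columns="chronic")
        steps = stepwise_r2(panel)
        assert len(steps) == len(DIMENSIONS) + 1
        assert all(b >= a - 1e-12 for a, b in zip(steps, steps[1:]))

    def test_true_regressor_increases_r2(self):
        panel = _toy_panel(seed=6, noise=1.0)
        steps = stepwise_r2(panel, order=("expertise",))
        assert steps[1] > steps[0]

    def test_monotone_on_random_panels(self):
        for seed in range(20):
            steps = stepwise_r2(_toy_panel(n_doctors=6, n_weeks=4, seed=seed))
            assert all(b >= a - 1e-12 for a, b in zip(steps, steps[1:]))

    def test_redundant_dimension_adds_nothing(self):
        """A dimension exactly duplicating an already-included regressor
        leaves R² unchanged."""
        panel = _toy_panel(seed=7)
        panel["process"] = panel["expertise"]
        steps = stepwise_r2(panel, order=("expertise", "process"))
        assert steps[2] == pytest.approx(steps[1], abs=1e-12)


class TestCensorDependent:
    def test_fraction_zero_is_identity(self):
        panel = _toy_panel()
        out = censor_dependent(panel, 0.0)
        pd.testing.assert_frame_equal(out, panel)

    def test_order_statistics_1_to_100(self):
        panel = pd.DataFrame(
            {"doctor_id": "d", "week": range(100), "demand": np.arange(1.0, 101.0)}
        )
        out = censor_dependent(panel, 0.10)
        assert out["demand"].min() == 11 and out["demand"].max() == 90
        assert len(out) == 80

    def test_matches_sort_and_slice_oracle(self, rng):
        panel = _toy_panel(n_doctors=10, n_weeks=8, seed=8)
        f = 0.1
        out = censor_dependent(panel, f)
        k = int(np.floor(f * len(panel)))
        kept = np.sort(panel["demand"].to_numpy())[k : len(panel) - k]
        assert np.array_equal(np.sort(out["demand"].to_numpy()), kept)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            censor_dependent(_toy_panel(), 0.5)


class TestParameterRecovery:
    def test_gamma_recovered_within_monte_carlo_error(self):
        """Panels simulated from the demand model with the published
        coefficients return estimates whose replicate mean is within
        2 Monte-Carlo SEs of the truth (scaled-down replicate count)."""
        cfg = GeneratorConfig(n_doctors=120, n_weeks=10)
        est = []
        for s in range(12):
            scores = draw_dimension_scores(cfg, seed=100 + s)
            demand, _, _ = generate_panel(cfg, scores, seed=500 + s)
            res = fit_fe(build_panel(scores, demand), mode="twoway_fe")
            est.append([res.params[d] for d in DIMENSIONS])
        est = np.array(est)
        mean = est.mean(axis=0)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        for g, m, se in zip(cfg.gamma, mean, mc_se):
            assert abs(m - g) <= 2 * se + 1e-12

    def test_zero_noise_latent_panel_exact(self):
        """With zero noise and the oracle fixed effects included as
        regressors implicitly via demeaning, recovery is exact."""
        cfg = GeneratorConfig(n_doctors=30, n_weeks=8, noise_sd=0.0)
        scores = draw_dimension_scores(cfg, seed=1)
        demand, _, _ = generate_panel(cfg, scores, seed=2)
        res = fit_fe(build_panel(scores, demand), mode="twoway_fe")
        for g, d in zip(cfg.gamma, DIMENSIONS):
            assert res.params[d] == pytest.approx(g, abs=1e-8)
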