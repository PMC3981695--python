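"""Design construction, likelihood, sampler behavior, model screening."""

import numpy as np
import pandas as pd
import pytest

from divebout.bayes import (
    BoutTypeModel,
    build_design,
    fit_mwg,
    loglik,
    screen_models,
    summarize_effects,
)
from divebout.synth import OutcomeGenParams, generate_outcomes


def _bout_frame(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "animal_id": rng.choice(["A", "B", "C"], n),
            "site": rng.choice(["Bird Rocks", "Padilla Bay"], n),
            "season": rng.choice(["breeding", "non-breeding"], n),
            "light": rng.choice(["day", "night"], n),
            "sex": rng.choice(["female", "male"], n),
            "bout_type": rng.choice(["I", "II"], n),
        }
    )


def test_full_design_has_sixteen_columns():
    d = build_design(_bout_frame(), order=4)
    assert d.X.shape[1] == 16
    assert d.xnames[0] == "Intercept"
    assert d.xnames[-1] == "Site1:Season1:Light1:Sex1"
    assert len(d.xnames) == len(set(d.xnames))


def test_main_effects_design_has_five_columns():
    d = build_design(_bout_frame(), order=1)
    assert d.xnames == ["Intercept", "Site1", "Season1", "Light1", "Sex1"]


def test_reference_level_row_is_intercept_only():
    df = _bout_frame()
    df.loc[0, ["site", "season", "light", "sex"]] = (
        "Bird Rocks", "breeding", "day", "female"
    )
    d = build_design(df, order=4)
    assert d.X[0, 0] == 1.0
    assert np.all(d.X[0, 1:] == 0.0)


def test_interaction_columns_are_products_of_mains():
    d = build_design(_bout_frame(), order=4)
    cols = dict(zip(d.xnames, d.X.T))
    np.testing.assert_array_equal(
        cols["Site1:Season1"], cols["Site1"] * cols["Season1"]
    )
    np.testing.assert_array_equal(
        cols["Site1:Season1:Light1:Sex1"],
        cols["Site1"] * cols["Season1"] * cols["Light1"] * cols["Sex1"],
    )


def test_single_level_factor_raises_with_factor_name():
    df = _bout_frame()
    df["sex"] = "female"
    with pytest.raises(ValueError, match="sex"):
        build_design(df)


def test_loglik_null_model():
    n = 25
    X = np.ones((n, 1))
    y = np.zeros(n)
    assert loglik(np.zeros(1), None, X, y) == pytest.approx(n * np.log(0.5))


def test_loglik_saturation_limit():
    X = np.ones((1, 1))
    val = loglik(np.array([500.0]), None, X, np.ones(1))
    assert -1e-6 < val <= 0.0
    val = loglik(np.array([900.0]), None, X, np.ones(1))
    assert np.isfinite(val)


def test_loglik_matches_scalar_oracle():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((6, 3))
    y = rng.integers(0, 2, 6).astype(float)
    beta = rng.standard_normal(3)
    seal = np.array([0, 0, 1, 1, 2, 2])
    alpha = rng.standard_normal(3)
    expected = 0.0
    for i in range(6):
        eta = float(X[i] @ beta + alpha[seal[i]])
        theta = 1.0 / (1.0 + np.exp(-eta))
        expected += y[i] * np.log(theta) + (1 - y[i]) * np.log(1 - theta)
    assert loglik(beta, alpha, X, y, seal) == pytest.approx(expected, abs=1e-12)
    # aggregated model likelihood agrees with the per-row form
    m = BoutTypeModel(y, X, seal_index=seal)
    assert m.loglike(beta, alpha) == pytest.approx(expected, abs=1e-10)


def test_sampler_determinism():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=6, bouts_per_seal=30), seed=2
    )
    m = BoutTypeModel.from_dataframe(bouts, order=1)
    r1 = m.fit(draws=500, burn=500, seed=9)
    r2 = m.fit(draws=500, burn=500, seed=9)
    assert np.array_equal(r1.beta_draws, r2.beta_draws)
    assert np.array_equal(r1.alpha_draws, r2.alpha_draws)
    assert np.array_equal(r1.sigma_draws, r2.sigma_draws)


def test_nonfinite_initial_state_raises():
    X = np.ones((4, 1)) * np.nan
    with pytest.raises(ValueError):
        BoutTypeModel(np.zeros(4), X).fit(draws=10, burn=10)


def test_posterior_concentrates_on_truth_at_large_n():
    params = OutcomeGenParams(n_seals=21, bouts_per_seal=500)
    bouts, _, beta_true = generate_outcomes(params, seed=5)
    m = BoutTypeModel.from_dataframe(bouts)
    res = m.fit(draws=6000, burn=6000, seed=5)
    sd = res.beta_draws.std(axis=0)
    err = np.abs(res.beta_draws.mean(axis=0) - beta_true.to_numpy())
    assert np.all(err < 3 * sd + 0.05)


def test_hierarchical_and_fixed_sigma_modes_agree():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=10, bouts_per_seal=80), seed=3
    )
    m = BoutTypeModel.from_dataframe(bouts, order=1)
    hier = m.fit(draws=8000, burn=8000, seed=1, hierarchical=True)
    sigma_hat = float(hier.sigma_draws.mean())
    flat = m.fit(draws=8000, burn=8000, seed=2, hierarchical=False,
                 sigma_alpha=sigma_hat)
    mc = 3 * (hier.beta_draws.std(0) + flat.beta_draws.std(0)) / np.sqrt(200)
    diff = np.abs(hier.params.to_numpy() - flat.params.to_numpy())
    assert np.all(diff < np.maximum(mc, 0.08))


def test_acceptance_rates_in_open_interval():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=6, bouts_per_seal=40), seed=0
    )
    res = BoutTypeModel.from_dataframe(bouts, order=1).fit(
        draws=2000, burn=2000, seed=0
    )
    for rate in (res.accept_beta, res.accept_alpha, res.accept_sigma):
        assert 0.0 < rate < 1.0


def test_summary_schema_and_significance():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=6, bouts_per_seal=40), seed=0
    )
    res = BoutTypeModel.from_dataframe(bouts, order=1).fit(
        draws=1000, burn=1000, seed=0
    )
    eff, seals = summarize_effects(res)
    assert list(eff.columns) == ["Mean", "0.025", "0.975", "significant"]
    assert list(seals.columns) == ["Mean", "0.025", "0.975", "significant"]
    assert (eff["0.025"] <= eff["0.975"]).all()
    assert set(seals.index) == set(bouts.animal_id.unique())
    text = res.summary()
    assert "Intercept" in text and "sigma_alpha" in text


def test_quantiles_match_percentile_rule_on_grid():
    res = _fake_results(np.arange(1.0, 1001.0)[:, None], ["Intercept"])
    frame = res.summary_frame()
    assert frame.loc["Intercept", "0.025"] == pytest.approx(
        np.quantile(np.arange(1.0, 1001.0), 0.025)
    )
    assert frame.loc["Intercept", "0.975"] == pytest.approx(
        np.quantile(np.arange(1.0, 1001.0), 0.975)
    )


def _fake_results(beta_draws, names):
    from divebout.bayes import BoutTypeResults

    model = BoutTypeModel(
        y=np.array([0.0, 1.0]),
        X=np.ones((2, beta_draws.shape[1])),
        xnames=names,
    )
    return BoutTypeResults(
        model=model, beta_draws=beta_draws, alpha_draws=None,
        sigma_draws=np.zeros(len(beta_draws)), accept_beta=0.3,
        accept_alpha=np.nan, accept_sigma=np.nan,
    )


def test_significance_flag_semantics():
    all_pos = _fake_results(np.abs(np.random.default_rng(0)
                                   .normal(2, 0.1, (500, 1))), ["a"])
    assert all_pos.summary_frame()["significant"].iloc[0]
    sym = _fake_results(np.random.default_rng(0).normal(0, 1, (500, 1)), ["a"])
    assert not sym.summary_frame()["significant"].iloc[0]


def test_diagnostics_frame():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=5, bouts_per_seal=40), seed=1
    )
    res = BoutTypeModel.from_dataframe(bouts, order=1).fit(
        draws=2000, burn=1000, seed=1
    )
    diag = res.diagnostics()
    assert set(diag.columns) == {"rhat", "ess"}
    assert (diag["ess"] > 50).all()
    assert (diag["rhat"] < 1.2).all()


def test_identical_candidates_score_identically():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=6, bouts_per_seal=50), seed=2
    )
    table = screen_models(bouts, orders=(2, 2))
    assert table.loc[0, "bic"] == table.loc[1, "bic"]
    assert table.loc[0, "aic"] == table.loc[1, "aic"]


def test_saturated_model_penalized_on_tiny_data():
    bouts, _, _ = generate_outcomes(
        OutcomeGenParams(n_seals=4, bouts_per_seal=10), seed=3
    )
    table = screen_models(bouts, orders=(1, 4))
    worst = table.sort_values("bic").iloc[-1]
    assert worst["order"] == 4


def test_mains_only_truth_ranked_first_by_bic():
    beta = {"Intercept": 0.4, "Site1": 0.8, "Season1": -0.9,
            "Light1": -0.6, "Sex1": 0.7}
    params = OutcomeGenParams(beta=beta, sigma_alpha=0.3, n_seals=20,
                              bouts_per_seal=100)
    bouts, _, _ = generate_outcomes(params, seed=8)
    table = screen_models(bouts, orders=(1, 2, 4))
    assert table.loc[0, "order"] == 1
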