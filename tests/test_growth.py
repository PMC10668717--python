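"""State-space growth model: simulation, closed-form oracles, MCMC fits,
diagnostics."""

import numpy as np
import pytest

from wolfalps.growth import (
    TEST_MCMC,
    ConvergenceError,
    CountSeries,
    GrowthModelSpec,
    McmcSettings,
    fit_growth_model,
    implied_geometric_rate,
    recovery_experiment,
    simulate_series,
    split_rhat,
)

QUICK_MCMC = McmcSettings(n_chains=4, n_iterations=4_000, thin=2, n_adapt=1_000)


def full_series(counts, start=1993):
    return CountSeries.from_dict(
        {f"{start + t}–{start + t + 1}": c for t, c in enumerate(counts)},
        start, start + len(counts) - 1,
    )


# ---------------------------------------------------------------------------
# simulation


def test_deterministic_limit_doubling():
    """σ_p → 0, φ → 0: the latent path is exactly geometric."""
    series, latent = simulate_series(2.0, 0.0, 0.0, 1.0, 10, seed=0)
    assert np.allclose(latent, [2.0**t for t in range(10)])
    assert len(series.years) == 10 and series.years[0] == "1993–1994"


def test_simulation_mean_log_growth():
    """E[log(N_{t+1}/N_t)] = log λ within Monte-Carlo error."""
    rng = np.random.default_rng(0)
    logs = []
    for _ in range(400):
        _, latent = simulate_series(1.22, 0.05, 0.1, 10.0, 12, rng)
        logs.extend(np.diff(np.log(latent)))
    logs = np.asarray(logs)
    se = logs.std(ddof=1) / np.sqrt(len(logs))
    assert abs(logs.mean() - np.log(1.22)) < 3 * se


def test_simulation_seed_reproducible():
    a, _ = simulate_series(1.2, 0.05, 0.1, 5.0, 15, seed=9)
    b, _ = simulate_series(1.2, 0.05, 0.1, 5.0, 15, seed=9)
    assert np.array_equal(a.observed, b.observed)


def test_series_validation():
    with pytest.raises(ValueError):
        CountSeries(["1993–1994"], np.array([2.5]))
    with pytest.raises(ValueError):
        CountSeries(["1993–1994", "1994–1995"], np.array([-1.0, 2.0]))
    with pytest.raises(ValueError):
        fit_growth_model(full_series([5]), mcmc=QUICK_MCMC)


# ---------------------------------------------------------------------------
# closed-form oracle


@pytest.mark.parametrize(
    "n0,n1,t,expected",
    [
        (1, 243, 27, 243 ** (1 / 27)),  # ≈ 1.2256
        (77, 243, 5, (243 / 77) ** (1 / 5)),  # ≈ 1.2585
        (50, 50, 12, 1.0),
    ],
)
def test_implied_geometric_rate(n0, n1, t, expected):
    assert implied_geometric_rate(n0, n1, t) == pytest.approx(expected)
    # spot values computed independently by repeated multiplication
    assert implied_geometric_rate(1, 243, 27) == pytest.approx(1.2256, abs=5e-4)
    assert implied_geometric_rate(77, 243, 5) == pytest.approx(1.2585, abs=5e-4)


def test_implied_rate_errors():
    with pytest.raises(ValueError):
        implied_geometric_rate(0, 10, 5)
    with pytest.raises(ValueError):
        implied_geometric_rate(1, 10, 0)


# ---------------------------------------------------------------------------
# fitting


def test_constant_series_gives_lambda_near_one():
    post = fit_growth_model(full_series([50] * 10), mcmc=QUICK_MCMC)
    s = post.summary().loc["lambda"]
    assert abs(s["mean"] - 1.0) < 0.05
    assert s["ci2.5"] < 1.0 < s["ci97.5"]


def test_noise_free_doubling_recovers_two():
    """1, 2, 4, …, 1024 with tight error priors: λ median within 2% of 2."""
    spec = GrowthModelSpec(sigma_scale=1e-3, phi_scale=1e-3)
    post = fit_growth_model(full_series([2**t for t in range(11)]), spec, QUICK_MCMC)
    assert post.summary().at["lambda", "median"] == pytest.approx(2.0, rel=0.02)


def test_fit_reproducible_with_seed():
    s = full_series([5, 6, 8, 10, 11, 14, 18, 21])
    p1 = fit_growth_model(s, mcmc=QUICK_MCMC)
    p2 = fit_growth_model(s, mcmc=QUICK_MCMC)
    assert np.array_equal(p1.lam, p2.lam)


def test_posterior_concentrates_on_geometric_rate_as_noise_vanishes():
    counts = [round(5 * 1.3**t) for t in range(12)]
    spec = GrowthModelSpec(sigma_scale=1e-3, phi_scale=1e-3)
    post = fit_growth_model(full_series(counts), spec, QUICK_MCMC)
    target = implied_geometric_rate(counts[0], counts[-1], 11)
    assert post.summary().at["lambda", "median"] == pytest.approx(target, rel=0.03)


def test_missing_years_imputed_between_observations():
    """Latent medians in an unobserved gap of a monotone series lie between
    the neighbouring observed levels."""
    series = CountSeries.from_dict({"2000–2001": 5, "2007–2008": 50}, 2000, 2007)
    post = fit_growth_model(series, mcmc=QUICK_MCMC, check_convergence=False)
    med = post.latent_summary()["median"].to_numpy()
    assert np.all(med[1:-1] > 2.0) and np.all(med[1:-1] < 80.0)
    assert np.all(np.diff(med) > 0)  # monotone imputation for monotone data


def test_credible_intervals_nested():
    post = fit_growth_model(full_series([5, 8, 9, 13, 15, 20, 24, 30]), mcmc=QUICK_MCMC)
    lam = post.lam.ravel()
    q25, q75 = np.quantile(lam, [0.25, 0.75])
    s = post.summary().loc["lambda"]
    assert s["ci2.5"] <= q25 <= q75 <= s["ci97.5"]
    assert (lam > 0).all()
    assert (np.exp(post.latent_log_n) > 0).all()


def test_convergence_gate_raises_on_tiny_run():
    bad = McmcSettings(n_chains=4, n_iterations=40, thin=1, n_adapt=10)
    series = CountSeries.from_dict({"1993–1994": 1, "2015–2016": 77}, 1993, 2015)
    with pytest.raises(ConvergenceError):
        # 23 latent states cannot mix in 40 iterations
        fit_growth_model(series, mcmc=bad, rhat_threshold=1.01)


def test_split_rhat_matches_arviz():
    """Our split-R̂ agrees with arviz's classic split estimator."""
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(0)
    good = rng.normal(size=(4, 500))
    drifted = good + np.linspace(0, 3, 500)
    for draws in (good, drifted):
        ours = split_rhat(draws)
        theirs = float(az.rhat(draws, method="split"))
        assert ours == pytest.approx(theirs, abs=0.02)


def test_chain_count_invariance():
    """Posterior mean is stable (within MC error) across chain counts."""
    s = full_series([5, 7, 8, 11, 13, 17, 20, 26, 30, 38])
    m4 = fit_growth_model(s, mcmc=QUICK_MCMC).summary().at["lambda", "mean"]
    m8 = fit_growth_model(
        s, mcmc=McmcSettings(n_chains=8, n_iterations=4_000, thin=2, n_adapt=1_000)
    ).summary().at["lambda", "mean"]
    assert m4 == pytest.approx(m8, abs=0.02)


def test_recovery_zero_noise_bias_small():
    tab = recovery_experiment(
        2.0, 1e-4, 1e-4, 4.0, 12, 20,
        McmcSettings(n_chains=2, n_iterations=2_000, thin=2, n_adapt=1_000),
        seed=3,
    )
    assert abs(tab.at["lambda", "bias"]) < 0.05
    assert tab.at["lambda", "rmse"] < 0.05
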