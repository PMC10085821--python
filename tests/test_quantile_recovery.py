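"""Quantile model fitting, return times, and bootstrap inference."""

import numpy as np
import pytest

from tagrecover.quantile_recovery import (
    QRDesign,
    bootstrap_ci,
    compare_slopes,
    fit_quantile_model,
    pinball_loss,
    recovery_curve,
    recovery_time,
)
from tagrecover.synthetic import AccelScenario, simulate_accel


def _design(t, y, tau, animal="a", group="g"):
    n = len(t)
    return QRDesign([animal] * n, [group] * n, np.asarray(t, float), np.asarray(y, float), tau)


def grid_pinball_min(ly, z, tau, beta_grid, alpha_grid):
    """Brute-force pinball minimization over a parameter grid (oracle)."""
    best = (np.inf, None, None)
    for b in beta_grid:
        r = ly - b - np.outer(alpha_grid, z)
        losses = pinball_loss(r, tau).sum(axis=1)
        j = int(np.argmin(losses))
        if losses[j] < best[0]:
            best = (losses[j], b, alpha_grid[j])
    return best


# ---------------------------------------------------------------------------
# fitting


def test_noiseless_data_interpolated_exactly():
    t = np.array([0.0, 1.0, 3.0, 9.0])
    y = np.exp(1.0 - 2.0 / (t + 1.0))
    fit = fit_quantile_model(_design(t, y, 0.5), method="exact")
    assert fit.beta_ind["a"] == pytest.approx(1.0, abs=1e-6)
    assert fit.alpha["g"] == pytest.approx(-2.0, abs=1e-6)
    assert fit.loss == pytest.approx(0.0, abs=1e-6)


def test_intercept_only_median_tie_broken_low():
    # median of {1, 2, 3, 9} on the log scale: any value in [2, 3] attains
    # the same pinball loss; the fit must return the lower endpoint
    y = np.exp([1.0, 2.0, 3.0, 9.0])
    design = _design([0.0, 1.0, 2.0, 3.0], y, 0.5)
    fit = fit_quantile_model(design, method="exact", include_decay=False)
    # brute-force check that the whole interval [2, 3] is optimal
    grid = np.linspace(0, 10, 2001)
    losses = np.array([pinball_loss(np.log(y) - b, 0.5).sum() for b in grid])
    optimal = grid[losses <= losses.min() + 1e-12]
    assert optimal.min() == pytest.approx(2.0, abs=0.01)
    assert optimal.max() == pytest.approx(3.0, abs=0.01)
    assert fit.beta_ind["a"] == pytest.approx(2.0, abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("tau", [0.25, 0.5, 0.9])
def test_exact_fit_matches_grid_oracle(seed, tau):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 50))
    t = np.sort(rng.uniform(0, 30, n))
    ly = rng.uniform(0.0, 2.0) + rng.uniform(-4, 0) / (t + 1) + rng.standard_normal(n)
    design = _design(t, np.exp(ly), tau)
    fit = fit_quantile_model(design, method="exact")
    res = 0.01
    loss, b_star, a_star = grid_pinball_min(
        ly, design.z, tau,
        np.arange(-3, 5, res), np.arange(-8, 4, res),
    )
    # the LP solution can never be beaten by any grid point, and the grid
    # optimum can exceed it by at most the loss Lipschitz slack of one cell
    lipschitz = n * max(tau, 1 - tau) * 2.0  # d(loss)/d(beta,alpha), |z|<=1
    assert fit.loss <= loss + 1e-9
    assert loss <= fit.loss + lipschitz * res
    # reported loss is the actual pinball objective at the fitted parameters
    r = ly - fit.beta_ind["a"] - fit.alpha["g"] * design.z
    assert fit.loss == pytest.approx(pinball_loss(r, tau).sum(), abs=1e-8)


def test_irls_agrees_with_exact_lp(rng):
    n = 4000
    t = np.sort(rng.uniform(0, 50, n))
    ly = 1.0 - 2.5 / (t + 1) + rng.standard_normal(n)
    design = _design(t, np.exp(ly), 0.5)
    exact = fit_quantile_model(design, method="exact")
    irls = fit_quantile_model(design, method="irls")
    assert irls.alpha["g"] == pytest.approx(exact.alpha["g"], abs=0.02)
    assert irls.loss <= exact.loss * 1.001


def test_fit_matches_statsmodels_quantreg(rng):
    statsmodels = pytest.importorskip("statsmodels.api")
    n = 800
    t = np.sort(rng.uniform(0, 40, n))
    z = 1 / (t + 1)
    ly = 0.7 - 3.0 * z + rng.standard_normal(n)
    design = _design(t, np.exp(ly), 0.5)
    ours = fit_quantile_model(design, method="exact")
    sm_fit = statsmodels.QuantReg(ly, np.column_stack([np.ones(n), z])).fit(q=0.5)
    assert ours.beta_ind["a"] == pytest.approx(sm_fit.params[0], abs=1e-3)
    assert ours.alpha["g"] == pytest.approx(sm_fit.params[1], abs=1e-3)


def test_fit_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="positive"):
        _design([0, 1, 2], [1.0, -1.0, 2.0], 0.5)
    with pytest.raises(ValueError, match="distinct"):
        fit_quantile_model(_design([3.0, 3.0, 3.0], [1.0, 2.0, 3.0], 0.5))


def test_objective_beats_zero_parameter_vector(rng):
    t = np.sort(rng.uniform(0, 20, 60))
    ly = 0.5 - 1.0 / (t + 1) + 0.3 * rng.standard_normal(60)
    design = _design(t, np.exp(ly), 0.9)
    fit = fit_quantile_model(design, method="exact")
    assert fit.loss <= pinball_loss(ly, 0.9).sum() + 1e-9


def test_quantile_curves_do_not_cross_on_location_scale_data():
    sc = AccelScenario(
        n_animals=4, duration_h=40.0, obs_per_h=30,
        slopes={"g": (-2.0, -0.5)}, seed=11,
    )
    series, groups, _ = simulate_accel(sc)
    t_grid = np.linspace(0.0, 40.0, 200)
    fits = {}
    for tau in (0.5, 0.9):
        design = QRDesign.from_series(series, groups, tau)
        fits[tau] = fit_quantile_model(design)
    for animal in fits[0.5].beta_ind:
        lo = fits[0.5].predict_log(animal, "g", t_grid)
        hi = fits[0.9].predict_log(animal, "g", t_grid)
        assert np.all(hi >= lo - 1e-6)


def test_fitted_curve_monotone_and_vanishing():
    t = np.array([0.0, 0.5, 2.0, 5.0, 20.0, 80.0])
    y = np.exp(1.2 - 2.0 / (t + 1.0))
    fit = fit_quantile_model(_design(t, y, 0.5), method="exact")
    t_grid = np.linspace(0, 300, 500)
    curve = fit.predict_log("a", "g", t_grid)
    assert np.all(np.diff(curve) >= -1e-12)  # monotone relaxation
    assert curve[-1] == pytest.approx(fit.beta_ind["a"], abs=0.01)


# ---------------------------------------------------------------------------
# return times


def test_recovery_time_closed_form():
    base = fit_quantile_model(
        _design([0.0, 1.0, 3.0], np.exp([0.0, 0.0, 0.0]) * np.exp(1 - 2 / (np.array([0.0, 1, 3]) + 1)), 0.5),
        method="exact",
    )
    base.alpha["g"] = np.log(0.25)
    assert recovery_time(base, "g", 0.25).t_r == 0.0
    base.alpha["g"] = 2 * np.log(0.25)
    assert recovery_time(base, "g", 0.25).t_r == pytest.approx(1.0, abs=1e-12)
    base.alpha["g"] = 0.0
    assert recovery_time(base, "g", 0.25).t_r == 0.0
    base.alpha["g"] = 2.0 * abs(np.log(0.25))  # elevated response, same magnitude
    assert recovery_time(base, "g", 0.25).t_r == pytest.approx(1.0, abs=1e-12)


def test_recovery_curve_values_and_monotonicity():
    fit = fit_quantile_model(
        _design([0.0, 1.0, 4.0], np.exp(1 - 3 / (np.array([0.0, 1, 4]) + 1)), 0.5),
        method="exact",
    )
    assert fit.alpha["g"] == pytest.approx(-3.0, abs=1e-6)
    ests = recovery_curve(fit, "g", [0.1, 0.25, 0.5])
    got = [e.t_r for e in ests]
    np.testing.assert_allclose(got, [0.302895, 1.163953, 3.328085], atol=1e-4)
    assert np.all(np.diff(got) >= 0)  # looser tolerance -> later recovery
    capped = recovery_curve(fit, "g", [0.999999], cap_h=100.0)
    assert capped[0].t_r == 100.0
    zero = recovery_curve(fit, "g", [np.exp(-3.0)])
    assert zero[0].t_r == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# bootstrap inference


def _noiseless_cohort(alpha=-3.0, n_animals=4, tau=0.5):
    t = np.linspace(0.0, 30.0, 40)
    animals, groups, ts, ys = [], [], [], []
    for i in range(n_animals):
        beta = 0.5 + 0.2 * i
        animals += [f"a{i}"] * t.size
        groups += ["g"] * t.size
        ts.append(t)
        ys.append(np.exp(beta + alpha / (t + 1)))
    return QRDesign(animals, groups, np.concatenate(ts), np.concatenate(ys), tau)


def test_bootstrap_ci_noiseless_has_zero_width():
    design = _noiseless_cohort()
    fit = fit_quantile_model(design)
    est = bootstrap_ci(design, fit, "g", n_boot=200, seed=0)
    assert est.ci_upper - est.ci_lower < 1e-6
    assert est.ci_lower <= est.t_r <= est.ci_upper


def test_bootstrap_ci_deterministic_per_seed():
    design = _noiseless_cohort(alpha=-2.0)
    fit = fit_quantile_model(design)
    a = bootstrap_ci(design, fit, "g", n_boot=200, seed=7)
    b = bootstrap_ci(design, fit, "g", n_boot=200, seed=7)
    assert (a.t_r, a.ci_lower, a.ci_upper) == (b.t_r, b.ci_lower, b.ci_upper)


def test_bootstrap_rejects_too_few_replicates():
    design = _noiseless_cohort()
    fit = fit_quantile_model(design)
    with pytest.raises(ValueError, match="200"):
        bootstrap_ci(design, fit, "g", n_boot=50)


def test_two_animal_group_falls_back_to_block_bootstrap():
    design = _noiseless_cohort(n_animals=2)
    fit = fit_quantile_model(design)
    with pytest.warns(UserWarning, match="block"):
        est = bootstrap_ci(design, fit, "g", n_boot=200, seed=0)
    assert np.isfinite(est.ci_upper)


def test_identical_groups_give_statistic_zero_p_one():
    design = _noiseless_cohort(alpha=-2.5)
    noisy = QRDesign(
        design.animal, design.group, design.t,
        design.y * np.exp(0.1 * np.random.default_rng(3).standard_normal(design.y.size)),
        design.tau,
    )
    test = compare_slopes(noisy, noisy, "g", "g", n_boot=200, seed=1)
    assert test.statistic == 0.0
    assert test.p_value == 1.0


def test_slope_test_detects_large_group_difference():
    """Power check: strongly different decay slopes are flagged.

    20 seeded cohorts of 6+6 animals with slopes -3 vs -0.3 and unit
    log-scale noise; the group contrast should reject at 5% in at least
    80% of them.
    """
    rejections = 0
    n_reps = 20
    for rep in range(n_reps):
        sc = AccelScenario(
            n_animals=6, duration_h=50.0, obs_per_h=10,
            slopes={"long": (-3.0, 0.0), "short": (-0.3, 0.0)},
            seed=1000 + rep,
        )
        series, groups, _ = simulate_accel(sc)
        design = QRDesign.from_series(series, groups, 0.5)
        test = compare_slopes(design, design, "long", "short", n_boot=100, seed=rep)
        rejections += test.p_value < 0.05
    assert rejections >= 0.8 * n_reps
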