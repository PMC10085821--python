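"""Hourly distributions, reference weighting, divergences, RoR, labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagrecover.entropy import (
    EntropySeries,
    HourlyDistribution,
    build_schedule,
    entropy_series,
    hourly_distributions,
    hourly_duration_profiles,
    js_divergence,
    kl_divergence,
    label_series,
    leave_one_out_divergences,
    pooled_region_of_recovery,
    reference_distribution,
    region_of_recovery,
)
from tagrecover.synthetic import DiveScenario, simulate_dives


def _hd(hour, p):
    return HourlyDistribution(hour, np.asarray(p, float), n_dives=5,
                              total_dive_seconds=600.0, n_animals=2)


probvec = st.lists(st.integers(1, 50), min_size=3, max_size=3).map(
    lambda v: np.array(v, float) / sum(v)
)


# ---------------------------------------------------------------------------
# hourly distributions


def test_duration_weighted_proportions(dive_table_factory):
    dives = dive_table_factory(
        [("a", 0.1, 120.0, "Shallow"), ("a", 0.4, 60.0, "Medium"), ("b", 0.8, 20.0, "Deep")]
    )
    (h,) = hourly_distributions(dives)
    assert h.hour == 0
    np.testing.assert_allclose(h.p, [0.6, 0.3, 0.1])
    assert h.n_dives == 3 and h.n_animals == 2


def test_single_dive_hour_is_degenerate(dive_table_factory):
    dives = dive_table_factory([("a", 3.2, 100.0, "Shallow")])
    (h,) = hourly_distributions(dives)
    assert h.hour == 3
    np.testing.assert_allclose(h.p, [1, 0, 0])


def test_count_vs_duration_weighting(dive_table_factory):
    dives = dive_table_factory(
        [("a", 0.0, 10.0, "Shallow"), ("a", 0.3, 10.0, "Shallow"), ("a", 0.6, 80.0, "Deep")]
    )
    (dur,) = hourly_distributions(dives, weighting="duration")
    (cnt,) = hourly_distributions(dives, weighting="count")
    np.testing.assert_allclose(dur.p, [0.2, 0.0, 0.8])
    np.testing.assert_allclose(cnt.p, [2 / 3, 0.0, 1 / 3])


def test_empty_table_gives_no_distributions():
    assert hourly_distributions(pd.DataFrame(
        columns=["animal_id", "start_h", "duration_s", "target_depth_m", "category"]
    )) == []


# ---------------------------------------------------------------------------
# drop schedule and reference distribution


def test_schedule_two_staggered_drops():
    s = build_schedule([60.0, 100.0], t_n=40.0)
    np.testing.assert_allclose(s.drops, [60, 100])
    np.testing.assert_allclose(s.n_active, [2, 1])
    np.testing.assert_allclose(s.weights, [2 / 3, 1 / 3])
    assert s.segments == [(40.0, 60.0), (60.0, 100.0)]


def test_schedule_single_animal():
    s = build_schedule([72.0], t_n=40.0)
    np.testing.assert_allclose(s.weights, [1.0])


def test_schedule_tied_and_staggered_drops():
    s = build_schedule([50.0, 50.0, 90.0], t_n=40.0)
    np.testing.assert_allclose(s.drops, [50, 90])
    np.testing.assert_allclose(s.n_active, [3, 1])
    np.testing.assert_allclose(s.weights, [0.75, 0.25])


def test_schedule_rejects_empty_normal_region():
    with pytest.raises(ValueError, match="normal region"):
        build_schedule([10.0, 20.0], t_n=40.0)


def test_reference_idempotent_on_identical_hours():
    sched = build_schedule([60.0, 100.0], t_n=40.0)
    p_star = np.array([0.5, 0.3, 0.2])
    hourly = [_hd(h, p_star) for h in range(41, 101)]
    ref = reference_distribution(hourly, sched)
    np.testing.assert_allclose(ref.q, p_star, atol=1e-12)


def test_reference_equal_weight_segments():
    sched = build_schedule([50.0, 60.0], t_n=40.0)
    # one animal drops at 50, one at 60 -> weights (2/3, 1/3)... use equal
    # weights via a crafted schedule: two animals, both reaching 50, one to 60
    hourly = [_hd(h, [1, 0, 0]) for h in range(41, 51)]
    hourly += [_hd(h, [0, 1, 0]) for h in range(51, 61)]
    ref = reference_distribution(hourly, sched)
    w = sched.weights
    np.testing.assert_allclose(ref.q, [w[0], w[1], 0.0])


def test_reference_weighted_average_three_animals():
    sched = build_schedule([50.0, 50.0, 90.0], t_n=40.0)
    hourly = [_hd(h, [0.8, 0.1, 0.1]) for h in range(41, 51)]
    hourly += [_hd(h, [0.2, 0.4, 0.4]) for h in range(51, 91)]
    ref = reference_distribution(hourly, sched)
    np.testing.assert_allclose(ref.q, [0.65, 0.175, 0.175])


def test_reference_redistributes_weight_of_empty_segment():
    sched = build_schedule([50.0, 50.0, 90.0], t_n=40.0)
    hourly = [_hd(h, [0.2, 0.4, 0.4]) for h in range(51, 91)]  # first segment empty
    with pytest.warns(UserWarning, match="redistributed"):
        ref = reference_distribution(hourly, sched)
    np.testing.assert_allclose(ref.q, [0.2, 0.4, 0.4])


def test_equal_length_records_reduce_to_plain_average(rng):
    # single drop point -> one segment -> Q must equal the plain mean
    sched = build_schedule([80.0, 80.0, 80.0], t_n=40.0)
    hourly = [
        _hd(h, rng.dirichlet([2.0, 2.0, 2.0])) for h in range(41, 81)
    ]
    ref = reference_distribution(hourly, sched)
    np.testing.assert_allclose(ref.q, np.mean([h.p for h in hourly], axis=0))


# ---------------------------------------------------------------------------
# divergences


def test_kl_examples():
    assert kl_divergence([0.5, 0.5, 0], [0.5, 0.5, 0]) == 0.0
    assert kl_divergence([0.5, 0.5, 0], [0.25, 0.75, 0]) == pytest.approx(0.2075, abs=1e-4)
    assert kl_divergence([1, 0, 0], [0, 1, 0]) == np.inf


def test_js_examples():
    assert js_divergence([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0
    assert js_divergence([1, 0, 0], [0, 1, 0]) == pytest.approx(1.0, abs=1e-12)
    assert js_divergence([1, 0, 0], [0.5, 0.5, 0]) == pytest.approx(0.3113, abs=1e-4)


@given(probvec, probvec)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_js_symmetric_and_bounded(p, q):
    j = js_divergence(p, q)
    assert 0.0 <= j <= 1.0
    assert j == pytest.approx(js_divergence(q, p), abs=1e-12)
    if np.allclose(p, q):
        assert j == pytest.approx(0.0, abs=1e-12)
    else:
        assert j > 0.0


@given(probvec, probvec, probvec)
@settings(deadline=None, derandomize=True, max_examples=40)
def test_sqrt_js_triangle_inequality(p, q, r):
    d = lambda a, b: np.sqrt(js_divergence(a, b))
    assert d(p, r) <= d(p, q) + d(q, r) + 1e-9


def test_js_cross_check_scipy(rng):
    from scipy.spatial.distance import jensenshannon

    for _ in range(10):
        p, q = rng.dirichlet([1, 1, 1]), rng.dirichlet([1, 1, 1])
        assert js_divergence(p, q) == pytest.approx(
            jensenshannon(p, q, base=2) ** 2, abs=1e-10
        )


# ---------------------------------------------------------------------------
# region of recovery and labels


def test_ror_degenerate_when_all_hours_identical():
    sched = build_schedule([80.0, 80.0, 80.0], t_n=40.0)
    hourly = [_hd(h, [0.5, 0.3, 0.2]) for h in range(41, 81)]
    ror = region_of_recovery(hourly, sched, t_upper=80.0)
    assert ror.lo == pytest.approx(0.0, abs=1e-12)
    assert ror.hi == pytest.approx(ror.lo, abs=1e-12)


def test_ror_is_empirical_quantile_band_of_loo_divergences(rng):
    sched = build_schedule([80.0] * 4, t_n=40.0)
    hourly = [_hd(h, rng.dirichlet([8.0, 5.0, 3.0])) for h in range(41, 81)]
    hours, loo = leave_one_out_divergences(hourly, sched, 80.0)
    assert hours.size == 40
    ror = region_of_recovery(hourly, sched, t_upper=80.0)
    lo, hi = np.quantile(loo, [0.025, 0.975])
    assert (ror.lo, ror.hi) == (pytest.approx(lo), pytest.approx(hi))
    # widening T never shrinks the source set
    smaller = region_of_recovery(hourly, sched, t_upper=60.0)
    assert smaller.source_hours.size <= ror.source_hours.size


def test_ror_warns_when_few_hours():
    sched = build_schedule([50.0, 50.0], t_n=40.0)
    hourly = [_hd(h, [0.6, 0.3, 0.1]) for h in range(41, 51)]
    with pytest.warns(UserWarning, match="unstable"):
        region_of_recovery(hourly, sched, t_upper=46.0)


def test_leave_one_out_consistency_on_stationary_data():
    """With more normal-region hours, Q_-t converges to Q."""
    rng = np.random.default_rng(5)

    def max_gap(n_hours):
        end = 40.0 + n_hours
        sched = build_schedule([end] * 6, t_n=40.0)
        hourly = [_hd(h, rng.dirichlet([10.0, 6.0, 4.0])) for h in range(41, int(end) + 1)]
        ref = reference_distribution(hourly, sched)
        _, loo = leave_one_out_divergences(hourly, sched, end)
        full = np.array(
            [js_divergence(h.p, ref.q) for h in sorted(hourly, key=lambda h: h.hour)]
        )
        return np.max(np.abs(loo - full))

    small, large = max_gap(20), max_gap(160)
    assert large < small
    assert large < 2e-3


def test_pooled_ror_uses_combined_divergences(rng):
    sched = build_schedule([80.0] * 3, t_n=40.0)
    ha = [_hd(h, rng.dirichlet([8, 4, 2])) for h in range(41, 81)]
    hb = [_hd(h, rng.dirichlet([8, 4, 2])) for h in range(41, 81)]
    pooled = pooled_region_of_recovery([(ha, sched), (hb, sched)], 80.0)
    _, la = leave_one_out_divergences(ha, sched, 80.0)
    _, lb = leave_one_out_divergences(hb, sched, 80.0)
    lo, hi = np.quantile(np.concatenate([la, lb]), [0.025, 0.975])
    assert (pooled.lo, pooled.hi) == (pytest.approx(lo), pytest.approx(hi))


@pytest.mark.parametrize(
    "j, expected",
    [(0.05, 1), (0.5, -1), (0.1, 1), (0.01, 1), (0.005, -1)],  # closed at bounds
)
def test_label_series_interval_rule(j, expected):
    from tagrecover.entropy import RoR

    ror = RoR(0.01, 0.1, 0.95, np.arange(5), 80.0, np.full(5, 0.05))
    series = EntropySeries(np.array([3]), np.array([j]))
    labels = label_series(series, ror)
    assert labels["label"].tolist() == [expected]


def test_hourly_duration_profiles_sum_to_one(dive_table_factory):
    dives = dive_table_factory(
        [("a", 0.1, 90.0, "Shallow"), ("a", 0.5, 450.0, "Medium"),
         ("b", 0.7, 800.0, "Deep"), ("b", 1.2, 60.0, "Shallow")]
    )
    prof = hourly_duration_profiles(dives)
    sums = prof.groupby("hour")["share"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 1.0)
    row = prof[(prof["hour"] == 0) & (prof["category"] == "Medium")]
    assert row["duration_bin"].iloc[0] == "300-600s"
    assert row["share"].iloc[0] == pytest.approx(450.0 / (90 + 450 + 800))


def test_entropy_series_on_simulated_step_scenario_decays():
    sc = DiveScenario(n_animals=8, duration_h=90.0, t_star=10.0, seed=3)
    dives, _ = simulate_dives(sc)
    hourly = hourly_distributions(dives)
    sched = build_schedule(sc.resolved_drop_times(), t_n=40.0)
    ref = reference_distribution(hourly, sched)
    series = entropy_series(hourly, ref)
    early = series.values[series.hours < 10].mean()
    late = series.values[(series.hours > 40) & (series.hours <= 63)].mean()
    assert early > 5 * late
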