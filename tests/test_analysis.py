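"""Subsampling, moment computation, log-log fits, KDE, bootstrap, pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swimfatigue import (
    MomentSeries, compute_moments, fit_loglog, kde_density, bootstrap_ci,
    reliability_index, run_pipeline, simulate_experiment, subsample_by_length,
)
from swimfatigue.analysis import FitRefusedError

from conftest import make_trials


# ---------------------------------------------------------------- subsampling

def test_length_windows_split_where_ratio_exceeds_bound():
    trials = make_trials([4.0, 4.2, 4.4, 6.0])
    groups = subsample_by_length(trials, tolerance=0.10)
    members = [sorted(g.trials["fork_length"]) for g in groups]
    assert members == [[4.0, 4.2, 4.4], [6.0]]


def test_equal_lengths_form_one_group():
    groups = subsample_by_length(make_trials([5.0] * 8))
    assert len(groups) == 1 and groups[0].n_trials == 8


def test_huge_tolerance_collapses_to_one_group():
    groups = subsample_by_length(make_trials([1.0, 3.0, 9.0, 50.0]), tolerance=10)
    assert len(groups) == 1


def test_unsuccessful_trials_are_excluded():
    trials = make_trials([5.0, 5.1, 5.2], success=[True, False, True])
    groups = subsample_by_length(trials)
    assert sum(g.n_trials for g in groups) == 2


def test_tolerance_must_be_positive():
    with pytest.raises(ValueError):
        subsample_by_length(make_trials([5.0]), tolerance=0.0)


@settings(max_examples=50, deadline=None)
@given(lengths=st.lists(st.floats(0.5, 100.0), min_size=1, max_size=40))
def test_windows_are_disjoint_cover_and_respect_tolerance(lengths):
    trials = make_trials(lengths)
    groups = subsample_by_length(trials, tolerance=0.10)
    ids = sorted(i for g in groups for i in g.trials["fish_id"])
    assert ids == sorted(trials["fish_id"])          # disjoint cover
    assert all(g.check() for g in groups)            # +/-10% of each center


# ---------------------------------------------------------------- moments

def test_moments_of_constant_sample():
    trials = make_trials([5.0] * 3, T_f=[5.0, 5.0, 5.0])
    mean, var = compute_moments(trials, k_max=2)
    assert mean.table["value"].iloc[0] == 5.0
    assert var.table["value"].iloc[0] == 0.0


def test_population_convention_and_sample_switch():
    trials = make_trials([5.0] * 3, T_f=[1.0, 2.0, 3.0])
    mean, var = compute_moments(trials, k_max=2)
    assert mean.table["value"].iloc[0] == pytest.approx(2.0)
    assert var.table["value"].iloc[0] == pytest.approx(2 / 3)   # divide by n
    _, var1 = compute_moments(trials, k_max=2, ddof=1)
    assert var1.table["value"].iloc[0] == pytest.approx(1.0)


def test_singleton_velocity_kept_for_mean_dropped_for_variance():
    trials = make_trials([5.0] * 4, U_f=[40, 40, 50, 55], T_f=[3, 5, 2, 1])
    mean, var = compute_moments(trials, k_max=2)
    assert set(mean.table["U_f"]) == {40, 50, 55}
    assert set(var.table["U_f"]) == {40}             # only level with n >= 2


# ---------------------------------------------------------------- regression

def _series(U, values, n_per=50, k=1):
    table = pd.DataFrame({"U_f": U, "n": n_per, "value": values})
    return MomentSeries(group_id="g0", k=k, table=table)


def test_exact_mean_power_law_recovered():
    U = np.array([40.0, 45.0, 50.0, 55.0])
    fit = fit_loglog(_series(U, 1e6 * U**-3.0, k=1))
    assert fit.slope == pytest.approx(-3.0, abs=1e-10)
    assert fit.beta_hat == pytest.approx(2.0, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.accepted and fit.physical
    assert fit.alpha_coefficient == pytest.approx(1e6, rel=1e-9)


def test_exact_variance_power_law_recovered():
    U = np.array([45.0, 50.0, 55.0])
    fit = fit_loglog(_series(U, 1e12 * U**-5.46, k=2))
    assert fit.slope == pytest.approx(-5.46, abs=1e-10)
    assert fit.beta_hat == pytest.approx(1.73, abs=1e-10)


def test_constant_moment_is_rejected_and_flagged():
    fit = fit_loglog(_series([40.0, 45.0, 50.0, 55.0], [7.0] * 4))
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert not fit.physical
    assert not fit.accepted


def test_fit_refused_below_three_levels():
    with pytest.raises(FitRefusedError):
        fit_loglog(_series([40.0, 50.0], [2.0, 1.0]))


def test_nonpositive_moments_dropped_with_warning(caplog):
    U = np.array([40.0, 45.0, 50.0, 55.0])
    vals = 1e6 * U**-3.0
    vals[0] = 0.0
    with caplog.at_level("WARNING", logger="swimfatigue.analysis"):
        fit = fit_loglog(_series(U, vals))
    assert fit.n_points == 3
    assert "dropped" in caplog.text
    assert fit.slope == pytest.approx(-3.0, abs=1e-10)


def test_fit_bookkeeping_feeds_reliability_index():
    U = np.array([40.0, 45.0, 50.0, 55.0])
    fit = fit_loglog(_series(U, 1e6 * U**-3.0, n_per=25))
    assert fit.p_trials == 100
    assert (fit.U_min, fit.U_max) == (40.0, 55.0)
    assert fit.rei == pytest.approx(100 * np.log(55 / 40))


@pytest.mark.parametrize("p, Umax, Umin, expected", [
    (0, 60.0, 50.0, 0.0),
    (100, 50.0, 50.0, 0.0),
    (100, 60.0, 50.0, 18.232155679395463),   # frozen: 100 ln(1.2) at 30 digits
])
def test_reliability_index(p, Umax, Umin, expected):
    assert reliability_index(p, Umax, Umin) == pytest.approx(expected, abs=1e-12)


def test_reliability_index_domain():
    with pytest.raises(ValueError):
        reliability_index(10, 50.0, 0.0)
    with pytest.raises(ValueError):
        reliability_index(-1, 60.0, 50.0)


# ---------------------------------------------------------------- KDE

def test_kde_integrates_to_one_within_two_percent():
    rng = np.random.default_rng(0)
    for n in (10, 50, 500):
        d = kde_density(rng.lognormal(2.0, 0.5, n))
        assert d.integral == pytest.approx(1.0, abs=0.02)
        assert (d.density >= 0).all()


def test_kde_degenerate_sample_peaks_at_value():
    d = kde_density([7.0, 7.0])
    assert d.grid[np.argmax(d.density)] == pytest.approx(7.0, abs=1e-2)


def test_kde_needs_two_values():
    with pytest.raises(ValueError):
        kde_density([3.0])


def test_fatigue_spread_narrows_with_velocity(default_config):
    """Higher test velocity, tighter time-to-fatigue distribution."""
    tr = simulate_experiment(default_config, [40, 45, 50, 55], 300, seed=8)
    widths = {}
    for U, vals in tr.groupby("U_f")["T_f"]:
        widths[U] = kde_density(vals, U_f=U).interquartile_width()
    assert widths[40] > widths[55]


# ---------------------------------------------------------------- bootstrap

def test_bootstrap_degenerate_sample_zero_width():
    assert bootstrap_ci([5.0] * 4, np.mean, reps=200, seed=0) == (5.0, 5.0)


def test_bootstrap_reproducible():
    x = np.random.default_rng(1).lognormal(1.0, 0.5, 50)
    assert bootstrap_ci(x, np.mean, seed=42) == bootstrap_ci(x, np.mean, seed=42)


def test_bootstrap_rejects_few_reps():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0, 2.0], np.mean, reps=10)


def test_bootstrap_coverage_near_nominal():
    """Percentile interval for the mean of a lognormal sample: ~95% coverage."""
    rng = np.random.default_rng(123)
    true_mean = np.exp(1.0 + 0.5**2 / 2)
    hits = 0
    runs = 100
    for _ in range(runs):
        x = rng.lognormal(1.0, 0.5, 100)
        lo, hi = bootstrap_ci(x, np.mean, reps=300, seed=rng)
        hits += lo <= true_mean <= hi
    assert 0.85 <= hits / runs <= 0.99


# ---------------------------------------------------------------- pipeline

def test_noiseless_pipeline_recovers_exponent_exactly(noiseless_config):
    tr = simulate_experiment(noiseless_config, [40, 45, 50, 55], 50, seed=1)
    res = run_pipeline(tr)
    accepted = [f for f in res.fits if f.accepted and f.k == 1]
    assert accepted
    for f in accepted:
        assert f.beta_hat == pytest.approx(noiseless_config.beta_true, abs=1e-10)


def test_pipeline_reports_refusals_not_errors():
    # two velocity levels only: every group's regression must be refused
    trials = make_trials([5.0] * 8, U_f=[40, 40, 40, 40, 55, 55, 55, 55],
                         T_f=[9, 8, 7, 9, 2, 3, 2, 2])
    res = run_pipeline(trials)
    assert res.fits == []
    assert res.refused and all("usable velocity" in r["reason"]
                               for r in res.refused)


def test_pipeline_success_summary_counts():
    trials = make_trials([5.0] * 4, success=[True, True, True, False])
    res = run_pipeline(trials)
    row = res.success_summary.loc["TOTAL"]
    assert (row["total_fish"], row["successful_trials"]) == (4, 3)
    assert row["success_rate_pct"] == 75


def test_pipeline_groups_respect_length_windows(default_config):
    tr = simulate_experiment(default_config, [45, 50, 55], 120, seed=3)
    res = run_pipeline(tr)
    assert len(res.groups) >= 2            # realistic length spread splits
    assert all(g.check() for g in res.groups)


def test_pooled_estimate_aggregates_by_reliability(default_config):
    tr = simulate_experiment(default_config, [40, 45, 50, 55], 200, seed=10)
    res = run_pipeline(tr)
    est = res.pooled(k=1)
    lo = min(f.beta_hat for f in res.fits if f.k == 1 and f.physical)
    hi = max(f.beta_hat for f in res.fits if f.k == 1 and f.physical)
    assert lo <= est.beta_hat <= hi
    assert est.p_trials == sum(f.p_trials for f in res.fits
                               if f.k == 1 and f.physical)
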