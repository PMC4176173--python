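"""Induction experiment, velocity estimator, steady state and queues."""

import numpy as np
import pytest

from rnapjam.core_model import GeneModel, KineticParams, Scenario, build_gene
from rnapjam.kmc_engine import preload, run
from rnapjam import virtual_experiments as vx


# ---------------------------------------------------------------------------
# analytic oracles


def test_analytic_transit_time():
    assert vx.analytic_transit_time(100, 0, 50.0, 1.0, 10.0) == pytest.approx(2.0)
    assert vx.analytic_transit_time(100, 5, 50.0, 1.0, 10.0) == pytest.approx(3.0)
    # f=0 reduces to L/eps for any pause count
    assert vx.analytic_transit_time(100, 7, 50.0, 0.0, 99.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        vx.analytic_transit_time(100, 0, 0.0, 1.0, 1.0)


def test_max_current_bound():
    assert vx.max_current_bound(60.0, 1) == pytest.approx(15.0)
    assert vx.max_current_bound(60.0, 35) == pytest.approx(60.0 / (1 + np.sqrt(35)) ** 2)
    bounds = [vx.max_current_bound(60.0, d) for d in (1, 4, 16, 35, 50)]
    assert all(a > b for a, b in zip(bounds, bounds[1:]))
    with pytest.raises(ValueError):
        vx.max_current_bound(60.0, 0)


# ---------------------------------------------------------------------------
# induction and velocity


@pytest.fixture(scope="module")
def small_induction():
    gene = build_gene(800, 0.005, seed=2)
    params = KineticParams(alpha=0.3, epsilon=50.0, f=0.2, tau=1.0, footprint=35, dt=0.002)
    return gene, vx.simulate_induction(gene, params, n_runs=150, seed=4, duration=60.0)


def test_induction_signal_invariants(small_induction):
    gene, sig = small_induction
    assert sig.early_signal[0] == 0.0 and sig.late_signal[0] == 0.0
    assert np.all(np.diff(sig.early_signal) >= 0)
    assert np.all(np.diff(sig.late_signal) >= 0)
    assert np.all(sig.early_signal >= sig.late_signal)
    assert sig.early_signal[-1] > 0


def test_signal_series_validation():
    t = np.arange(5.0)
    with pytest.raises(ValueError):
        vx.ProbeSignalSeries(t, np.array([0, 1, 2, 3, 4.0]), np.array([0, 1, 3, 3, 4.0]), 1)
    with pytest.raises(ValueError):
        vx.ProbeSignalSeries(t, np.array([0, 2, 1, 3, 4.0]), np.zeros(5), 1)


def test_equal_asymptotic_slopes_without_pausing():
    gene = build_gene(800, 0.0, seed=2)
    params = KineticParams(alpha=0.3, epsilon=50.0, f=0.0, footprint=35, dt=0.002)
    sig = vx.simulate_induction(gene, params, n_runs=200, seed=9, duration=60.0)
    assert vx.slope_ratio(sig) == pytest.approx(1.0, abs=0.1)


def test_velocity_on_exact_linear_signals():
    """Onsets 10 s and 45 s at 2100 nt probe distance give 60 nt/s."""
    gene = GeneModel(2700, (), (1, 500), (2101, 2600))
    t = np.linspace(0, 150, 601)
    early = np.clip(t - 10.0, 0, None) * 0.2
    late = np.clip(t - 45.0, 0, None) * 0.2
    sig = vx.ProbeSignalSeries(t, early, late, n_runs=1)
    v = vx.estimate_velocity(sig, gene)
    assert v.probe_distance == 2100
    assert v.onset_early == pytest.approx(10.0, abs=0.1)
    assert v.onset_late == pytest.approx(45.0, abs=0.1)
    assert v.velocity == pytest.approx(60.0, rel=0.02)
    # the threshold alternative crosses a fraction of each signal's own
    # final value, so it overestimates when the window truncates the late
    # signal more than the early one; it stays within ~15% here
    vt = vx.estimate_velocity(sig, gene, method="threshold")
    assert vt.velocity == pytest.approx(60.0, rel=0.15)


def test_velocity_estimator_consistency():
    """Pause-free estimate converges to the configured stepping rate."""
    gene = build_gene(1200, 0.0, seed=1)
    params = KineticParams(alpha=0.3, epsilon=50.0, f=0.0, footprint=35, dt=0.002)
    sig = vx.simulate_induction(gene, params, n_runs=300, seed=6, duration=60.0)
    v = vx.estimate_velocity(sig, gene)
    assert v.velocity == pytest.approx(50.0, rel=0.05)
    assert v.onset_late > v.onset_early


def test_no_onset_error():
    gene = build_gene(800, 0.0, seed=2)
    t = np.linspace(0, 10, 50)
    flat = vx.ProbeSignalSeries(t, np.zeros(50), np.zeros(50), 1)
    with pytest.raises(vx.NoOnsetError):
        vx.estimate_velocity(flat, gene)


# ---------------------------------------------------------------------------
# steady state


def test_initiation_limited_rate_matches_alpha():
    """alpha far below saturation: throughput equals the initiation rate."""
    gene = build_gene(1000, 0.0, seed=0)
    params = KineticParams(alpha=0.01, epsilon=60.0, footprint=35, dt=0.003)
    res = vx.steady_state_rate(gene, params, n_steps=20_000_000, seed=13)
    assert res.transcription_rate == pytest.approx(0.01, rel=0.05)
    assert res.mean_occupancy < 1.0


def test_longer_stalls_reduce_rate():
    gene = build_gene(600, 0.005, seed=11)
    base = KineticParams(alpha=0.5, epsilon=62.0, f=0.2, tau=1.0, footprint=35, dt=0.002)
    long_stall = KineticParams(alpha=0.5, epsilon=62.0, f=0.2, tau=100.0, footprint=35, dt=0.002)
    n_steps = 2_000_000
    r_wt = np.mean(
        [vx.steady_state_rate(gene, base, n_steps, seed=s).transcription_rate for s in (1, 2)]
    )
    r_mut = np.mean(
        [
            vx.steady_state_rate(gene, long_stall, n_steps, seed=s).transcription_rate
            for s in (1, 2)
        ]
    )
    assert r_mut < r_wt


def test_steady_state_errors_and_warnings():
    gene = build_gene(600, 0.0, seed=0)
    none = KineticParams(alpha=0.0, epsilon=50.0, dt=0.002)
    with pytest.warns(UserWarning):
        with pytest.raises(vx.UndefinedRateError):
            vx.steady_state_rate(gene, none, n_steps=10_000, seed=0)
    with pytest.raises(ValueError):
        vx.steady_state_rate(gene, none, n_steps=1000, burn_in_fraction=1.2)


# ---------------------------------------------------------------------------
# sweeps (small versions; full-scale patterns live in the acceptance suite)


def test_sweep_alpha_wildtype_fold_is_unity():
    gene = build_gene(400, 0.0, seed=0)
    base = KineticParams(alpha=0.1, epsilon=50.0, f=0.0, footprint=35, dt=0.002)
    tab = vx.sweep_alpha(
        gene, base, Scenario("wildtype"), [0.05, 0.5], n_steps=1_500_000, n_reps=3, seed=21
    )
    for _, row in tab.iterrows():
        assert row.fold_change == pytest.approx(1.0, abs=0.1)
        assert row.fold_ci_lo <= 1.0 <= row.fold_ci_hi


def test_sweep_alpha_validates_grid():
    gene = build_gene(400, 0.0, seed=0)
    base = KineticParams(alpha=0.1, epsilon=50.0, dt=0.002)
    with pytest.raises(ValueError):
        vx.sweep_alpha(gene, base, Scenario("wildtype"), [0.5, 0.1], n_steps=1000)
    with pytest.raises(ValueError):
        vx.sweep_alpha(gene, base, Scenario("wildtype"), [-0.1, 0.5], n_steps=1000)


def test_sweep_length_no_pausing_fold_is_unity():
    base = KineticParams(alpha=1.0, epsilon=50.0, f=0.0, footprint=35, dt=0.002)
    tab = vx.sweep_length(
        base,
        Scenario("nogre_pause_duration", 100.0),
        [300, 600],
        pause_density=0.0,
        n_steps=400_000,
        n_reps=3,
        seed=31,
    )
    # with f=0 the tau scenario is inert
    assert np.allclose(tab.fold_change, 1.0, atol=0.08)


# ---------------------------------------------------------------------------
# queue statistics


def _stalled_run(duration, alpha=2.0):
    gene = GeneModel(600, (300,), (1, 100), (500, 600))
    # effectively permanent stall; rescue rate ~1e-9
    params = KineticParams(alpha=alpha, epsilon=50.0, f=1e-9, tau=1e9, footprint=35, dt=0.002)
    start = preload(gene, [300], states=["stalled"], footprint=35)
    return gene, run(
        gene,
        params,
        duration=duration,
        seed=5,
        record_interval=1.0,
        preloaded=start,
        record_positions=True,
    )


def test_queue_grows_behind_forced_stall(check_trajectory):
    gene, short = _stalled_run(30.0)
    _, long = _stalled_run(120.0)
    check_trajectory(short)
    qs_short = vx.queue_statistics(short, 35)
    qs_long = vx.queue_statistics(long, 35)
    # the queue keeps building until the upstream lattice saturates at
    # floor(300/35) = 8 complexes packed behind the stall
    assert qs_long.mean_size > qs_short.mean_size >= 1
    assert qs_short.max_size == qs_long.max_size == 8
    assert qs_long.fraction_snapshots_with_queue > 0.5
    assert qs_long.fraction_promoter_blocked > qs_short.fraction_promoter_blocked > 0.0


def test_queue_stats_trivial_cases(plain_gene, single_complex_params):
    traj = run(
        plain_gene,
        single_complex_params,
        duration=1.0,
        seed=1,
        record_interval=0.1,
        preloaded=preload(plain_gene, [1]),
        record_positions=True,
    )
    qs = vx.queue_statistics(traj, 35)
    assert qs.max_size == 0
    assert qs.fraction_snapshots_with_queue == 0.0
    # f=0 under traffic: no stalled complexes, hence no queues behind stalls
    gene = build_gene(300, 0.01, seed=1)
    p = KineticParams(alpha=2.0, epsilon=50.0, f=0.0, footprint=35, dt=0.002)
    traj2 = run(gene, p, duration=20.0, seed=3, record_interval=0.2, record_positions=True)
    qs2 = vx.queue_statistics(traj2, 35)
    assert qs2.fraction_snapshots_with_queue == 0.0
    with pytest.raises(ValueError):
        vx.queue_statistics(run(gene, p, duration=1.0, seed=1), 35)  # no positions
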