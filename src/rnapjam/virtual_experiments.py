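"""In-silico experiments on the elongation model.

Three virtual experiments mirror the study design of the wet-lab assays the
model was built to interpret:

* an *induction* (two-probe) experiment: start from an empty lattice, track
  run-averaged cumulative amounts of transcript that carry the early (5')
  and late (3') probe targets, and estimate the elongation velocity as
  probe distance over the difference in signal onset times;
* a *steady-state expression sweep* over initiation rate alpha (expression
  level) comparing wild type against a no-Gre scenario;
* a *gene-length sweep* at fixed pause density.

Analytic oracles (`analytic_transit_time`, `max_current_bound`) provide
independent closed-form checks on the simulation engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_model import GeneModel, KineticParams, Scenario, apply_scenario, build_gene
from .kmc_engine import Trajectory, run

__all__ = [
    "ProbeSignalSeries",
    "VelocityEstimate",
    "SteadyStateResult",
    "QueueStats",
    "NoOnsetError",
    "UndefinedRateError",
    "simulate_induction",
    "estimate_velocity",
    "slope_ratio",
    "steady_state_rate",
    "sweep_alpha",
    "sweep_length",
    "queue_statistics",
    "analytic_transit_time",
    "max_current_bound",
]


class NoOnsetError(RuntimeError):
    """A probe signal never rises enough to define an onset time."""


class UndefinedRateError(RuntimeError):
    """No completions observed; the steady-state rate is undefined."""


@dataclass(frozen=True)
class ProbeSignalSeries:
    """Run-averaged cumulative probe signals of an induction experiment.

    ``early_signal[t]`` is the mean number of transcripts (on-lattice or
    completed) whose active site has passed the early probe's 3' end by
    time ``times[t]``; likewise ``late_signal``.  Both are non-decreasing
    and ``early >= late`` pointwise.
    """

    times: np.ndarray
    early_signal: np.ndarray
    late_signal: np.ndarray
    n_runs: int
    gene: GeneModel | None = None

    def __post_init__(self) -> None:
        e, l = np.asarray(self.early_signal), np.asarray(self.late_signal)
        if np.any(np.diff(e) < -1e-9) or np.any(np.diff(l) < -1e-9):
            raise ValueError("probe signals must be non-decreasing")
        if np.any(l - e > 1e-9):
            raise ValueError("late signal exceeded early signal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "early": self.early_signal, "late": self.late_signal}
        )


@dataclass(frozen=True)
class VelocityEstimate:
    """Two-probe elongation velocity: probe distance over onset difference."""

    velocity: float
    onset_early: float
    onset_late: float
    probe_distance: float


@dataclass(frozen=True)
class QueueStats:
    """Statistics of traffic jams: runs of complexes packed behind a stall."""

    size_histogram: dict[int, int]
    mean_size: float
    max_size: int
    fraction_snapshots_with_queue: float
    fraction_promoter_blocked: float


@dataclass(frozen=True)
class SteadyStateResult:
    transcription_rate: float  # transcripts/s
    mean_occupancy: float  # mean complexes on the gene
    completions: int
    elapsed: float  # post-burn-in seconds
    queue_stats: QueueStats | None = None


# ---------------------------------------------------------------------------
# analytic oracles


def analytic_transit_time(L: int, n_pause: int, epsilon: float, f: float, tau: float) -> float:
    """Exact mean single-complex transit time of the continuous-time model.

    Crossing each of ``L`` sites costs ``1/epsilon`` on average; at each of
    the ``n_pause`` pause sites the complex suffers ``f/epsilon`` stall
    events on average, each of mean duration ``tau``, giving
    ``(L + n_pause*f*tau)/epsilon``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return (L + n_pause * f * tau) / epsilon


def max_current_bound(epsilon: float, d: int) -> float:
    """Maximal steady-state flux of an exclusion process with particle size d.

    The classic maximal-current result ``epsilon/(1+sqrt(d))**2``; reduces
    to ``epsilon/4`` for point particles.
    """
    if d < 1:
        raise ValueError("footprint d must be >= 1")
    return epsilon / (1.0 + np.sqrt(d)) ** 2


# ---------------------------------------------------------------------------
# induction experiment and velocity estimator


def simulate_induction(
    gene: GeneModel,
    params: KineticParams,
    n_runs: int,
    seed: int = 0,
    duration: float = 150.0,
    record_interval: float = 0.25,
) -> ProbeSignalSeries:
    """Induction experiment: empty lattice at t=0, averaged over replicates.

    Replicate ``r`` uses seed ``(seed + r) % 2**31``.  Signals count
    transcripts extended past each probe window's 3' end (an RNA must
    contain the full probe target to hybridise), including completed ones.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    thr = [gene.probe_early[1], gene.probe_late[1]]
    acc_e = acc_l = times = None
    for r in range(n_runs):
        traj = run(
            gene,
            params,
            duration=duration,
            seed=(seed + r) % 2**31,
            record_interval=record_interval,
            thresholds=thr,
        )
        if times is None:
            times = traj.times
            acc_e = traj.passed[:, 0].astype(float)
            acc_l = traj.passed[:, 1].astype(float)
        else:
            acc_e += traj.passed[:, 0]
            acc_l += traj.passed[:, 1]
    return ProbeSignalSeries(
        times=times,
        early_signal=acc_e / n_runs,
        late_signal=acc_l / n_runs,
        n_runs=n_runs,
        gene=gene,
    )


def _onset_risefit(times: np.ndarray, signal: np.ndarray, lo: float, hi: float) -> float:
    final = signal[-1]
    if final <= 0:
        raise NoOnsetError("signal never rises above zero")
    sel = (signal >= lo * final) & (signal <= hi * final)
    if sel.sum() < 2:
        raise NoOnsetError(
            f"fewer than 2 samples in the {lo:.0%}-{hi:.0%} rising phase; "
            "record more finely or extend the run"
        )
    slope, intercept = np.polyfit(times[sel], signal[sel], 1)
    if slope <= 0:
        raise NoOnsetError("rising-phase fit has non-positive slope")
    return -intercept / slope


def _onset_threshold(times: np.ndarray, signal: np.ndarray, frac: float) -> float:
    final = signal[-1]
    if final <= 0:
        raise NoOnsetError("signal never rises above zero")
    idx = np.nonzero(signal >= frac * final)[0]
    return float(times[idx[0]])


def estimate_velocity(
    signals: ProbeSignalSeries,
    gene: GeneModel | None = None,
    method: str = "risefit",
    fit_lo: float = 0.10,
    fit_hi: float = 0.50,
) -> VelocityEstimate:
    """Elongation velocity from the two probe signals.

    The onset of each signal is the x-intercept of a straight line fitted
    to its rising phase (samples between ``fit_lo`` and ``fit_hi`` of the
    signal's value at the end of the fitting window); the velocity is the
    distance between the probes' 3' ends divided by the onset difference.
    ``method="threshold"`` instead takes the first crossing of
    ``fit_lo * final`` as the onset.
    """
    gene = gene or signals.gene
    if gene is None:
        raise ValueError("gene required to compute the probe distance")
    t = np.asarray(signals.times)
    if method == "risefit":
        onset_e = _onset_risefit(t, np.asarray(signals.early_signal), fit_lo, fit_hi)
        onset_l = _onset_risefit(t, np.asarray(signals.late_signal), fit_lo, fit_hi)
    elif method == "threshold":
        onset_e = _onset_threshold(t, np.asarray(signals.early_signal), fit_lo)
        onset_l = _onset_threshold(t, np.asarray(signals.late_signal), fit_lo)
    else:
        raise ValueError(f"unknown onset method {method!r}")
    if onset_l <= onset_e:
        raise NoOnsetError(
            f"late onset ({onset_l:.2f}s) not after early onset ({onset_e:.2f}s)"
        )
    dist = gene.probe_distance
    return VelocityEstimate(
        velocity=dist / (onset_l - onset_e),
        onset_early=onset_e,
        onset_late=onset_l,
        probe_distance=dist,
    )


def slope_ratio(signals: ProbeSignalSeries, tail_fraction: float = 0.3) -> float:
    """Ratio of late to early signal slopes over the final part of the run.

    Equal asymptotic slopes (ratio ~1) mean every complex that passes the
    early probe eventually passes the late probe within the window; a
    reduced ratio is the signature of complexes lost to long-lived stalls.
    """
    t = np.asarray(signals.times)
    sel = t >= t[-1] * (1.0 - tail_fraction)
    slope_e = np.polyfit(t[sel], np.asarray(signals.early_signal)[sel], 1)[0]
    slope_l = np.polyfit(t[sel], np.asarray(signals.late_signal)[sel], 1)[0]
    if slope_e <= 0:
        raise NoOnsetError("early signal has non-positive tail slope")
    return slope_l / slope_e


# ---------------------------------------------------------------------------
# steady state and sweeps


def steady_state_rate(
    gene: GeneModel,
    params: KineticParams,
    n_steps: int,
    burn_in_fraction: float = 0.1,
    seed: int = 0,
    record_interval: float | None = None,
    with_queue_stats: bool = False,
) -> SteadyStateResult:
    """Time-averaged transcription rate after a burn-in.

    The rate is completions after burn-in divided by the post-burn-in time.
    Warns when fewer than 100 completions are expected there (estimated
    from ``min(alpha, max-current bound)``).
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must lie in [0, 1)")
    t_post = n_steps * params.dt * (1 - burn_in_fraction)
    expected = min(params.alpha, max_current_bound(params.epsilon, params.footprint)) * t_post
    if expected < 100:
        warnings.warn(
            f"only ~{expected:.0f} completions expected post-burn-in; "
            "rate estimate will be noisy",
            stacklevel=2,
        )
    if record_interval is None:
        record_interval = max(params.dt, n_steps * params.dt / 2000)
    traj = run(
        gene,
        params,
        n_steps=n_steps,
        seed=seed,
        record_interval=record_interval,
        record_positions=with_queue_stats,
    )
    t = traj.times
    burn_t = n_steps * params.dt * burn_in_fraction
    i0 = int(np.searchsorted(t, burn_t))
    i0 = min(i0, len(t) - 2)
    completions = int(traj.completed[-1] - traj.completed[i0])
    elapsed = float(t[-1] - t[i0])
    if completions == 0:
        raise UndefinedRateError(
            f"zero completions in {elapsed:.0f}s post-burn-in "
            f"(alpha={params.alpha}, epsilon={params.epsilon}, f={params.f}, "
            f"tau={params.tau}, L={gene.length}); lengthen the run"
        )
    occ = float(np.mean(traj.on_lattice[i0:]))
    qs = queue_statistics(traj, params.footprint) if with_queue_stats else None
    return SteadyStateResult(
        transcription_rate=completions / elapsed,
        mean_occupancy=occ,
        completions=completions,
        elapsed=elapsed,
        queue_stats=qs,
    )


def _replicate_rates(gene, params, n_steps, seed, n_reps, burn_in_fraction):
    rates = []
    for r in range(n_reps):
        res = steady_state_rate(
            gene, params, n_steps, burn_in_fraction, seed=(seed + r) % 2**31
        )
        rates.append(res.transcription_rate)
    return np.asarray(rates)


def _bootstrap_ci(values: np.ndarray, n_resamples: int, rng: np.random.Generator, q=(2.5, 97.5)):
    idx = rng.integers(0, len(values), size=(n_resamples, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, q)
    return float(lo), float(hi)


def _sweep_row(gene, base, scen_params, n_steps, seed, n_reps, n_boot, burn_in):
    rng = np.random.default_rng(seed)
    r_wt = _replicate_rates(gene, base, n_steps, seed, n_reps, burn_in)
    r_sc = _replicate_rates(gene, scen_params, n_steps, seed + 10_000, n_reps, burn_in)
    fold = r_wt.mean() / r_sc.mean()
    # bootstrap the fold change by resampling replicate pairs
    idx = rng.integers(0, n_reps, size=(n_boot, n_reps))
    f_boot = r_wt[idx].mean(axis=1) / np.maximum(r_sc[idx].mean(axis=1), 1e-12)
    lo, hi = np.percentile(f_boot, [2.5, 97.5])
    return r_wt.mean(), r_sc.mean(), fold, float(lo), float(hi)


def suggest_n_steps(
    params: KineticParams,
    target_completions: int = 200,
    min_time: float = 200.0,
    tau_multiples: float = 40.0,
) -> int:
    """Steps for roughly ``target_completions`` post-burn-in.

    The run must also cover many stall lifetimes (``tau_multiples * tau``
    when pausing is active), otherwise long-pause conditions are sampled
    far from their steady state.
    """
    rate = min(params.alpha, max_current_bound(params.epsilon, params.footprint))
    t = max(min_time, target_completions / max(rate, 1e-9))
    if params.f > 0:
        t = max(t, tau_multiples * params.tau)
    return int(round(t / params.dt))


def sweep_alpha(
    gene: GeneModel,
    base_params: KineticParams,
    scenario: Scenario,
    alpha_grid,
    n_steps: int | None = None,
    n_reps: int = 6,
    n_boot: int = 200,
    burn_in_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Steady-state rate and WT/scenario fold change across expression levels.

    The transcription rate serves as the measure of gene expression; the
    fold change ``rate_wt / rate_scenario`` (> 1 means expression reduced
    without the Gre factor) is reported with a bootstrap CI over replicate
    runs (paired seed batches for the two conditions).
    """
    alpha_grid = list(alpha_grid)
    if any(a <= 0 for a in alpha_grid) or sorted(alpha_grid) != alpha_grid:
        raise ValueError("alpha_grid must be positive and ascending")
    rows = []
    for k, a in enumerate(alpha_grid):
        wt = replace(base_params, alpha=a)
        sc = apply_scenario(wt, scenario)
        steps = n_steps if n_steps is not None else max(suggest_n_steps(wt), suggest_n_steps(sc))
        rw, rs, fold, lo, hi = _sweep_row(
            gene, wt, sc, steps, seed + 1000 * k, n_reps, n_boot, burn_in_fraction
        )
        rows.append((a, rw, rs, fold, np.log2(fold), lo, hi))
    return pd.DataFrame(
        rows,
        columns=[
            "alpha",
            "rate_wt",
            "rate_scenario",
            "fold_change",
            "log2_fold_change",
            "fold_ci_lo",
            "fold_ci_hi",
        ],
    )


def sweep_length(
    base_params: KineticParams,
    scenario: Scenario,
    L_grid,
    pause_density: float = 0.005,
    gene_seed: int = 7,
    n_steps: int | None = None,
    n_reps: int = 6,
    n_boot: int = 200,
    burn_in_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold change across gene lengths at fixed pause density."""
    L_grid = list(L_grid)
    rows = []
    for k, L in enumerate(L_grid):
        gene = build_gene(int(L), pause_density, seed=gene_seed + k)
        sc = apply_scenario(base_params, scenario)
        steps = (
            n_steps
            if n_steps is not None
            else max(suggest_n_steps(base_params), suggest_n_steps(sc))
        )
        rw, rs, fold, lo, hi = _sweep_row(
            gene, base_params, sc, steps, seed + 1000 * k, n_reps, n_boot, burn_in_fraction
        )
        rows.append((L, rw, rs, fold, np.log2(fold), lo, hi))
    return pd.DataFrame(
        rows,
        columns=[
            "length",
            "rate_wt",
            "rate_scenario",
            "fold_change",
            "log2_fold_change",
            "fold_ci_lo",
            "fold_ci_hi",
        ],
    )


# ---------------------------------------------------------------------------
# queue statistics


def queue_statistics(trajectory: Trajectory, d: int) -> QueueStats:
    """Traffic-jam statistics over a position-recorded trajectory.

    A queue is a maximal run of complexes at mutual spacing exactly ``d``
    immediately behind a stalled complex; its size counts the queued
    complexes (excluding the stalled leader).  The promoter-proximal
    region counts as blocked when sites ``[1, d]`` are occupied.
    """
    if trajectory.snapshot_positions is None:
        raise ValueError("queue statistics need a trajectory recorded with positions")
    if trajectory.n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    hist: dict[int, int] = {}
    snaps_with_queue = 0
    promoter_blocked = 0
    max_size = 0
    sizes_sum = 0
    n_stalled_leaders = 0
    for i in range(trajectory.n_snapshots):
        pos, states = trajectory.snapshot(i)  # descending positions
        if pos.size and pos[-1] <= d:
            promoter_blocked += 1
        any_queue = False
        for j in range(pos.size):
            if states[j] != 1:  # stalled leaders only
                continue
            size = 0
            k = j
            while k + 1 < pos.size and pos[k] - pos[k + 1] == d:
                size += 1
                k += 1
            hist[size] = hist.get(size, 0) + 1
            sizes_sum += size
            n_stalled_leaders += 1
            max_size = max(max_size, size)
            if size > 0:
                any_queue = True
        if any_queue:
            snaps_with_queue += 1
    n_snap = trajectory.n_snapshots
    return QueueStats(
        size_histogram=dict(sorted(hist.items())),
        mean_size=sizes_sum / n_stalled_leaders if n_stalled_leaders else 0.0,
        max_size=max_size,
        fraction_snapshots_with_queue=snaps_with_queue / n_snap,
        fraction_promoter_blocked=promoter_blocked / n_snap,
    )
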