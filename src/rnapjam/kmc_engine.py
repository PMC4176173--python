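"""Fixed-timestep kinetic Monte Carlo simulation of elongation traffic.

Elongation complexes are stochastic steppers on a 1-D lattice with hard-core
exclusion: each occupies ``footprint`` sites ``[position, position+d-1]``
(``position`` = active site), so positions of any two complexes differ by at
least ``d``.  Per timestep ``dt``, in downstream-to-upstream order:

* a stalled complex is rescued (becomes active, same position) with
  probability ``dt/tau``;
* an active complex on a pause site first stalls with probability ``f*dt``,
  otherwise attempts a +1 step with probability ``epsilon*dt``;
* an active complex elsewhere attempts a +1 step with probability
  ``epsilon*dt``; steps violating exclusion are rejected;
* a complex whose active site passes ``L`` terminates and is removed;
* finally a new complex enters at site 1 with probability ``alpha*dt`` if
  the promoter region ``[1, d]`` is free.

A stalled complex keeps its footprint and blocks the traffic behind it —
this queueing is what couples rare long pauses to large expression losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel
from .core_model import GeneModel, KineticParams

__all__ = ["Trajectory", "run", "preload", "ExclusionError"]


class ExclusionError(ValueError):
    """A configuration violates the hard-core exclusion constraint."""


@dataclass(frozen=True)
class Trajectory:
    """Recorded output of one simulation run.

    ``snapshot_positions``/``snapshot_states`` are only populated when the
    run was recorded with ``record_positions=True``; rows are padded with
    -1 beyond the on-lattice count.  ``passed`` holds cumulative counts of
    complexes (including terminated ones) whose active site passed each
    threshold in ``thresholds``.
    """

    times: np.ndarray
    completed: np.ndarray
    initiated: np.ndarray
    on_lattice: np.ndarray
    thresholds: np.ndarray
    passed: np.ndarray
    snapshot_positions: np.ndarray | None
    snapshot_states: np.ndarray | None
    snapshot_ids: np.ndarray | None
    gene: GeneModel = field(repr=False, default=None)
    params: KineticParams = field(repr=False, default=None)
    seed: int = 0
    #: time at which an early-stop condition fired, -1.0 if it never did
    stop_time: float = -1.0

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def snapshot(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions and states (0=active, 1=stalled) at snapshot ``i``."""
        if self.snapshot_positions is None:
            raise ValueError("trajectory was recorded without positions")
        row = self.snapshot_positions[i]
        keep = row >= 0
        return row[keep], self.snapshot_states[i][keep]

    def occupancy_matrix(self) -> np.ndarray:
        """Dense time x site matrix (0 empty, 1 active, 2 stalled active site)."""
        if self.snapshot_positions is None:
            raise ValueError("trajectory was recorded without positions")
        mat = np.zeros((self.n_snapshots, self.gene.length + 1), dtype=np.int8)
        for i in range(self.n_snapshots):
            p, s = self.snapshot(i)
            mat[i, p] = np.where(s == _kernel.STALLED, 2, 1)
        return mat[:, 1:]

    def to_table(self):
        """Long-form tabular view: time, complex id, position, state."""
        import pandas as pd

        if self.snapshot_positions is None:
            raise ValueError("trajectory was recorded without positions")
        rows = []
        for i in range(self.n_snapshots):
            row = self.snapshot_positions[i]
            keep = row >= 0
            for idn, p, s in zip(
                self.snapshot_ids[i][keep], row[keep], self.snapshot_states[i][keep]
            ):
                rows.append((self.times[i], int(idn), int(p), "stalled" if s else "active"))
        return pd.DataFrame(rows, columns=["time", "complex_id", "position", "state"])


def preload(
    gene: GeneModel,
    positions: Sequence[int],
    states: Sequence[str] | None = None,
    footprint: int = 35,
) -> tuple[np.ndarray, np.ndarray]:
    """Validate and encode a starting configuration for :func:`run`.

    ``positions`` are active-site sites; ``states`` entries are ``"active"``
    or ``"stalled"`` (default all active).  Positions are returned sorted
    downstream-first.
    """
    pos = np.asarray(sorted((int(p) for p in positions), reverse=True), dtype=np.int64)
    if states is None:
        states = ["active"] * len(pos)
    if len(states) != len(pos):
        raise ValueError("positions and states must have equal length")
    order = np.argsort([-int(p) for p in positions], kind="stable")
    st = np.array(
        [_kernel.STALLED if states[i] == "stalled" else _kernel.ACTIVE for i in order],
        dtype=np.uint8,
    )
    for i, s in enumerate(states):
        if s not in ("active", "stalled"):
            raise ValueError(f"unknown state {s!r}")
    if np.any(pos < 1) or np.any(pos > gene.length):
        raise ValueError("preloaded positions must lie within [1, L]")
    if np.any(np.diff(pos) > -footprint):
        raise ExclusionError(
            f"preloaded positions {list(pos)} violate exclusion (spacing < {footprint})"
        )
    pause = set(gene.pause_sites)
    for p, s in zip(pos, st):
        if s == _kernel.STALLED and int(p) not in pause:
            raise ValueError(f"stalled complex at non-pause site {int(p)}")
    return pos, st


def run(
    gene: GeneModel,
    params: KineticParams,
    *,
    duration: float | None = None,
    n_steps: int | None = None,
    seed: int = 0,
    record_interval: float = 0.1,
    thresholds: Sequence[int] | None = None,
    preloaded: tuple[np.ndarray, np.ndarray] | None = None,
    record_positions: bool = False,
    update_order: str = "downstream",
    stop_after_completions: int = 0,
) -> Trajectory:
    """Simulate one trajectory; identical inputs and seed are reproducible.

    Exactly one of ``duration`` (seconds) or ``n_steps`` must be given.
    ``thresholds`` default to the 3' ends of the gene's probe windows.
    ``update_order`` is ``"downstream"`` (default) or ``"random"``
    (sensitivity mode re-drawing the within-step order each step).
    """
    params.check_dt()
    if (duration is None) == (n_steps is None):
        raise ValueError("give exactly one of duration or n_steps")
    if duration is not None:
        if duration <= 0:
            raise ValueError("duration must be > 0")
        n_steps = int(round(duration / params.dt))
    if n_steps <= 0:
        raise ValueError("n_steps must be > 0")
    if update_order not in ("downstream", "random"):
        raise ValueError(f"unknown update_order {update_order!r}")
    if thresholds is None:
        thresholds = [gene.probe_early[1], gene.probe_late[1]]
    thr = np.asarray(sorted(int(t) for t in thresholds), dtype=np.int64)
    if preloaded is None:
        init_pos = np.empty(0, dtype=np.int64)
        init_state = np.empty(0, dtype=np.uint8)
    else:
        init_pos, init_state = preloaded
    record_every = max(1, int(round(record_interval / params.dt)))
    rescue = 1.0 / params.tau if (params.tau > 0) else 0.0

    (times, completed, initiated, on_lattice, passed, snap_pos, snap_state, snap_id, stop_time) = (
        _kernel.simulate(
            gene.length,
            params.footprint,
            gene.pause_mask,
            params.alpha,
            params.epsilon,
            params.f,
            rescue,
            params.dt,
            n_steps,
            int(seed) % 2**31,
            init_pos,
            init_state,
            record_every,
            thr,
            record_positions,
            update_order == "random",
            int(stop_after_completions),
        )
    )
    return Trajectory(
        times=times,
        completed=completed,
        initiated=initiated,
        on_lattice=on_lattice,
        thresholds=thr,
        passed=passed,
        snapshot_positions=snap_pos if record_positions else None,
        snapshot_states=snap_state if record_positions else None,
        snapshot_ids=snap_id if record_positions else None,
        gene=gene,
        params=params,
        seed=seed,
        stop_time=float(stop_time),
    )


def transit_times(
    gene: GeneModel,
    params: KineticParams,
    n_replicates: int,
    seed: int = 0,
    start_position: int = 1,
) -> np.ndarray:
    """Completion times of a single preloaded complex over replicate runs.

    Initiation is switched off (``alpha=0``); replicate ``r`` uses seed
    ``seed + r``.  Used to check the engine against the closed-form mean
    transit time ``(L + n_pause*f*tau)/epsilon``.
    """
    from dataclasses import replace

    p0 = replace(params, alpha=0.0)
    start = preload(gene, [start_position], footprint=params.footprint)
    # generous horizon: 50x the expected transit
    n_pause = sum(1 for s in gene.pause_sites if s >= start_position)
    expect = (gene.length - start_position + 1 + n_pause * params.f * params.tau) / params.epsilon
    horizon = max(expect * 50, 10 * params.dt)
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        traj = run(
            gene,
            p0,
            duration=horizon,
            seed=seed + r,
            record_interval=horizon,
            preloaded=start,
            thresholds=[gene.length],
            stop_after_completions=1,
        )
        if traj.stop_time < 0:
            raise RuntimeError("complex did not complete within 50x expected transit")
        out[r] = traj.stop_time
    return out
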