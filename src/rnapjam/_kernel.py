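"""Numba inner loop of the fixed-timestep kinetic Monte Carlo engine.

The kernel keeps on-lattice complexes in an array sorted by decreasing
position (index 0 = most downstream).  Because overtaking is impossible the
order is preserved; terminated complexes are flagged dead and compacted at
the end of each timestep.  One Mersenne-Twister stream (numba's internal
``np.random`` state, seeded per call) drives the whole run, so identical
inputs and seed give an identical trajectory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# state codes
ACTIVE = 0
STALLED = 1


@njit(cache=True)
def simulate(
    L,
    d,
    pause_mask,      # bool[L+2], index = lattice site
    alpha,
    epsilon,
    f,
    rescue_rate,     # 1/tau (0 if tau infinite / f == 0)
    dt,
    n_steps,
    seed,
    init_pos,        # int64[:], strictly decreasing positions
    init_state,      # uint8[:], ACTIVE/STALLED
    record_every,    # steps between records (>= 1)
    thresholds,      # int64[:], cumulative-passage counters (probe 3' ends)
    record_positions,  # bool: store full snapshots
    random_order,    # bool: random within-step update order (sensitivity mode)
    stop_after,      # stop once this many completions (0 = run all steps)
):
    np.random.seed(seed)
    cap = L // d + 2 + init_pos.size
    pos = np.zeros(cap, np.int64)
    st = np.zeros(cap, np.uint8)
    idn = np.full(cap, -1, np.int64)
    alive = np.zeros(cap, np.bool_)
    count = init_pos.size
    for i in range(count):
        pos[i] = init_pos[i]
        st[i] = init_state[i]
        idn[i] = i
        alive[i] = True
    next_id = count
    initiated = count
    completed = 0

    nthr = thresholds.size
    passed = np.zeros(nthr, np.int64)
    for i in range(count):
        for j in range(nthr):
            if pos[i] > thresholds[j]:
                passed[j] += 1

    p_step = epsilon * dt
    p_stall = f * dt
    p_rescue = rescue_rate * dt
    p_init = alpha * dt

    # +2: initial record plus a possible off-grid final record on early stop
    n_rec = n_steps // record_every + 2
    rec_time = np.empty(n_rec, np.float64)
    rec_completed = np.empty(n_rec, np.int64)
    rec_initiated = np.empty(n_rec, np.int64)
    rec_non = np.empty(n_rec, np.int64)
    rec_passed = np.empty((n_rec, nthr), np.int64)
    if record_positions:
        snap_pos = np.full((n_rec, cap), -1, np.int64)
        snap_state = np.zeros((n_rec, cap), np.uint8)
        snap_id = np.full((n_rec, cap), -1, np.int64)
    else:
        snap_pos = np.full((1, 1), -1, np.int64)
        snap_state = np.zeros((1, 1), np.uint8)
        snap_id = np.full((1, 1), -1, np.int64)

    # record initial state
    rec_time[0] = 0.0
    rec_completed[0] = 0
    rec_initiated[0] = initiated
    rec_non[0] = count
    for j in range(nthr):
        rec_passed[0, j] = passed[j]
    if record_positions:
        for i in range(count):
            snap_pos[0, i] = pos[i]
            snap_state[0, i] = st[i]
            snap_id[0, i] = idn[i]

    order = np.empty(cap, np.int64)
    r = 0
    stop_time = -1.0
    for step in range(1, n_steps + 1):
        n = count
        if random_order:
            perm = np.random.permutation(n)
            for k in range(n):
                order[k] = perm[k]
        else:
            for k in range(n):
                order[k] = k  # downstream (front) first

        for k in range(n):
            i = order[k]
            if not alive[i]:
                continue
            if st[i] == STALLED:
                if np.random.random() < p_rescue:
                    st[i] = ACTIVE
                continue
            p = pos[i]
            if pause_mask[p] and np.random.random() < p_stall:
                st[i] = STALLED
                continue
            if np.random.random() < p_step:
                newp = p + 1
                # nearest live downstream neighbour
                m = i - 1
                while m >= 0 and not alive[m]:
                    m -= 1
                if m >= 0 and newp > pos[m] - d:
                    continue  # excluded
                for j in range(nthr):
                    if newp == thresholds[j] + 1:
                        passed[j] += 1
                if newp > L:
                    completed += 1
                    alive[i] = False
                else:
                    pos[i] = newp

        # compact dead entries, preserving order
        w = 0
        for i in range(count):
            if alive[i]:
                if w != i:
                    pos[w] = pos[i]
                    st[w] = st[i]
                    idn[w] = idn[i]
                alive[w] = True
                w += 1
        for i in range(w, count):
            alive[i] = False
        count = w

        # initiation attempt, last within the timestep
        if count == 0 or pos[count - 1] > d:
            if np.random.random() < p_init:
                pos[count] = 1
                st[count] = ACTIVE
                idn[count] = next_id
                alive[count] = True
                next_id += 1
                count += 1
                initiated += 1

        if step % record_every == 0:
            r += 1
            rec_time[r] = step * dt
            rec_completed[r] = completed
            rec_initiated[r] = initiated
            rec_non[r] = count
            for j in range(nthr):
                rec_passed[r, j] = passed[j]
            if record_positions:
                for i in range(count):
                    snap_pos[r, i] = pos[i]
                    snap_state[r, i] = st[i]
                    snap_id[r, i] = idn[i]

        if stop_after > 0 and completed >= stop_after:
            stop_time = step * dt
            if step % record_every != 0:
                r += 1
                rec_time[r] = stop_time
                rec_completed[r] = completed
                rec_initiated[r] = initiated
                rec_non[r] = count
                for j in range(nthr):
                    rec_passed[r, j] = passed[j]
                if record_positions:
                    for i in range(count):
                        snap_pos[r, i] = pos[i]
                        snap_state[r, i] = st[i]
                        snap_id[r, i] = idn[i]
            break

    return (
        rec_time[: r + 1],
        rec_completed[: r + 1],
        rec_initiated[: r + 1],
        rec_non[: r + 1],
        rec_passed[: r + 1],
        snap_pos[: r + 1] if record_positions else snap_pos,
        snap_state[: r + 1] if record_positions else snap_state,
        snap_id[: r + 1] if record_positions else snap_id,
        stop_time,
    )
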