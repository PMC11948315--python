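"""Independent hand simulation of the switching-control loop.

This walks a scripted loss table directly — plain dicts and lists, no
controller code — implementing the procedure as written: probe and rank
all candidates from a common state (ties broken by candidate order), train
under patience with reset-on-non-increase counting, roll back to the best
state on trigger, re-rank the survivors, prune the worst above the floor.
Used as the golden-trace oracle for ``run_afcs``.
"""

from __future__ import annotations

import math
from copy import deepcopy


def _cell(columns, af, k, hold_last):
    col = columns[af]
    if k < len(col):
        return float(col[k])
    if hold_last:
        return float(col[-1])
    raise KeyError(f"column {af!r} exhausted at position {k}")


def _probe_rank(columns, candidates, positions, probe_epochs, hold_last):
    losses = {}
    for af in candidates:
        pos = dict(positions)
        loss = math.nan
        for _ in range(probe_epochs):
            loss = _cell(columns, af, pos[af], hold_last)
            pos[af] += 1
        losses[af] = loss
    finite = [c for c in candidates if math.isfinite(losses[c])]
    flagged = [c for c in candidates if not math.isfinite(losses[c])]
    order = sorted(finite, key=lambda c: losses[c]) + flagged
    return order, losses


def hand_simulate(
    columns,
    p0,
    p1,
    loop,
    min_count,
    probe_epochs=1,
    hold_last=True,
    patience_mode="consecutive_increases",
    epoch_cap=10_000,
):
    """Return (schedule records, per-epoch (epoch, af, loss) trace)."""
    order_of = list(columns)
    positions = {af: 0 for af in order_of}
    epoch = 0
    remaining = list(order_of)

    rank, _ = _probe_rank(columns, remaining, positions, probe_epochs, hold_last)
    active = rank[0]
    schedule = [(1, 1, active)]
    if rank[-1] != active:
        remaining.remove(rank[-1])  # initial removal is unconditional

    best = {"positions": dict(positions), "epoch": epoch, "active": active}
    best_loss = math.inf
    prev = None
    count = 0
    trace = []
    work = 0

    for cycle in range(1, loop + 1):
        p = p0 if cycle == 1 else p1
        while True:
            if work >= epoch_cap:
                return schedule, trace
            loss = _cell(columns, active, positions[active], hold_last)
            positions[active] += 1
            epoch += 1
            work += 1
            trace.append((epoch, active, loss))
            if patience_mode == "consecutive_increases":
                degraded = prev is not None and loss > prev
            else:
                degraded = not loss < best_loss
            count = count + 1 if degraded else 0
            prev = loss
            if loss < best_loss:
                best_loss = loss
                best = {
                    "positions": dict(positions),
                    "epoch": epoch,
                    "active": active,
                }
            if count >= p:
                break
        if cycle == loop:
            break
        # roll back to the best state, re-rank survivors from it
        positions = dict(best["positions"])
        epoch = best["epoch"]
        rank, _ = _probe_rank(columns, remaining, positions, probe_epochs, hold_last)
        active = rank[0]
        schedule.append((cycle + 1, max(1, epoch), active))
        if rank[-1] != active and len(remaining) > min_count:
            remaining.remove(rank[-1])
        count = 0
        prev = best_loss if math.isfinite(best_loss) else None
    return schedule, trace
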