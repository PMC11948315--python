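"""Cyclic activation-switching training controller.

Training proceeds in ``afcs_loop`` segments.  Before the first segment
every candidate activation is probed from a common checkpoint and ranked
by validation loss: the best candidate becomes the active activation, the
worst is dropped from the candidate list.  The segment then trains under a
patience rule — ``p0`` tolerated validation-loss degradations for the
first segment, ``p1`` for the rest.  When patience triggers, the weights
roll back to the best-validation-loss checkpoint, the surviving candidates
are re-probed from it, the new best is activated (the new worst is dropped
unless the list has shrunk to ``min_af_count``), and training continues.
The run ends at the last segment's trigger, with the best checkpoint
restored, and reports the ordered switch schedule (step, epoch,
activation), the full loss trace, and per-segment cost accounting.

Any model can be driven by the controller by implementing
:class:`TrainerPort`: epoch-granular training, metric evaluation, exact
snapshot/restore, and weight-preserving activation swap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Protocol, Sequence, runtime_checkable

import pandas as pd

from .activations import DEFAULT_LIST_AF

__all__ = [
    "AFCSConfig",
    "TrainerPort",
    "ControllerState",
    "SwitchRecord",
    "SwitchSchedule",
    "TraceRow",
    "SegmentSummary",
    "AFCSResult",
    "Ranking",
    "RankingError",
    "rank_activations",
    "patience_step",
    "prune_worst",
    "run_afcs",
]


class RankingError(RuntimeError):
    """Every probe produced a non-finite validation loss."""


@runtime_checkable
class TrainerPort(Protocol):
    """Contract a trainable model must satisfy to be controller-driven.

    ``restore(snapshot())`` must be an exact round-trip (weights, optimizer
    state, data-order RNG and epoch counter), so that deterministic
    evaluation after a restore is bit-identical.  ``set_activation`` must
    preserve every learnable parameter.
    """

    def train_one_epoch(self) -> float: ...

    def evaluate(self, split: str): ...

    def snapshot(self) -> Any: ...

    def restore(self, token: Any) -> None: ...

    def set_activation(self, name: str) -> None: ...

    @property
    def current_epoch(self) -> int: ...


@dataclass(frozen=True)
class AFCSConfig:
    """The controller's hyperparameters.

    list_af
        Ordered candidate activations (>= 3 distinct names); order breaks
        probe-loss ties.
    p0, p1
        Patience of the first segment and of every later segment, in
        epochs.  Values below 2 are accepted with a warning (the cost
        model's own worked examples use p1 = 1).
    afcs_loop
        Number of training segments (>= 2).
    min_af_count
        Floor on the candidate list size; pruning stops there.
    probe_epochs
        Training epochs per candidate when ranking (1 keeps probes cheap
        and matches ranking by first-epoch loss).
    patience_mode
        ``"consecutive_increases"`` counts strict epoch-over-epoch loss
        increases, resetting on any non-increase; ``"no_best_improvement"``
        counts epochs without a new best loss, as classic early stopping.
    rollback_mode
        ``"best"`` resumes each segment from the best-loss checkpoint,
        ``"last"`` from the current weights.
    """

    list_af: tuple[str, ...] = tuple(DEFAULT_LIST_AF)
    p0: int = 3
    p1: int = 2
    afcs_loop: int = 5
    min_af_count: int = 3
    probe_epochs: int = 1
    patience_mode: str = "consecutive_increases"
    rollback_mode: str = "best"
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "list_af", tuple(self.list_af))
        if len(set(self.list_af)) != len(self.list_af):
            raise ValueError("list_af contains duplicate names")
        if len(self.list_af) < 3:
            raise ValueError("list_af needs at least 3 distinct activations")
        if self.p0 < 1 or self.p1 < 1:
            raise ValueError("patience values must be >= 1")
        if self.p0 < 2 or self.p1 < 2:
            warnings.warn(
                "patience below 2 switches on a single degradation",
                stacklevel=3,
            )
        if self.afcs_loop < 2:
            raise ValueError("afcs_loop must be >= 2")
        if self.min_af_count < 2:
            raise ValueError("min_af_count must be >= 2")
        if self.min_af_count > len(self.list_af) - 1:
            raise ValueError("min_af_count must be <= len(list_af) - 1")
        if self.patience_mode not in ("consecutive_increases", "no_best_improvement"):
            raise ValueError(f"unknown patience_mode {self.patience_mode!r}")
        if self.rollback_mode not in ("best", "last"):
            raise ValueError(f"unknown rollback_mode {self.rollback_mode!r}")

    def as_dict(self) -> dict:
        return {
            "list_AF": list(self.list_af),
            "p0": self.p0,
            "p1": self.p1,
            "AFCS_loop": self.afcs_loop,
            "min_AF_count": self.min_af_count,
            "probe_epochs": self.probe_epochs,
            "patience_mode": self.patience_mode,
            "rollback_mode": self.rollback_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "AFCSConfig":
        alias = {
            "list_AF": "list_af",
            "AFCS_loop": "afcs_loop",
            "min_AF_count": "min_af_count",
        }
        known = {
            "list_af", "p0", "p1", "afcs_loop", "min_af_count",
            "probe_epochs", "patience_mode", "rollback_mode", "seed",
        }
        kwargs = {}
        for key, value in raw.items():
            key = alias.get(key, key)
            if key in known:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class ControllerState:
    """Mutable bookkeeping of a controller run."""

    active_af: str
    remaining_afs: list[str]
    cycle_index: int = 1
    consecutive_increase_count: int = 0
    previous_loss: float | None = None
    best_loss: float = math.inf
    best_checkpoint: Any = None
    best_epoch: int = 0
    epoch: int = 0


@dataclass(frozen=True)
class SwitchRecord:
    step: int
    epoch: int
    af: str


@dataclass(frozen=True)
class SwitchSchedule:
    """Ordered (step, epoch, activation) switch record of a run."""

    records: tuple[SwitchRecord, ...]
    complete: bool = True

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def validate(self, afcs_loop: int | None = None) -> None:
        steps = [r.step for r in self.records]
        epochs = [r.epoch for r in self.records]
        if steps != list(range(1, len(steps) + 1)):
            raise ValueError(f"steps must be 1..n strictly increasing, got {steps}")
        if any(b < a for a, b in zip(epochs, epochs[1:])):
            raise ValueError(f"epochs must be non-decreasing, got {epochs}")
        if self.complete:
            if afcs_loop is not None and len(self.records) != afcs_loop:
                raise ValueError(
                    f"completed run must have {afcs_loop} records, got {len(self.records)}"
                )
            if self.records and self.records[0].epoch != 1:
                raise ValueError("first switch record must be at epoch 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.step, r.epoch, r.af) for r in self.records],
            columns=["step", "epoch", "af"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, complete: bool = True) -> "SwitchSchedule":
        records = tuple(
            SwitchRecord(int(r.step), int(r.epoch), str(r.af))
            for r in frame.itertuples()
        )
        return cls(records, complete=complete)

    @classmethod
    def from_csv(cls, path, complete: bool = True) -> "SwitchSchedule":
        return cls.from_frame(pd.read_csv(path), complete=complete)


@dataclass(frozen=True)
class TraceRow:
    epoch: int
    af: str
    val_loss: float
    train_loss: float = math.nan
    val_accuracy: float = math.nan


@dataclass(frozen=True)
class SegmentSummary:
    """Cost accounting for one training segment."""

    cycle: int
    af: str
    epochs_trained: int
    post_best_epochs: int
    triggered: bool


@dataclass(frozen=True)
class Ranking:
    """Probe outcome: candidate order (best first), losses, non-finite flags."""

    order: tuple[str, ...]
    losses: dict[str, float]
    flagged: tuple[str, ...] = ()

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def worst(self) -> str:
        return self.order[-1]


@dataclass(frozen=True)
class AFCSResult:
    """Everything a completed (or truncated) controller run produced."""

    schedule: SwitchSchedule
    trace: tuple[TraceRow, ...]
    segments: tuple[SegmentSummary, ...]
    final_state: ControllerState
    config: AFCSConfig
    truncated: bool = False
    events: tuple[str, ...] = ()

    @property
    def post_best_epochs(self) -> int:
        return sum(s.post_best_epochs for s in self.segments)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.epoch, r.af, r.train_loss, r.val_loss, r.val_accuracy)
                for r in self.trace
            ],
            columns=["epoch", "af", "train_loss", "val_loss", "val_accuracy"],
        )


def rank_activations(
    trainer: TrainerPort,
    candidates: Sequence[str],
    probe_epochs: int = 1,
    seed: int | None = None,
) -> Ranking:
    """Probe every candidate from a common checkpoint and rank by loss.

    Each candidate is activated on a restored copy of the reference state
    and trained for ``probe_epochs`` epochs; candidates are ordered by
    their final probe validation loss, ascending, ties broken by candidate
    order.  Non-finite probes rank last and are flagged.  The reference
    state is restored before returning.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    if probe_epochs < 1:
        raise ValueError("probe_epochs must be >= 1")
    if seed is not None and hasattr(trainer, "reseed"):
        trainer.reseed(seed)
    reference = trainer.snapshot()
    losses: dict[str, float] = {}
    for name in candidates:
        trainer.restore(reference)
        trainer.set_activation(name)
        loss = math.nan
        for _ in range(probe_epochs):
            loss = trainer.train_one_epoch()
        losses[name] = float(loss)
    trainer.restore(reference)
    finite = [c for c in candidates if math.isfinite(losses[c])]
    flagged = tuple(c for c in candidates if not math.isfinite(losses[c]))
    if not finite:
        raise RankingError("all candidate probes produced non-finite losses")
    order = tuple(sorted(finite, key=lambda c: losses[c])) + flagged
    return Ranking(order=order, losses=losses, flagged=flagged)


def patience_step(
    state: ControllerState,
    val_loss: float,
    p: int,
    checkpoint: Any = None,
    mode: str = "consecutive_increases",
) -> bool:
    """Feed one epoch's validation loss to the patience counter.

    Returns ``True`` exactly when the tolerated-degradation count reaches
    ``p``.  A NaN loss counts as a degradation and can never become the
    best.  When ``checkpoint`` is given and the loss improves the best,
    the checkpoint is stored as the rollback target.
    """
    if p < 1:
        raise ValueError("patience must be >= 1")
    is_nan = isinstance(val_loss, float) and math.isnan(val_loss)
    if mode == "consecutive_increases":
        prev = state.previous_loss
        degraded = is_nan or (
            prev is not None and not math.isnan(prev) and val_loss > prev
        )
    elif mode == "no_best_improvement":
        degraded = is_nan or not val_loss < state.best_loss
    else:
        raise ValueError(f"unknown patience mode {mode!r}")
    state.consecutive_increase_count = (
        state.consecutive_increase_count + 1 if degraded else 0
    )
    state.previous_loss = val_loss
    if not is_nan and val_loss < state.best_loss:
        state.best_loss = val_loss
        state.best_epoch = state.epoch
        if checkpoint is not None:
            state.best_checkpoint = checkpoint
    return state.consecutive_increase_count >= p


def prune_worst(
    remaining: Sequence[str],
    worst: str,
    min_af_count: int,
    phase: str = "loop",
) -> list[str]:
    """Drop the worst candidate, preserving the order of survivors.

    In the initial phase the removal is unconditional; in the loop phase
    it happens only while the list is above ``min_af_count``.
    """
    remaining = list(remaining)
    if worst not in remaining:
        raise ValueError(f"worst activation {worst!r} not among {remaining}")
    if phase not in ("initial", "loop"):
        raise ValueError(f"phase must be 'initial' or 'loop', got {phase!r}")
    if phase == "loop" and len(remaining) <= min_af_count:
        return remaining
    remaining.remove(worst)
    return remaining


def run_afcs(
    trainer: TrainerPort,
    config: AFCSConfig,
    epoch_cap: int = 200,
) -> AFCSResult:
    """Execute the full switching-controller loop.

    ``epoch_cap`` bounds the total number of segment training epochs (the
    probes are not counted); hitting it returns a truncated result.  On
    return the trainer holds the best checkpoint seen (when rolling back
    to best), so a subsequent ``trainer.evaluate("test")`` scores the
    delivered model.
    """
    if epoch_cap < 1:
        raise ValueError("epoch_cap must be >= 1")
    events: list[str] = []

    def log(msg: str) -> None:
        events.append(msg)

    ranking = rank_activations(
        trainer, list(config.list_af), config.probe_epochs, seed=config.seed
    )
    log(f"probe step=1 losses={ranking.losses}")
    active = ranking.best
    trainer.set_activation(active)
    remaining = list(config.list_af)
    if ranking.worst != active:
        remaining = prune_worst(remaining, ranking.worst, config.min_af_count, "initial")
        log(f"prune step=1 removed={ranking.worst} remaining={remaining}")
    state = ControllerState(
        active_af=active,
        remaining_afs=remaining,
        best_checkpoint=trainer.snapshot(),
        best_epoch=trainer.current_epoch,
        epoch=trainer.current_epoch,
    )
    records = [SwitchRecord(1, 1, active)]
    log(f"switch step=1 epoch=1 af={active}")

    trace: list[TraceRow] = []
    segments: list[SegmentSummary] = []
    work = 0
    truncated = False

    for cycle in range(1, config.afcs_loop + 1):
        state.cycle_index = cycle
        p = config.p0 if cycle == 1 else config.p1
        seg_epoch_start = trainer.current_epoch
        seg_best_start = state.best_epoch
        triggered = False
        while True:
            if work >= epoch_cap:
                truncated = True
                break
            loss = trainer.train_one_epoch()
            work += 1
            state.epoch = trainer.current_epoch
            extras = getattr(trainer, "last_epoch_metrics", {}) or {}
            trace.append(
                TraceRow(
                    epoch=state.epoch,
                    af=state.active_af,
                    val_loss=float(loss),
                    train_loss=float(extras.get("train_loss", math.nan)),
                    val_accuracy=float(extras.get("val_accuracy", math.nan)),
                )
            )
            if isinstance(loss, float) and math.isnan(loss):
                log(f"nan-loss epoch={state.epoch} af={state.active_af}")
            triggered = patience_step(
                state, float(loss), p, checkpoint=trainer.snapshot(),
                mode=config.patience_mode,
            )
            if triggered:
                log(f"trigger cycle={cycle} epoch={state.epoch} patience={p}")
                break
        epochs_trained = trainer.current_epoch - seg_epoch_start
        best_advance = max(0, state.best_epoch - seg_epoch_start)
        segments.append(
            SegmentSummary(
                cycle=cycle,
                af=state.active_af,
                epochs_trained=epochs_trained,
                post_best_epochs=epochs_trained - best_advance,
                triggered=triggered,
            )
        )
        if truncated or cycle == config.afcs_loop:
            break
        # -- switch: roll back, re-rank survivors, activate the new best --
        if config.rollback_mode == "best" and state.best_checkpoint is not None:
            trainer.restore(state.best_checkpoint)
            log(f"rollback cycle={cycle} to epoch={trainer.current_epoch}")
        ranking = rank_activations(
            trainer, state.remaining_afs, config.probe_epochs, seed=config.seed
        )
        log(f"probe step={cycle + 1} losses={ranking.losses}")
        active = ranking.best
        trainer.set_activation(active)
        state.active_af = active
        switch_epoch = max(1, trainer.current_epoch)
        records.append(SwitchRecord(cycle + 1, switch_epoch, active))
        log(f"switch step={cycle + 1} epoch={switch_epoch} af={active}")
        if ranking.worst != active:
            pruned = prune_worst(
                state.remaining_afs, ranking.worst, config.min_af_count, "loop"
            )
            if len(pruned) != len(state.remaining_afs):
                log(f"prune step={cycle + 1} removed={ranking.worst} remaining={pruned}")
            state.remaining_afs = pruned
        state.consecutive_increase_count = 0
        state.previous_loss = (
            state.best_loss if math.isfinite(state.best_loss) else None
        )
        state.epoch = trainer.current_epoch

    if config.rollback_mode == "best" and state.best_checkpoint is not None:
        trainer.restore(state.best_checkpoint)
        log(f"final restore to epoch={trainer.current_epoch}")
    schedule = SwitchSchedule(tuple(records), complete=not truncated)
    if not truncated:
        schedule.validate(config.afcs_loop)
    return AFCSResult(
        schedule=schedule,
        trace=tuple(trace),
        segments=tuple(segments),
        final_state=state,
        config=config,
        truncated=truncated,
        events=tuple(events),
    )
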