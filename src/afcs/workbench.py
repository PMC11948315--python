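"""Experiment orchestration: fixed-activation baselines vs the switching
controller, with reproducible on-disk result bundles.

A :class:`ExperimentPlan` names a dataset (a synthetic blob recipe or an
image directory), a training mode — one fixed activation, or the switching
controller with an :class:`~afcs.controller.AFCSConfig` — a split, and a
seed.  :func:`run_experiment` executes preprocessing, training and held-out
evaluation, and writes the metric report, per-epoch loss trace, switch
schedule (controller mode), confusion matrix and run log to the output
directory, each stamped with the plan's config hash and seed so a bundle
can be reproduced bit-for-bit.  :func:`compare_runs` assembles bundles into
a result table, one row per run, flagging the best accuracy.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .controller import AFCSConfig, SwitchSchedule, run_afcs
from .evaluation import MetricsReport, confusion_matrix
from .preprocess import SplitSpec
from .synthetic import BlobDataset, SyntheticDatasetSpec, make_blob_dataset, make_tiny_cnn

__all__ = ["ExperimentPlan", "RunBundle", "run_experiment", "compare_runs"]


@dataclass(frozen=True)
class ExperimentPlan:
    """One training run: dataset + mode (fixed AF or controller) + seed."""

    dataset: SyntheticDatasetSpec
    mode: str  # "fixed" | "afcs"
    fixed_af: str | None = None
    afcs: AFCSConfig | None = None
    split: tuple[float, ...] = (0.7, 0.15, 0.15)
    seed: int = 0
    max_epochs: int = 30
    patience: int = 10  # fixed-mode early stopping
    epoch_cap: int = 200  # controller safety bound

    def __post_init__(self):
        if self.mode not in ("fixed", "afcs"):
            raise ValueError(f"mode must be 'fixed' or 'afcs', got {self.mode!r}")
        if self.mode == "fixed" and not self.fixed_af:
            raise ValueError("fixed mode needs fixed_af")
        if self.mode == "afcs" and self.afcs is None:
            raise ValueError("afcs mode needs an AFCSConfig")

    def label(self) -> str:
        return self.fixed_af if self.mode == "fixed" else "AFCS"

    def as_dict(self) -> dict:
        d = {
            "dataset": self.dataset.__dict__ | {},
            "mode": self.mode,
            "fixed_af": self.fixed_af,
            "afcs": self.afcs.as_dict() if self.afcs else None,
            "split": list(self.split),
            "seed": self.seed,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "epoch_cap": self.epoch_cap,
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class RunBundle:
    """In-memory result of one experiment run."""

    plan: ExperimentPlan
    metrics: MetricsReport
    trace: pd.DataFrame
    confusion: np.ndarray
    schedule: SwitchSchedule | None = None
    events: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        return self.plan.label()


def _train_fixed(trainer, max_epochs: int, patience: int):
    """Plain early-stopped training with best-checkpoint restore."""
    best_loss = math.inf
    best_token = trainer.snapshot()
    wait = 0
    rows = []
    for _ in range(max_epochs):
        loss = trainer.train_one_epoch()
        extras = trainer.last_epoch_metrics
        rows.append(
            (
                trainer.current_epoch,
                trainer.active_activation,
                extras.get("train_loss", math.nan),
                loss,
                extras.get("val_accuracy", math.nan),
            )
        )
        if loss < best_loss:
            best_loss = loss
            best_token = trainer.snapshot()
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    trainer.restore(best_token)
    return pd.DataFrame(
        rows, columns=["epoch", "af", "train_loss", "val_loss", "val_accuracy"]
    )


def run_experiment(plan: ExperimentPlan, out_dir: str | Path | None = None) -> RunBundle:
    """Execute a plan end to end and (optionally) write its bundle."""
    dataset = make_blob_dataset(plan.dataset)
    trainer = make_tiny_cnn(
        n_classes=plan.dataset.n_classes,
        seed=plan.seed,
        dataset=dataset,
        fractions=plan.split,
    )
    schedule = None
    events: tuple[str, ...] = ()
    if plan.mode == "fixed":
        trainer.set_activation(plan.fixed_af)
        trace = _train_fixed(trainer, plan.max_epochs, plan.patience)
    else:
        result = run_afcs(trainer, plan.afcs, epoch_cap=plan.epoch_cap)
        schedule = result.schedule
        events = result.events
        trace = result.trace_frame()
    metrics = trainer.evaluate("test")
    x_test, y_test = trainer._data["test"]
    probs = trainer.predict_proba(x_test * 255.0)
    cm = confusion_matrix(y_test, probs.argmax(axis=1), plan.dataset.n_classes)
    bundle = RunBundle(
        plan=plan,
        metrics=metrics,
        trace=trace,
        confusion=cm,
        schedule=schedule,
        events=events,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: RunBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": bundle.plan.config_hash(), "seed": bundle.plan.seed}
    meta = {
        "plan": bundle.plan.as_dict(),
        **stamp,
        "metrics": bundle.metrics.as_dict(),
    }
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    trace = bundle.trace.copy()
    for key, value in stamp.items():
        trace[key] = value
    trace.to_csv(out_dir / "trace.csv", index=False)
    pd.DataFrame(bundle.confusion).to_csv(out_dir / "confusion.csv", index=False)
    if bundle.schedule is not None:
        sched = bundle.schedule.to_frame()
        for key, value in stamp.items():
            sched[key] = value
        sched.to_csv(out_dir / "schedule.csv", index=False)
    if bundle.events:
        (out_dir / "run.log").write_text(
            "\n".join(f"INFO {line}" for line in bundle.events) + "\n"
        )


def compare_runs(bundles: list[RunBundle]) -> pd.DataFrame:
    """One row per run bundle, best accuracy flagged.

    All bundles must come from the same dataset recipe and split, so the
    comparison is apples to apples.
    """
    if len(bundles) < 2:
        raise ValueError("need at least two bundles to compare")
    first = bundles[0].plan
    for b in bundles[1:]:
        if b.plan.dataset != first.dataset or b.plan.split != first.split:
            raise ValueError("bundles come from different datasets or splits")
    rows = [
        {
            "mode": b.label,
            "accuracy": b.metrics.accuracy,
            "loss": b.metrics.loss,
            "precision": b.metrics.precision,
            "recall": b.metrics.recall,
            "f1": b.metrics.f1,
        }
        for b in bundles
    ]
    frame = pd.DataFrame(rows)
    frame["best"] = frame["accuracy"] == frame["accuracy"].max()
    return frame
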