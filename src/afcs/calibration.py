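"""Patience calibration from validation-loss traces.

The controller's patience values (how many consecutive validation-loss
degradations to tolerate before switching activation) are not guessed:
they are calibrated from reference trainings.  For every (model, repeat,
activation) trace the *consecutive degradation number* is measured — the
longest run of consecutive epochs that fail to improve the best-so-far
validation loss, i.e. the maximum value an early-stopping wait counter
reaches on that trace.  Per-repeat means of these counts (rounded to two
decimals) are averaged into an overall mean, and the patience is that mean
rounded half-up to an integer, plus one: tolerate the typical number of
degradations and act on the next.

Applied to the bundled reference traces this yields an overall mean of
2.39 for DenseNet121 from-scratch segments (patience p0 = 3) and 1.38 for
continued segments (p1 = 2).

A second statistic, :func:`count_loss_increases` — the total number of
strict epoch-over-epoch increases in a trace — is provided for trace
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import calibration_data

__all__ = [
    "LossTrace",
    "count_loss_increases",
    "longest_degradation_run",
    "counts_from_traces",
    "summarize_counts",
    "derive_patience",
    "CalibrationSummary",
    "reference_first_segment",
    "reference_next_segment",
]

#: keys are experiment identifiers with the activation name last; values are
#: non-negative degradation counts.  Blank table cells are simply absent.
CountsTable = Mapping[tuple, int]


@dataclass(frozen=True)
class LossTrace:
    """Per-epoch validation losses (epoch 1 first) with an optional label."""

    losses: tuple[float, ...]
    label: tuple = ()

    def __post_init__(self):
        if len(self.losses) < 1:
            raise ValueError("a loss trace needs at least one entry")
        if not np.all(np.isfinite(self.losses)):
            raise ValueError(f"non-finite loss in trace {self.label!r}")


def _as_losses(trace) -> np.ndarray:
    losses = np.asarray(
        trace.losses if isinstance(trace, LossTrace) else trace, dtype=float
    )
    if losses.ndim != 1 or losses.size < 1:
        raise ValueError("a loss trace must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(losses)):
        raise ValueError("non-finite loss entry in trace")
    return losses


def count_loss_increases(trace) -> int:
    """Total number of strict epoch-over-epoch increases in the trace.

    A length-1 trace has no increases.  Invariant under adding a constant
    to, or positively scaling, every entry.
    """
    losses = _as_losses(trace)
    return int(np.sum(losses[1:] > losses[:-1]))


def longest_degradation_run(trace) -> int:
    """Longest run of consecutive epochs without a new best loss.

    This is the calibration statistic: a wait counter increments on every
    epoch whose loss exceeds the best seen so far and resets whenever the
    best improves; the statistic is the counter's maximum.  It equals the
    smallest early-stopping patience that the trace would have survived.
    """
    losses = _as_losses(trace)
    best = losses[0]
    run = longest = 0
    for x in losses[1:]:
        if x > best:
            run += 1
            longest = max(longest, run)
        else:
            best = min(best, x)
            run = 0
    return longest


_STATISTICS = {
    "longest_run": longest_degradation_run,
    "total_increases": count_loss_increases,
}


def counts_from_traces(
    traces: Mapping[tuple, Sequence[float]], statistic: str = "longest_run"
) -> dict[tuple, int]:
    """Apply a degradation statistic to every trace of a table."""
    try:
        fn = _STATISTICS[statistic]
    except KeyError:
        raise ValueError(
            f"statistic must be one of {sorted(_STATISTICS)}, got {statistic!r}"
        ) from None
    return {key: fn(trace) for key, trace in traces.items()}


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class CalibrationSummary:
    """Per-experiment mean degradation counts and their overall mean.

    Per-experiment means are rounded to two decimals before the overall
    mean is taken (itself rounded to two decimals), matching how the
    reference tables report them.
    """

    per_experiment: dict[tuple, float]
    overall: float

    @property
    def patience(self) -> int:
        return derive_patience(self.overall)


def summarize_counts(table: CountsTable) -> CalibrationSummary:
    """Group counts by experiment (all key fields but the final activation
    name), average each group, then average the rounded group means."""
    if not table:
        raise ValueError("empty counts table")
    groups: dict[tuple, list[int]] = {}
    for key, count in table.items():
        if count < 0:
            raise ValueError(f"negative count at {key!r}")
        groups.setdefault(tuple(key[:-1]), []).append(int(count))
    per_experiment = {
        row: _round_half_up(float(np.mean(cells)), 2) for row, cells in groups.items()
    }
    overall = _round_half_up(float(np.mean(list(per_experiment.values()))), 2)
    return CalibrationSummary(per_experiment=per_experiment, overall=overall)


def derive_patience(overall_mean: float) -> int:
    """Patience = round-half-up(mean degradation count) + 1.

    Tolerate the typical number of consecutive degradations and stop (or
    switch) on the next one.  Non-decreasing in its argument.
    """
    if not np.isfinite(overall_mean) or overall_mean < 0:
        raise ValueError(f"overall mean must be finite and >= 0, got {overall_mean}")
    return int(_round_half_up(overall_mean)) + 1


# -- bundled reference data ------------------------------------------------


def reference_first_segment(model: str = "DenseNet121"):
    """(traces, published counts) for from-scratch fixed-activation segments.

    Count keys are (model, repeat, activation); Tanh traces exist but have
    no counts (Tanh was dropped from the candidate list for not learning).
    """
    traces = {
        k: v for k, v in calibration_data.FIRST_SEGMENT_TRACES.items() if k[0] == model
    }
    counts = {
        k: v for k, v in calibration_data.FIRST_SEGMENT_COUNTS.items() if k[0] == model
    }
    if not traces:
        raise ValueError(f"no bundled traces for model {model!r}")
    return traces, counts


def reference_next_segment(model: str = "DenseNet121"):
    """(traces, published counts) for continued segments, keyed by
    (model, repeat, previous best activation, next activation)."""
    traces = {
        k: v for k, v in calibration_data.NEXT_SEGMENT_TRACES.items() if k[0] == model
    }
    counts = {
        k: v for k, v in calibration_data.NEXT_SEGMENT_COUNTS.items() if k[0] == model
    }
    if not traces:
        raise ValueError(f"no bundled traces for model {model!r}")
    return traces, counts
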