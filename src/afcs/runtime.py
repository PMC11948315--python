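"""Epoch-cost model for activation-switching training.

A run of the switching controller consists of ``AFCS_loop`` training
segments: the first ends after ``p0`` tolerated validation-loss
degradations, each of the remaining ``AFCS_loop - 1`` after ``p1``.  The
extra training charged on top of the underlying network's own runtime is
therefore ``p0 + (AFCS_loop - 1) * p1`` epochs, and the total runtime is

    runtime = Rt_cnn + Rt_ep * (p0 + sum_{i=2..AFCS_loop} p1)

where ``Rt_cnn`` is the base runtime of the network and ``Rt_ep`` the cost
of one epoch.  Probe epochs used to rank candidates are not part of this
model and are reported separately by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RuntimeEstimate", "extra_epochs", "total_runtime"]


def extra_epochs(p0: int, p1: int, afcs_loop: int) -> int:
    """Patience epochs charged beyond the per-segment best epochs.

    Equals ``p0 + (afcs_loop - 1) * p1``; with uniform patience ``p`` this
    is ``afcs_loop * p``.
    """
    if p0 < 1 or p1 < 1:
        raise ValueError(f"patience values must be >= 1, got p0={p0}, p1={p1}")
    if afcs_loop < 2:
        raise ValueError(f"afcs_loop must be >= 2, got {afcs_loop}")
    return p0 + (afcs_loop - 1) * p1


def total_runtime(
    rt_cnn: float, rt_ep: float, p0: int, p1: int, afcs_loop: int
) -> float:
    """Total runtime: base model runtime plus the patience-epoch surcharge."""
    if rt_cnn < 0 or rt_ep < 0:
        raise ValueError("runtimes must be non-negative")
    return rt_cnn + rt_ep * extra_epochs(p0, p1, afcs_loop)


@dataclass(frozen=True)
class RuntimeEstimate:
    """Decomposed runtime of a switching-controller run."""

    rt_cnn: float
    rt_ep: float
    extra_epochs: int

    def __post_init__(self):
        if self.rt_cnn < 0 or self.rt_ep < 0 or self.extra_epochs < 0:
            raise ValueError("all runtime components must be non-negative")

    @property
    def total(self) -> float:
        return self.rt_cnn + self.rt_ep * self.extra_epochs

    @classmethod
    def from_config(
        cls, rt_cnn: float, rt_ep: float, p0: int, p1: int, afcs_loop: int
    ) -> "RuntimeEstimate":
        return cls(rt_cnn, rt_ep, extra_epochs(p0, p1, afcs_loop))
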