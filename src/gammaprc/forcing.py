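"""External forcing: single pulses and periodic ("clock") pulse trains.

Three pulse kinds are supported:

* ``square_current`` — a square current pulse of given amplitude (pA) and
  duration delivered to every neuron of the target population through its
  external conductance ``g_ext``; for QIF populations the amplitude is a
  net voltage deflection ``dV`` delivered as a square current of height
  ``dV * tau / duration``.
* ``delta_kick`` — an instantaneous voltage increment.
* ``double_exp_conductance`` — a synaptic event identical to a
  within-network spike arriving through ``g_ext`` with weight ``W_ext``
  after delay ``tau_d`` (used for clock input).

A clock train is the idealized output of a perfectly synchronous
homogeneous network: one synaptic event per period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SynapseParams

__all__ = [
    "PulseDescriptor",
    "SquarePulse",
    "DeltaKick",
    "CondPulseTrain",
    "clock_train",
]


@dataclass(frozen=True)
class SquarePulse:
    """Square current pulse to all neurons of population ``pop``.

    ``amplitude`` is in pA for IF populations (converted through g_ext),
    or the net voltage deflection for QIF populations when
    ``amplitude_is_deflection`` is set.
    """

    pop: str
    amplitude: float
    duration: float
    t_on: float
    amplitude_is_deflection: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class DeltaKick:
    """Instantaneous voltage increment ``dV`` to population ``pop`` at ``t``."""

    pop: str
    dV: float
    t: float


@dataclass(frozen=True)
class CondPulseTrain:
    """Double-exponential conductance events at given onset times.

    Each onset mimics one presynaptic spike of weight ``syn.W`` arriving
    after ``syn.tau_d``, through the target population's ``g_ext`` (the
    conductance cancels for the voltage equation, exactly as for
    within-network synapses).
    """

    pop: str
    onsets: np.ndarray
    syn: SynapseParams

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "onsets", np.sort(np.asarray(self.onsets, dtype=float))
        )


@dataclass(frozen=True)
class PulseDescriptor:
    """User-facing pulse description (converted to kernel forcing).

    ``kind`` is one of ``square_current``, ``delta_kick``,
    ``double_exp_conductance``.  For periodic trains set ``period``;
    for single pulses set ``onset``.
    """

    kind: str
    amplitude: float
    duration: float = 0.1
    onset: float | None = None
    period: float | None = None
    syn: SynapseParams | None = None

    def __post_init__(self) -> None:
        if self.kind not in (
            "square_current",
            "delta_kick",
            "double_exp_conductance",
        ):
            raise ValueError(f"unknown pulse kind {self.kind!r}")
        if self.kind == "square_current" and self.duration <= 0:
            raise ValueError("duration must be > 0 for square pulses")
        if self.period is not None and self.period <= 0:
            raise ValueError("period must be > 0")

    def at(self, pop: str, t_on: float, *, deflection: bool = False):
        """Materialize a single pulse of this descriptor at time ``t_on``."""
        if self.kind == "square_current":
            return SquarePulse(
                pop, self.amplitude, self.duration, t_on,
                amplitude_is_deflection=deflection,
            )
        if self.kind == "delta_kick":
            return DeltaKick(pop, self.amplitude, t_on)
        if self.syn is None:
            raise ValueError("double_exp_conductance pulse needs syn params")
        return CondPulseTrain(pop, np.array([t_on]), self.syn)


def clock_train(
    pop: str,
    period: float,
    t_end: float,
    syn: SynapseParams,
    t_start: float = 0.0,
) -> CondPulseTrain:
    """Strictly periodic conductance pulse train with onsets ``k*period``.

    Mimics the output of a homogeneous (zero-heterogeneity) network firing
    perfectly synchronously at ``1/period``.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if t_end <= period:
        raise ValueError("t_end must exceed one period")
    onsets = np.arange(t_start, t_end, period)
    return CondPulseTrain(pop, onsets, syn)
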