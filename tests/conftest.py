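"""Shared fixtures: calibrated networks and measured PRCs.

The expensive objects (calibrations, fmPRCs, mean-field cycles) are
session-scoped so the unit and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from gammaprc import (
    calibrate_mean_input,
    simulate,
    table1_ing,
)
from gammaprc.fmprc import (
    clock_pulse_factory,
    measure_fmprc,
    square_pulse_factory,
)
from gammaprc.meanfield import MFParams, adjoint_imprc, find_limit_cycle
from gammaprc.runner import ING_CLOCK_W, ing_clock_syn

CV_GRID = (0.0, 0.05, 0.1, 0.15, 0.2)


@pytest.fixture(scope="session")
def fig1_net():
    """Standard ING network: mean 20.4 pA, CV 0.15 (the 47 Hz regime)."""
    return table1_ing(mean_current=20.4, cv=0.15)


@pytest.fixture(scope="session")
def fig1_sim(fig1_net):
    """2.5 s simulation of the standard ING network."""
    return simulate(fig1_net, t_end=2500.0, dt=0.01)


@pytest.fixture(scope="session")
def cal40():
    """Mean input per CV calibrated to a 40 Hz natural frequency."""
    out = {}
    for cv in CV_GRID:
        out[cv] = calibrate_mean_input(
            lambda I, cv=cv: table1_ing(mean_current=I, cv=cv), 40.0, tol=0.1
        )
    return out


@pytest.fixture(scope="session")
def prc40(cal40):
    """fmPRC per CV at 40 Hz for the standard inhibitory pulse (1600 pA)."""
    out = {}
    for cv, I in cal40.items():
        net = table1_ing(mean_current=I, cv=cv)
        out[cv] = measure_fmprc(
            net, square_pulse_factory("I", -1600.0), phases=32,
            meta={"I": I, "cv": cv},
        )
    return out


@pytest.fixture(scope="session")
def cv01_44():
    """(mean input, network) for CV 0.1 calibrated to 44 Hz."""
    I = calibrate_mean_input(
        lambda I: table1_ing(mean_current=I, cv=0.1), 44.0, tol=0.05,
        t_end=2100.0, transient=300.0,
    )
    return I, table1_ing(mean_current=I, cv=0.1)


@pytest.fixture(scope="session")
def prc_clock_44(cv01_44):
    """64-phase fmPRC of the 44 Hz CV-0.1 network under clock pulses."""
    _, net = cv01_44
    return measure_fmprc(
        net, clock_pulse_factory("I", ing_clock_syn(ING_CLOCK_W)), phases=64
    )


@pytest.fixture(scope="session")
def ing_mft():
    """ING mean-field limit cycle and adjoint at delta_I = 3."""
    p = MFParams.ing(delta_i=3.0)
    lc = find_limit_cycle(p)
    z = adjoint_imprc(lc)
    return p, lc, z
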