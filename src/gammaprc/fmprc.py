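"""Finite-amplitude macroscopic phase-response curve (fmPRC).

The fmPRC of a collective rhythm is measured by direct simulation: the
network is run unperturbed, a single pulse is delivered at a phase
``phi`` of the rhythm cycle (``phi = (t_pulse - t_firstspike)/T``,
wrapped into [-0.5, 0.5)), and the phase shift of a later cycle is read
off as ``dphi = (t_unperturbed - t_perturbed)/T`` for corresponding spike
volleys (positive = advance).  Because the perturbation transiently
changes how many neurons participate in a volley, the shift needs a few
cycles to settle; shifts are recorded for readout cycles m = 1..m_max and
the converged (persistent) value is reported.

For rhythms whose volley onset is ill-defined (QIF networks with
Lorentzian drive, where some neurons fire incessantly) the phase
reference is the peak of the within-network synaptic variable instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

from .forcing import CondPulseTrain, DeltaKick, SquarePulse
from .metrics import detect_volleys
from .network import SimState, simulate
from .params import NetworkSpec, SynapseParams

__all__ = [
    "FmPRC",
    "measure_fmprc",
    "max_advance",
    "fmprc_sweep",
    "mechanism_summary",
    "wrap_phase",
    "square_pulse_factory",
    "clock_pulse_factory",
    "kick_factory",
    "deflection_factory",
]


def wrap_phase(x):
    """Wrap phases / phase shifts into [-0.5, 0.5)."""
    return (np.asarray(x) + 0.5) % 1.0 - 0.5


@dataclass
class FmPRC:
    """Tabulated macroscopic phase response.

    ``dphi`` holds the converged shift (readout cycle ``m_report``),
    ``dphi_first`` the immediate (m=1) shift, ``dphi_by_cycle`` all
    readout cycles.  ``valid`` marks phases where the perturbed network
    kept a detectable rhythm; ``converged`` marks phases where the shift
    settled to within ``conv_tol`` between consecutive readout cycles.
    """

    phases: np.ndarray
    dphi: np.ndarray
    dphi_first: np.ndarray
    dphi_by_cycle: np.ndarray
    valid: np.ndarray
    converged: np.ndarray
    T: float
    m_report: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort(self.phases)
        for name in ("phases", "dphi", "dphi_first", "valid", "converged"):
            setattr(self, name, getattr(self, name)[order])
        self.dphi_by_cycle = self.dphi_by_cycle[order]

    def interpolator(self, which: str = "converged"):
        """Periodic linear interpolant of the selected shift column."""
        y = self.dphi if which == "converged" else self.dphi_first
        ph = self.phases[self.valid]
        yv = y[self.valid]
        ph_ext = np.r_[ph - 1.0, ph, ph + 1.0]
        y_ext = np.r_[yv, yv, yv]
        return lambda q: np.interp(wrap_phase(q), ph_ext, y_ext)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phase": self.phases,
                "dphi": self.dphi,
                "dphi_first": self.dphi_first,
                "valid": self.valid,
                "converged": self.converged,
            }
        )


# -- pulse factories: map the time a pulse takes effect to forcing ----------


def square_pulse_factory(pop: str, amplitude: float, duration: float = 0.1):
    """Square current pulse (pA) acting immediately at the effect time."""

    def make(t_eff: float):
        return SquarePulse(pop, amplitude, duration, t_eff)

    return make


def clock_pulse_factory(pop: str, syn: SynapseParams):
    """Single double-exponential conductance pulse.

    The onset (presynaptic clock spike) is placed ``syn.tau_d`` before the
    effect time so that ``t_eff`` is when the conductance starts rising.
    """

    def make(t_eff: float):
        return CondPulseTrain(pop, np.array([t_eff - syn.tau_d]), syn)

    return make


def kick_factory(pop: str, dV: float):
    """Instantaneous voltage increment (delta pulse)."""

    def make(t_eff: float):
        return DeltaKick(pop, dV, t_eff)

    return make


def deflection_factory(pop: str, dV: float, duration: float = 0.02):
    """Square pulse delivering a net voltage deflection ``dV`` (QIF)."""

    def make(t_eff: float):
        return SquarePulse(
            pop, dV, duration, t_eff, amplitude_is_deflection=True
        )

    return make


# ---------------------------------------------------------------------------


def _syn_peak_times(res, label: str, T_hint: float, t_min: float) -> np.ndarray:
    s = res.syn[label]
    dt_rec = res.t_lfp[1] - res.t_lfp[0]
    dist = max(int(0.5 * T_hint / dt_rec), 1)
    idx, _ = find_peaks(s, distance=dist, height=0.2 * s.max())
    # refine each peak with a local parabola through three samples
    t_pk = []
    for i in idx:
        if 0 < i < len(s) - 1:
            denom = s[i - 1] - 2 * s[i] + s[i + 1]
            off = 0.5 * (s[i - 1] - s[i + 1]) / denom if denom != 0 else 0.0
            t_pk.append(res.t_lfp[i] + off * dt_rec)
        else:
            t_pk.append(res.t_lfp[i])
    t_pk = np.array(t_pk)
    return t_pk[t_pk > t_min]


def _cycle_ref_times(
    res, net: NetworkSpec, phase_ref: str, ref_pop: str, syn_label: str,
    T_hint: float, t_min: float,
) -> np.ndarray:
    """Per-cycle reference times: volley first spikes or synaptic peaks."""
    if phase_ref == "syn_peak":
        return _syn_peak_times(res, syn_label, T_hint, t_min)
    ids, ts = res.spikes_of(net, ref_pop)
    m = ts > t_min
    if not np.any(m):
        return np.empty(0)
    volleys = detect_volleys(ids[m], ts[m], T_hint)
    return volleys.t_first


def measure_fmprc(
    net: NetworkSpec,
    pulse_factory: Callable[[float], object],
    phases: np.ndarray | int = 64,
    *,
    dt: float = 0.01,
    t_settle: float = 500.0,
    m_max: int = 8,
    m_report: int = 5,
    conv_tol: float = 0.002,
    ref_pop: str | None = None,
    phase_ref: str = "volley",
    syn_label: str | None = None,
    realizations: int = 1,
    realization_nets: Callable[[int], NetworkSpec] | None = None,
    t_hint: float = 30.0,
    t_probe: float = 300.0,
    meta: dict | None = None,
) -> FmPRC:
    """Measure the fmPRC of a rhythmic network by direct perturbation.

    Parameters
    ----------
    net : NetworkSpec
        Must sustain a rhythm without forcing.
    pulse_factory : callable
        ``pulse_factory(t_eff)`` returns the forcing element whose effect
        starts at ``t_eff``.
    phases : int or array
        Number of equally spaced phases on [-0.5, 0.5) or an explicit
        grid.
    t_settle : float
        Unperturbed settling time before the reference cycle.
    m_max, m_report : int
        Readout cycles recorded / reported.
    ref_pop : str
        Population whose volleys define the rhythm phase (default: the
        perturbed population for ING, the E population for PING; here
        simply the first population unless given).
    phase_ref : {"volley", "syn_peak"}
        Cycle reference: first spike of the volley, or peak of the
        within-network synaptic variable ``syn_label``.
    realizations, realization_nets
        For PING-style averaging: ``realization_nets(k)`` builds the
        k-th network realization (e.g. redrawing I-cell biases); results
        are averaged across realizations.
    """
    if isinstance(phases, (int, np.integer)):
        phases = -0.5 + np.arange(phases) / phases
    phases = np.asarray(phases, float)
    if ref_pop is None:
        ref_pop = net.populations[0].name
    if syn_label is None:
        syn_label = f"{net.blocks[0].source}->{net.blocks[0].target}"

    acc_cycle = np.zeros((len(phases), m_max))
    acc_valid = np.zeros(len(phases))
    T_acc = 0.0
    for k in range(max(realizations, 1)):
        net_k = net if realization_nets is None else realization_nets(k)
        one = _measure_single(
            net_k, pulse_factory, phases, dt, t_settle, m_max,
            ref_pop, phase_ref, syn_label, t_hint, t_probe,
        )
        T_acc += one["T"]
        v = one["valid"]
        acc_cycle[v] += one["by_cycle"][v]
        acc_valid += v
    nreal = max(realizations, 1)
    valid = acc_valid == nreal
    by_cycle = np.full((len(phases), m_max), np.nan)
    by_cycle[valid] = acc_cycle[valid] / nreal
    dphi = by_cycle[:, m_report - 1]
    dphi_first = by_cycle[:, 0]
    conv = np.zeros(len(phases), bool)
    conv[valid] = (
        np.abs(by_cycle[valid, m_report - 1] - by_cycle[valid, m_report - 2])
        < conv_tol
    )
    return FmPRC(
        phases=phases,
        dphi=dphi,
        dphi_first=dphi_first,
        dphi_by_cycle=by_cycle,
        valid=valid,
        converged=conv,
        T=T_acc / nreal,
        m_report=m_report,
        meta=meta or {},
    )


def _measure_single(
    net, pulse_factory, phases, dt, t_settle, m_max,
    ref_pop, phase_ref, syn_label, t_hint=30.0, t_probe=300.0,
):
    # settle and snapshot
    settle = simulate(net, t_end=t_settle, dt=dt)
    S0: SimState = settle.state

    # unperturbed reference run long enough for all readout cycles
    probe = simulate(net, t_end=t_settle + t_probe, dt=dt, state=S0.copy())
    ref0 = _cycle_ref_times(
        probe, net, phase_ref, ref_pop, syn_label, t_hint, t_settle
    )
    if len(ref0) < 4:
        raise ValueError("network is not rhythmic after settling")
    T = float(np.mean(np.diff(ref0)))
    horizon = t_settle + (m_max + 6) * T
    unpert = simulate(net, t_end=horizon, dt=dt, state=S0.copy())
    t_ref_u = _cycle_ref_times(
        unpert, net, phase_ref, ref_pop, syn_label, T, t_settle
    )
    T = float(np.mean(np.diff(t_ref_u)))
    # reference cycle: all pulse times t_ref + phi*T must lie after t_settle
    k0 = int(np.searchsorted(t_ref_u, t_settle + 0.8 * T))
    if k0 + m_max + 1 >= len(t_ref_u):
        raise ValueError("reference run too short")
    t_anchor = t_ref_u[k0]

    by_cycle = np.full((len(phases), m_max), np.nan)
    valid = np.zeros(len(phases), bool)
    for i, ph in enumerate(phases):
        t_eff = t_anchor + ph * T
        pert = simulate(
            net, pulse_factory(t_eff), t_end=horizon, dt=dt, state=S0.copy()
        )
        t_ref_p = _cycle_ref_times(
            pert, net, phase_ref, ref_pop, syn_label, T, t_settle
        )
        # rhythm lost if no cycle reference within 3T after the pulse
        if len(t_ref_p) == 0 or not np.any(
            (t_ref_p > t_eff) & (t_ref_p < t_eff + 3 * T)
        ):
            continue
        ok = True
        for m in range(1, m_max + 1):
            t_u = t_ref_u[k0 + m]
            j = int(np.argmin(np.abs(t_ref_p - t_u)))
            by_cycle[i, m - 1] = wrap_phase((t_u - t_ref_p[j]) / T)
        valid[i] = ok
    return {"T": T, "by_cycle": by_cycle, "valid": valid}


def max_advance(prc: FmPRC) -> tuple[float, float, bool]:
    """Maximum phase shift, its phase, and the paradoxical flag.

    For an inhibitory perturbation a positive maximum is *paradoxical*
    (inhibition advancing the rhythm although it delays every neuron).
    """
    if not np.any(prc.valid):
        raise ValueError("fmPRC has no valid entries")
    d = np.where(prc.valid, prc.dphi, -np.inf)
    i = int(np.nanargmax(d))
    return float(prc.dphi[i]), float(prc.phases[i]), bool(prc.dphi[i] > 0)


def mechanism_summary(
    net: NetworkSpec,
    pulse_factory,
    t_eff_phase: float,
    *,
    dt: float = 0.01,
    t_settle: float = 500.0,
    ref_pop: str | None = None,
    syn_label: str | None = None,
):
    """Spike-count and inhibition change in the perturbed cycle.

    Runs the unperturbed and perturbed network from identical state with
    a pulse at phase ``t_eff_phase`` of the reference cycle and returns
    the number of spikes in the cycle containing the pulse and the mean
    absolute within-network synaptic drive over the following period, for
    both runs.  The paradoxical-advance mechanism predicts fewer spikes
    and less within-network inhibition in the perturbed cycle.
    """
    if ref_pop is None:
        ref_pop = net.populations[0].name
    if syn_label is None:
        syn_label = f"{net.blocks[0].source}->{net.blocks[0].target}"
    settle = simulate(net, t_end=t_settle, dt=dt)
    S0 = settle.state
    horizon = t_settle + 200.0
    unpert = simulate(net, t_end=horizon, dt=dt, state=S0.copy())
    ids, ts = unpert.spikes_of(net, ref_pop)
    m = ts > t_settle
    volleys = detect_volleys(ids[m], ts[m], 30.0)
    T = volleys.mean_period()
    k0 = int(np.searchsorted(volleys.t_first, t_settle + 0.8 * T))
    t_anchor = volleys.t_first[k0]
    t_eff = t_anchor + t_eff_phase * T

    pert = simulate(net, pulse_factory(t_eff), t_end=horizon, dt=dt, state=S0.copy())

    def cycle_stats(res):
        ids_, ts_ = res.spikes_of(net, ref_pop)
        win = (ts_ >= t_anchor - 0.3 * T) & (ts_ < t_anchor + 0.7 * T)
        n_spk = int(np.sum(win))
        tm = (res.t_lfp >= t_eff) & (res.t_lfp < t_eff + T)
        inh = float(np.mean(np.abs(res.syn[syn_label][tm])))
        return n_spk, inh

    n_u, inh_u = cycle_stats(unpert)
    n_p, inh_p = cycle_stats(pert)
    return {
        "spikes_unperturbed": n_u,
        "spikes_perturbed": n_p,
        "inhibition_unperturbed": inh_u,
        "inhibition_perturbed": inh_p,
    }


def fmprc_sweep(
    make_net: Callable[..., NetworkSpec],
    pulse_factory_for: Callable[[dict], Callable],
    axes: dict[str, np.ndarray],
    *,
    calibration: str = "fixed-I",
    target_f: float | None = None,
    calibrate_kw: dict | None = None,
    fmprc_kw: dict | None = None,
):
    """Tidy table of fmPRC summaries over parameter grids.

    ``axes`` maps parameter names (passed to ``make_net`` as keywords) to
    grids; the sweep is over their Cartesian product.  In ``fixed-f``
    mode ``make_net`` must accept ``mean_current`` which is calibrated to
    ``target_f`` at every grid point.  Grid points whose rhythm has
    disintegrated are flagged (``ok = False``), not fatal.

    Returns a pandas DataFrame with one row per grid point: the axis
    values, the calibrated mean input (fixed-f mode), the rhythm period,
    and the maximal advance in phase units and in ms.
    """
    import itertools

    import pandas as pd

    from .network import calibrate_mean_input

    names = list(axes)
    rows = []
    for combo in itertools.product(*(axes[n] for n in names)):
        point = dict(zip(names, combo))
        row = dict(point)
        try:
            if calibration == "fixed-f":
                if target_f is None:
                    raise ValueError("fixed-f mode needs target_f")
                I = calibrate_mean_input(
                    lambda I, p=point: make_net(mean_current=I, **p),
                    target_f,
                    **(calibrate_kw or {}),
                )
                net = make_net(mean_current=I, **point)
                row["mean_current"] = I
            else:
                net = make_net(**point)
            prc = measure_fmprc(
                net, pulse_factory_for(point), **(fmprc_kw or {})
            )
            mx, arg, para = max_advance(prc)
            row.update(
                T=prc.T,
                max_advance_phase=mx,
                max_advance_ms=mx * prc.T,
                argmax_phase=arg,
                paradoxical=para,
                ok=True,
            )
        except (ValueError, RuntimeError) as e:  # disintegrated / no rhythm
            row.update(ok=False, error=str(e))
        rows.append(row)
    return pd.DataFrame(rows)
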