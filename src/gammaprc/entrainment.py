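"""Clock-forced simulations and synchronization phase diagrams.

A network with natural frequency ``f_nat`` receives one inhibitory (ING)
or excitatory (PING) conductance volley per clock cycle at ``f_clock``.
The synchronization state is characterized by

* the relative phase series ``Phi(n) = (t_clock(n) + tau_d -
  t_firstspike(n)) / T`` per clock cycle (silent cycles marked with the
  sentinel 2),
* the LFP spectrum: dominant frequency, strongest sub-/super-harmonic
  peaks relative to ``f_clock`` and their power ratios (capped at 1),
* a three-way classification: type 1 — ``f_dom != f_clock`` (not
  synchronized); type 2 — ``f_dom = f_clock`` with a subharmonic peak
  (frequency synchronization); type 3 — ``f_dom = f_clock`` with no
  subharmonic response (phase synchronization, 1:1 locking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcing import clock_train
from .metrics import SpectrumSummary, detect_volleys, lfp_spectrum
from .network import SimResult, simulate
from .params import NetworkSpec, SynapseParams

SILENT = 2.0  # sentinel value for clock cycles without a network volley

__all__ = [
    "SILENT",
    "EntrainmentSummary",
    "relative_phase_series",
    "classify_sync",
    "run_forced",
    "phase_diagram",
]


@dataclass
class EntrainmentSummary:
    """Spectral and phase-locking metrics of one forced simulation."""

    f_dom: float | None
    f_clock: float
    f_sub: float | None
    f_super: float | None
    power_ratio_sub: float
    power_ratio_super: float
    var_phase: float
    silent_fraction: float
    sync_type: int
    meta: dict = field(default_factory=dict)


def relative_phase_series(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    clock_onsets: np.ndarray,
    T_norm: float,
    tau_d: float,
    *,
    period_hint: float | None = None,
) -> np.ndarray:
    """Phase of the network volley relative to each clock cycle.

    For clock cycle ``n`` the volley nearest the delayed clock event
    ``t_clock(n) + tau_d`` (within half a cycle) defines ``Phi(n) =
    (t_clock(n) + tau_d - t_first(n)) / T_norm``; cycles with no volley
    within half a cycle get the sentinel :data:`SILENT`.  The centered
    window avoids spuriously silent cycles when the locked volley jitters
    around the cycle boundary.
    """
    hint = period_hint if period_hint is not None else T_norm
    volleys = detect_volleys(spike_ids, spike_times, hint)
    tf = volleys.t_first
    out = np.full(len(clock_onsets), SILENT)
    if len(tf) == 0:
        return out
    Tc = np.median(np.diff(clock_onsets)) if len(clock_onsets) > 1 else T_norm
    for n, tc in enumerate(clock_onsets):
        ref = tc + tau_d
        j = int(np.argmin(np.abs(tf - ref)))
        if abs(tf[j] - ref) <= 0.5 * Tc:
            out[n] = (ref - tf[j]) / T_norm
    return out


def classify_sync(
    spectrum: SpectrumSummary,
    f_clock: float,
    phi_series: np.ndarray,
    *,
    sub_power_floor: float = 0.02,
    f_tol: float | None = None,
) -> EntrainmentSummary:
    """Classify the synchronization state of a forced network.

    ``f_sub`` (``f_super``) is the strongest local spectral peak below
    (above) ``f_clock``; a subharmonic peak counts only if its power is at
    least ``sub_power_floor`` of the power at ``f_clock``.  Type 1 if the
    dominant frequency differs from ``f_clock`` (by more than one
    spectral bin), type 2 if it matches but a subharmonic is present,
    type 3 otherwise.
    """
    bin_w = spectrum.freqs[1] - spectrum.freqs[0] if len(spectrum.freqs) > 1 else 0.5
    tol = f_tol if f_tol is not None else 1.5 * bin_w
    p_clock = spectrum.power_at(f_clock)

    sub = spectrum.peak_below(f_clock, margin=2 * bin_w)
    sup = spectrum.peak_above(f_clock, margin=2 * bin_w)
    pr_sub = min(sub[1] / p_clock, 1.0) if (sub and p_clock > 0) else 0.0
    pr_sup = min(sup[1] / p_clock, 1.0) if (sup and p_clock > 0) else 0.0

    live = phi_series[phi_series != SILENT]
    var_phase = float(np.var(live)) if len(live) else float("nan")
    silent_fraction = float(np.mean(phi_series == SILENT)) if len(phi_series) else 1.0

    if spectrum.f_dom is None or abs(spectrum.f_dom - f_clock) > tol:
        sync_type = 1
    elif sub is not None and pr_sub >= sub_power_floor:
        sync_type = 2
    else:
        sync_type = 3
    return EntrainmentSummary(
        f_dom=spectrum.f_dom,
        f_clock=f_clock,
        f_sub=sub[0] if sub else None,
        f_super=sup[0] if sup else None,
        power_ratio_sub=pr_sub,
        power_ratio_super=pr_sup,
        var_phase=var_phase,
        silent_fraction=silent_fraction,
        sync_type=sync_type,
    )


def run_forced(
    net: NetworkSpec,
    f_clock: float,
    clock_syn: SynapseParams,
    *,
    target_pop: str | None = None,
    ref_pop: str | None = None,
    t_end: float = 4000.0,
    t_clock_start: float = 500.0,
    transient: float = 1500.0,
    dt: float = 0.01,
) -> tuple[SimResult, np.ndarray, EntrainmentSummary]:
    """Simulate a clock-forced network and summarize its entrainment.

    The clock train's per-volley weight is ``clock_syn.W`` (the summed
    strength of one synchronous clock volley).  Returns the simulation,
    the post-transient relative-phase series and the classification.
    """
    if target_pop is None:
        target_pop = net.populations[0].name
    if ref_pop is None:
        ref_pop = net.populations[0].name
    T_c = 1000.0 / f_clock
    train = clock_train(target_pop, T_c, t_end, clock_syn, t_start=t_clock_start)
    res = simulate(net, train, t_end=t_end, dt=dt)
    rec_dt = res.t_lfp[1] - res.t_lfp[0]
    spec = lfp_spectrum(res.lfp[ref_pop], rec_dt, transient=transient)
    ids, ts = res.spikes_of(net, ref_pop)
    m = ts > transient
    onsets = train.onsets[
        (train.onsets > transient) & (train.onsets < t_end - T_c)
    ]
    phi = relative_phase_series(
        ids[m], ts[m], onsets, T_c, clock_syn.tau_d, period_hint=T_c
    )
    summ = classify_sync(spec, f_clock, phi)
    return res, phi, summ


def phase_diagram(
    make_net,
    cv_grid: np.ndarray,
    df_grid: np.ndarray,
    *,
    target_f: float,
    clock_syn: SynapseParams,
    calibrate_kw: dict | None = None,
    forced_kw: dict | None = None,
):
    """Synchronization summary over a (heterogeneity, detuning) grid.

    At each ``cv`` the mean input is recalibrated so the unforced network
    keeps the target natural frequency; each ``delta_f`` then sets
    ``f_clock = target_f + delta_f``.  Calibration failures flag the
    whole ``cv`` row rather than aborting the sweep.

    Returns a tidy pandas DataFrame with one row per grid point.
    """
    import pandas as pd

    from .network import calibrate_mean_input

    rows = []
    for cv in np.asarray(cv_grid, float):
        try:
            I = calibrate_mean_input(
                lambda I, cv=cv: make_net(mean_current=I, cv=cv),
                target_f,
                **(calibrate_kw or {}),
            )
        except (RuntimeError, ValueError) as e:
            for df in df_grid:
                rows.append(dict(cv=cv, df=df, ok=False, error=str(e)))
            continue
        net = make_net(mean_current=I, cv=cv)
        for df in np.asarray(df_grid, float):
            f_clock = target_f + df
            try:
                _, phi, s = run_forced(
                    net, f_clock, clock_syn, **(forced_kw or {})
                )
                rows.append(
                    dict(
                        cv=cv,
                        df=df,
                        mean_current=I,
                        f_dom=s.f_dom,
                        f_clock=s.f_clock,
                        f_sub=s.f_sub,
                        f_super=s.f_super,
                        pr_sub=s.power_ratio_sub,
                        pr_super=s.power_ratio_super,
                        var_phase=s.var_phase,
                        silent_fraction=s.silent_fraction,
                        sync_type=s.sync_type,
                        ok=True,
                    )
                )
            except (RuntimeError, ValueError, FloatingPointError) as e:
                rows.append(dict(cv=cv, df=df, mean_current=I, ok=False, error=str(e)))
    return pd.DataFrame(rows)
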