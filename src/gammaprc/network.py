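"""Event-handling simulation of all-to-all IF and QIF networks.

:func:`simulate` marshals a :class:`~gammaprc.params.NetworkSpec` plus a
forcing description into the numba step kernels, and returns a
:class:`SimResult` with the spike raster, per-population LFP (mean
voltage) traces, per-block synaptic traces and a resumable end-state
snapshot.  Determinism: the integrator path depends only on the spec,
forcing and step size, so two runs that share those are bit-identical up
to the first differing pulse — the basis of the phase-response
measurements.

Conventions
-----------
* IF populations: ms / mV / pA / nS; voltage follows
  ``tau dV/dt = -(V - V_rest) + I_syn/g_syn + I_ext/g_ext + I_bias/g_bias``
  with delayed double-exponential conductance synapses.
* QIF populations: dimensionless units; ``tau dV/dt = eta + V^2 + I`` with
  current-based double-exponential synapses (inhibitory from populations
  named ``I``, excitatory otherwise) truncated at +-500.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import if_step_loop, qif_step_loop
from .forcing import CondPulseTrain, DeltaKick, SquarePulse
from .params import NetworkSpec

__all__ = [
    "SimState",
    "SimResult",
    "simulate",
    "single_neuron_prc",
    "calibrate_mean_input",
    "natural_frequency",
]


@dataclass
class SimState:
    """Resumable integrator snapshot at time ``t``."""

    t: float
    V: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    buf1: np.ndarray  # ring buffers rotated so slot j = boundary t + j*dt
    buf2: np.ndarray
    dt: float

    def copy(self) -> "SimState":
        return SimState(
            self.t,
            self.V.copy(),
            self.A1.copy(),
            self.A2.copy(),
            self.buf1.copy(),
            self.buf2.copy(),
            self.dt,
        )


@dataclass
class SimResult:
    """One network simulation: raster, LFP and synaptic traces."""

    spike_ids: np.ndarray
    spike_times: np.ndarray
    t_lfp: np.ndarray
    lfp: dict[str, np.ndarray]
    syn: dict[str, np.ndarray]
    rate: dict[str, np.ndarray] | None
    dt: float
    t0: float
    t_end: float
    state: SimState

    def spikes_of(self, spec: NetworkSpec, pop: str):
        """Raster restricted to one population (ids, times)."""
        names = [p.name for p in spec.populations]
        sizes = [p.n for p in spec.populations]
        off = np.cumsum([0] + sizes)
        k = names.index(pop)
        m = (self.spike_ids >= off[k]) & (self.spike_ids < off[k + 1])
        return self.spike_ids[m] - off[k], self.spike_times[m]

    def raster_table(self) -> np.ndarray:
        """Two-column (neuron_id, time_ms) array, time-sorted."""
        return np.column_stack([self.spike_ids, self.spike_times])


def _block_label(src: str | None, tgt: str, j: int) -> str:
    return f"{src}->{tgt}" if src is not None else f"ext{j}->{tgt}"


def _marshal_forcing(forcing):
    if forcing is None:
        return [], [], []
    if not isinstance(forcing, (list, tuple)):
        forcing = [forcing]
    squares = [f for f in forcing if isinstance(f, SquarePulse)]
    kicks = [f for f in forcing if isinstance(f, DeltaKick)]
    trains = [f for f in forcing if isinstance(f, CondPulseTrain)]
    if len(squares) + len(kicks) + len(trains) != len(forcing):
        bad = [f for f in forcing if not isinstance(f, (SquarePulse, DeltaKick, CondPulseTrain))]
        raise TypeError(f"unsupported forcing element(s): {bad!r}")
    return squares, kicks, trains


def simulate(
    net: NetworkSpec,
    forcing=None,
    *,
    t_end: float,
    dt: float = 0.01,
    record_every: float = 0.05,
    state: SimState | None = None,
    max_dv: float = 20.0,
    mean_rate_guess: float = 0.2,
) -> SimResult:
    """Integrate the network from ``state`` (or rest) to ``t_end``.

    Parameters
    ----------
    net : NetworkSpec
        Validated network description.
    forcing : SquarePulse | DeltaKick | CondPulseTrain | list | None
        External input; times are absolute (same axis as ``t_end``).
    t_end : float
        Absolute end time (ms or model units).
    dt : float
        Fixed step.  Must resolve the shortest pulse used.
    record_every : float
        LFP/synaptic-trace sampling interval; must be a multiple of dt.
    state : SimState, optional
        Resume from a previous run's end state (same net and dt).
    max_dv : float
        Abort guard on the per-step voltage change (IF family).
    mean_rate_guess : float
        Per-neuron spike-rate guess (spikes per unit time) used to size
        the raster buffer; the buffer grows by rerun if exceeded.
    """
    names = [p.name for p in net.populations]
    sizes = [p.n for p in net.populations]
    pop_off = np.cumsum([0] + sizes).astype(np.int64)
    n_tot = int(pop_off[-1])

    rec_every = int(round(record_every / dt))
    if abs(rec_every * dt - record_every) > 1e-9:
        raise ValueError("record_every must be a multiple of dt")

    t0 = 0.0 if state is None else state.t
    n_steps = int(round((t_end - t0) / dt))
    if n_steps <= 0:
        raise ValueError("t_end must exceed the start time")

    squares, kicks, trains = _marshal_forcing(forcing)

    # blocks: internal first, then one per conductance train
    b_src, b_tgt, labels = [], [], []
    b_tau1, b_tau2, b_vrev, b_norm, b_jump, b_taud, b_sign = [], [], [], [], [], [], []
    for blk in net.blocks:
        sp = names.index(blk.source)
        tp = names.index(blk.target)
        syn = blk.syn
        b_src.append(sp)
        b_tgt.append(tp)
        labels.append(_block_label(blk.source, blk.target, 0))
        b_tau1.append(syn.tau1)
        b_tau2.append(syn.tau2)
        b_vrev.append(syn.V_rev)
        b_taud.append(syn.tau_d)
        tgt_tau = net.populations[tp].neuron.tau
        b_norm.append(tgt_tau / (syn.tau2 - syn.tau1))
        if net.family == "IF":
            b_jump.append(syn.W)
        else:
            # mean-field convention: each spike jumps the unit-area kernel
            # by J/(N*(tau2-tau1)) so the population drive matches J*r
            b_jump.append(syn.W / (sizes[sp] * (syn.tau2 - syn.tau1)))
        b_sign.append(-1.0 if blk.source.startswith("I") else 1.0)
    onset_lists = [np.empty(0)] * len(net.blocks)
    for j, tr in enumerate(trains):
        tp = names.index(tr.pop)
        syn = tr.syn
        b_src.append(-1)
        b_tgt.append(tp)
        labels.append(_block_label(None, tr.pop, j))
        b_tau1.append(syn.tau1)
        b_tau2.append(syn.tau2)
        b_vrev.append(syn.V_rev)
        b_taud.append(syn.tau_d)
        tgt_tau = net.populations[tp].neuron.tau
        b_norm.append(tgt_tau / (syn.tau2 - syn.tau1))
        b_jump.append(syn.W)
        b_sign.append(-1.0)
        onset_lists.append(tr.onsets)
    nb = len(b_src)

    max_delay = max(b_taud) if b_taud else 0.0
    L = int(np.ceil(max_delay / dt)) + 3

    if state is not None:
        if state.dt != dt:
            raise ValueError("resume requires the same dt")
        nb_s, L_s = state.buf1.shape
        if nb_s > nb or L_s > L:
            raise ValueError("resume state does not match net/forcing layout")
        V = state.V.copy()
        # a run may add external blocks (appended after the internal ones)
        # and/or a longer delay buffer; pad the snapshot with zeros.
        A1 = np.zeros(nb)
        A2 = np.zeros(nb)
        A1[:nb_s] = state.A1
        A2[:nb_s] = state.A2
        buf1 = np.zeros((nb, L))
        buf2 = np.zeros((nb, L))
        # snapshot buffers are rotated to slot j = boundary t0 + j*dt; the
        # kernel indexes slots by (k + j) % L with k starting at 0, which
        # is the same alignment as long as pending arrivals fit in L.
        buf1[:nb_s, :L_s] = state.buf1
        buf2[:nb_s, :L_s] = state.buf2
    else:
        V = np.concatenate([
            np.full(p.n, p.neuron.V_rest if net.family == "IF" else -1.0)
            for p in net.populations
        ])
        A1 = np.zeros(nb)
        A2 = np.zeros(nb)
        buf1 = np.zeros((nb, L))
        buf2 = np.zeros((nb, L))

    onsets_flat = (
        np.concatenate(onset_lists) if onset_lists else np.empty(0)
    )
    onset_off = np.cumsum([0] + [len(o) for o in onset_lists]).astype(np.int64)
    # skip onsets whose arrival boundary already lies at or before t0
    onset_ptr = np.zeros(nb, dtype=np.int64)
    for b in range(nb):
        if b_src[b] == -1:
            o = onset_lists[b]
            onset_ptr[b] = int(np.sum(o + b_taud[b] <= t0 + 1e-12))

    # square pulses / kicks (absolute times; keep those overlapping the run)
    sq_tgt, sq_t0, sq_t1, sq_dv = [], [], [], []
    for sq in squares:
        tp = names.index(sq.pop)
        popn = net.populations[tp]
        if sq.duration < dt:
            raise ValueError("square pulse duration must be >= dt")
        if net.family == "IF":
            if sq.amplitude_is_deflection:
                dv = sq.amplitude * popn.neuron.tau / sq.duration
            else:
                dv = sq.amplitude / popn.g_ext
        else:
            # QIF: amplitude is the net voltage deflection dV
            dv = sq.amplitude * popn.neuron.tau / sq.duration
        sq_tgt.append(tp)
        sq_t0.append(sq.t_on)
        sq_t1.append(sq.t_on + sq.duration)
        sq_dv.append(dv)
    kicks = sorted((k for k in kicks if k.t > t0 - 1e-12), key=lambda k: k.t)
    kick_tgt = np.array([names.index(k.pop) for k in kicks], dtype=np.int64)
    kick_t = np.array([k.t for k in kicks])
    kick_dv = np.array([k.dV for k in kicks])
    kick_ptr = np.zeros(1, dtype=np.int64)

    nrec = (n_steps + rec_every - 1) // rec_every
    lfp_out = np.zeros((len(names), nrec))
    syn_out = np.zeros((nb, nrec))

    p_tau = np.array([p.neuron.tau for p in net.populations])
    bias = np.concatenate([
        np.asarray(p.bias, float) / (p.g_bias if net.family == "IF" else 1.0)
        for p in net.populations
    ])

    arr = lambda x, d=np.float64: np.asarray(x, dtype=d)
    max_spikes = max(1000, int(n_tot * mean_rate_guess * (t_end - t0)))
    while True:
        spike_id = np.empty(max_spikes, dtype=np.int64)
        spike_t = np.empty(max_spikes)
        V_run = V.copy()
        A1_run, A2_run = A1.copy(), A2.copy()
        buf1_run, buf2_run = buf1.copy(), buf2.copy()
        ptr_run = onset_ptr.copy()
        kick_ptr[:] = 0
        if net.family == "IF":
            p_vrest = np.array([p.neuron.V_rest for p in net.populations])
            p_vpeak = np.array([p.neuron.V_peak for p in net.populations])
            p_vreset = np.array([p.neuron.V_reset for p in net.populations])
            rate_out = None
            n_sp, err = if_step_loop(
                n_steps, dt, t0, pop_off,
                p_tau, p_vrest, p_vpeak, p_vreset,
                bias, V_run,
                arr(b_src, np.int64), arr(b_tgt, np.int64),
                arr(b_tau1), arr(b_tau2), arr(b_vrev), arr(b_norm),
                arr(b_jump), arr(b_taud),
                A1_run, A2_run, L, buf1_run, buf2_run,
                onsets_flat, onset_off, ptr_run,
                arr(sq_tgt, np.int64), arr(sq_t0), arr(sq_t1), arr(sq_dv),
                kick_tgt, kick_t, kick_dv, kick_ptr,
                rec_every, lfp_out, syn_out, spike_id, spike_t, max_dv,
            )
        else:
            p_vpeak = np.array([p.neuron.V_peak for p in net.populations])
            p_vreset = np.array([p.neuron.V_reset for p in net.populations])
            rate_out = np.zeros((len(names), nrec))
            n_sp, err = qif_step_loop(
                n_steps, dt, t0, pop_off,
                p_tau, p_vpeak, p_vreset,
                bias, V_run,
                arr(b_src, np.int64), arr(b_tgt, np.int64),
                arr(b_tau1), arr(b_tau2), arr(b_sign),
                arr(b_jump), arr(b_taud),
                A1_run, A2_run, L, buf1_run, buf2_run,
                arr(sq_tgt, np.int64), arr(sq_t0), arr(sq_t1), arr(sq_dv),
                kick_tgt, kick_t, kick_dv, kick_ptr,
                rec_every, lfp_out, rate_out, syn_out, spike_id, spike_t,
            )
        if err == 1:
            max_spikes *= 4
            continue
        if err == 2:
            raise FloatingPointError("voltage became non-finite")
        if err == 3:
            raise FloatingPointError(
                "per-step voltage change exceeded max_dv; reduce dt"
            )
        break

    order = np.argsort(spike_t[:n_sp], kind="stable")
    ids = spike_id[:n_sp][order]
    ts = spike_t[:n_sp][order]

    # rotate ring buffers so slot j corresponds to boundary t_end + j*dt
    shift = n_steps % L
    rot1 = np.roll(buf1_run, -shift, axis=1)
    rot2 = np.roll(buf2_run, -shift, axis=1)
    end_state = SimState(t0 + n_steps * dt, V_run, A1_run, A2_run, rot1, rot2, dt)

    t_lfp = t0 + dt * rec_every * np.arange(nrec)
    return SimResult(
        spike_ids=ids,
        spike_times=ts,
        t_lfp=t_lfp,
        lfp={nm: lfp_out[i] for i, nm in enumerate(names)},
        syn={labels[b]: syn_out[b] for b in range(nb)},
        rate=(
            {nm: rate_out[i] for i, nm in enumerate(names)}
            if rate_out is not None
            else None
        ),
        dt=dt,
        t0=t0,
        t_end=t0 + n_steps * dt,
        state=end_state,
    )


# ---------------------------------------------------------------------------


def single_neuron_prc(
    net_single: NetworkSpec,
    pulse_factory,
    phases: np.ndarray,
    *,
    dt: float = 0.01,
    t_settle: float = 200.0,
) -> np.ndarray:
    """Microscopic PRC of one uncoupled neuron.

    ``net_single`` must hold exactly one neuron and no synaptic blocks
    (periodic firing under bias alone); ``pulse_factory(t_on)`` returns
    the forcing element applied at time ``t_on``.  Returns an array of
    shape (len(phases), 2): (phase, shift of the next spike in phase
    units; positive = advance).

    Raises
    ------
    ValueError
        If the bias is subthreshold (no spiking).
    """
    if sum(p.n for p in net_single.populations) != 1 or net_single.blocks:
        raise ValueError("expected a single uncoupled neuron")
    base = simulate(net_single, t_end=t_settle + 400.0, dt=dt)
    ts = base.spike_times
    ts = ts[ts > t_settle]
    if len(ts) < 3:
        raise ValueError("subthreshold bias: neuron does not fire periodically")
    T = float(np.mean(np.diff(ts)))
    t_ref = float(ts[0])
    out = np.empty((len(phases), 2))
    for i, ph in enumerate(np.asarray(phases, float)):
        t_on = t_ref + ph * T
        pert = simulate(
            net_single, pulse_factory(t_on), t_end=t_ref + 3 * T, dt=dt
        )
        tp = pert.spike_times[pert.spike_times > t_on]
        tu = ts[ts > t_on]
        if len(tp) == 0 or len(tu) == 0:
            raise ValueError("no spike after perturbation")
        out[i] = ph, (tu[0] - tp[0]) / T
    return out


def natural_frequency(
    net: NetworkSpec,
    *,
    t_end: float = 1500.0,
    transient: float = 500.0,
    dt: float = 0.01,
    pop: str | None = None,
) -> float:
    """Natural frequency (Hz for IF) from the mean inter-volley interval.

    Uses volley detection on the post-transient raster; equals the
    spectral dominant frequency within one bin for a well-separated
    rhythm, with far finer resolution than a periodogram of the same
    length.
    """
    from .metrics import detect_volleys

    res = simulate(net, t_end=t_end, dt=dt)
    ids, ts = res.spike_ids, res.spike_times
    if pop is not None:
        ids, ts = res.spikes_of(net, pop)
    m = ts > transient
    if not np.any(m):
        raise ValueError("network does not spike after the transient")
    # coarse period guess from the median inter-spike gap structure
    ts_sel = ts[m]
    hint = max(np.median(np.diff(ts_sel)) * 10.0, 1.0)
    for _ in range(4):
        volleys = detect_volleys(ids[m], ts_sel, hint)
        if len(volleys) >= 5:
            new_hint = volleys.mean_period()
            if abs(new_hint - hint) < 0.01 * hint:
                hint = new_hint
                break
            hint = new_hint
        else:
            hint *= 2.0
    volleys = detect_volleys(ids[m], ts_sel, hint)
    if len(volleys) < 3:
        raise ValueError("rhythm not detected")
    return 1000.0 / volleys.mean_period()


def calibrate_mean_input(
    make_net,
    target_f: float,
    *,
    tol: float = 0.1,
    bracket: tuple[float, float] = (8.0, 26.0),
    t_end: float = 1100.0,
    transient: float = 300.0,
    dt: float = 0.01,
    max_iter: int = 40,
    pop: str | None = None,
) -> float:
    """Mean bias current yielding the target natural frequency.

    ``make_net(I)`` builds the network for mean input ``I``; the network
    frequency is monotone increasing in ``I`` on the single-spike-per-
    cycle branch, so safeguarded bisection applies.  The default bracket
    stays below the strong-drive regime where neurons fire twice per
    volley and f(I) folds back.  The initial bracket is expanded
    (boundedly) if it does not straddle the target.

    Returns the calibrated mean input; raises ``RuntimeError`` if no
    bracket is found.
    """

    def f_of(I):
        return natural_frequency(
            make_net(I), t_end=t_end, transient=transient, dt=dt, pop=pop
        )

    lo, hi = bracket
    f_lo, f_hi = f_of(lo), f_of(hi)
    grow = 0
    while f_lo > target_f and grow < 4:
        lo *= 0.5
        f_lo = f_of(lo)
        grow += 1
    while f_hi < target_f and grow < 8:
        hi *= 1.5
        f_hi = f_of(hi)
        grow += 1
    if not (f_lo <= target_f <= f_hi):
        raise RuntimeError(
            f"no bracket: f({lo})={f_lo:.2f}, f({hi})={f_hi:.2f} vs {target_f}"
        )
    for _ in range(max_iter):
        # secant proposal, safeguarded by the bracket
        if f_hi > f_lo:
            mid = lo + (target_f - f_lo) * (hi - lo) / (f_hi - f_lo)
            mid = min(max(mid, lo + 0.05 * (hi - lo)), hi - 0.05 * (hi - lo))
        else:
            mid = 0.5 * (lo + hi)
        f_mid = f_of(mid)
        if abs(f_mid - target_f) <= tol:
            return float(mid)
        if f_mid < target_f:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    raise RuntimeError("calibration did not converge")
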