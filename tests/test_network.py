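"""Spiking-network simulator: exactness, convergence, determinism."""

import numpy as np
import pytest

from gammaprc import (
    DeltaKick,
    SquarePulse,
    natural_frequency,
    simulate,
    single_neuron_prc,
    table1_ing,
    table1_ping,
    table2_ing,
)
from gammaprc.metrics import detect_volleys
from gammaprc.params import (
    ConnectionBlock,
    IFNeuronParams,
    NetworkSpec,
    Population,
    SynapseParams,
)

NEURON = IFNeuronParams(tau=20.0, V_rest=-55.0, V_peak=-50.0, V_reset=-60.0)


def single_if(bias=20.4):
    pop = Population("I", NEURON, np.array([bias]), g_bias=0.3, g_ext=4.0)
    return NetworkSpec("IF", (pop,), ())


def test_single_neuron_isi_closed_form():
    """Free IF period T = tau*ln((Vinf - Vreset)/(Vinf - Vpeak))."""
    res = simulate(single_if(20.4), t_end=100.0, dt=0.01)
    v_inf = -55.0 + 20.4 / 0.3
    T = 20.0 * np.log((v_inf + 60.0) / (v_inf + 50.0))
    isi = np.diff(res.spike_times)
    assert np.allclose(isi[1:], T, rtol=0.005)


def test_homogeneous_network_fires_synchronously():
    net = table1_ing(cv=0.0, mean_current=18.0)
    res = simulate(net, t_end=600.0, dt=0.01)
    m = res.spike_times > 200.0
    volleys = detect_volleys(res.spike_ids[m], res.spike_times[m], 25.0)
    for v in volleys[1:-1]:
        assert v.t_last - v.t_first == 0.0
        assert v.count == 500


def test_shared_synapse_matches_per_pair_reference():
    """The shared filtered-spike-train optimization is exact.

    Reference: per-presynaptic-neuron double-exponential states summed at
    the target (the definition of the pairwise synaptic current for
    identical weights), integrated with the same scheme in plain python.
    """
    n = 10
    rng_bias = np.linspace(16.0, 24.0, n)
    pop = Population("I", NEURON, rng_bias, g_bias=0.3, g_ext=4.0)
    syn = SynapseParams(tau1=0.5, tau2=5.0, tau_d=3.0, V_rev=-70.0, W=3e-2, g=4.0)
    net = NetworkSpec("IF", (pop,), (ConnectionBlock("I", "I", syn),))
    dt, t_end = 0.01, 300.0
    res = simulate(net, t_end=t_end, dt=dt)

    # reference integrator with one (A1, A2) pair per presynaptic neuron
    steps = int(round(t_end / dt))
    V = np.full(n, NEURON.V_rest)
    A1 = np.zeros(n)
    A2 = np.zeros(n)
    L = int(np.ceil(syn.tau_d / dt)) + 3
    buf1 = np.zeros((n, L))
    buf2 = np.zeros((n, L))
    d1, d2 = np.exp(-dt / syn.tau1), np.exp(-dt / syn.tau2)
    norm = NEURON.tau / (syn.tau2 - syn.tau1)
    bias_mv = rng_bias / 0.3
    spikes = []
    for k in range(steps):
        t = k * dt
        s = norm * (A2.sum() - A1.sum())
        G = 1.0 + s
        e = np.exp(-G * dt / NEURON.tau)
        a = (NEURON.V_rest + s * syn.V_rev + bias_mv) / G
        V_new = a + (V - a) * e
        crossed = V_new >= NEURON.V_peak
        for j in np.flatnonzero(crossed):
            frac = (NEURON.V_peak - V[j]) / (V_new[j] - V[j])
            t_cross = t + frac * dt
            spikes.append((j, t_cross))
            arr = t_cross + syn.tau_d
            ka = int(np.ceil(arr / dt - 1e-9))
            lag = ka * dt - arr
            buf1[j, ka % L] += syn.W * np.exp(-lag / syn.tau1)
            buf2[j, ka % L] += syn.W * np.exp(-lag / syn.tau2)
            V_new[j] = NEURON.V_reset
        V = V_new
        slot = (k + 1) % L
        A1 = A1 * d1 + buf1[:, slot]
        A2 = A2 * d2 + buf2[:, slot]
        buf1[:, slot] = 0.0
        buf2[:, slot] = 0.0
    ref_t = np.array([t for _, t in sorted(spikes, key=lambda x: x[1])])
    assert len(ref_t) == len(res.spike_times)
    assert np.allclose(ref_t, res.spike_times, atol=1e-9)


def test_dt_convergence_of_volley_times():
    net = table1_ing()
    fine = simulate(net, t_end=400.0, dt=0.005)
    coarse = simulate(net, t_end=400.0, dt=0.01)

    def volley_starts(res):
        m = res.spike_times > 200.0
        return detect_volleys(res.spike_ids[m], res.spike_times[m], 21.0).t_first

    vf, vc = volley_starts(fine), volley_starts(coarse)
    k = min(len(vf), len(vc))
    assert k >= 5
    assert np.all(np.abs(vf[:k] - vc[:k]) < 0.1)


def test_snapshot_resume_is_exact():
    net = table1_ing()
    whole = simulate(net, t_end=400.0, dt=0.01)
    first = simulate(net, t_end=200.0, dt=0.01)
    second = simulate(net, t_end=400.0, dt=0.01, state=first.state)
    t2 = np.r_[first.spike_times, second.spike_times]
    assert len(t2) == len(whole.spike_times)
    assert np.allclose(t2, whole.spike_times, atol=1e-9)
    assert np.allclose(second.lfp["I"], whole.lfp["I"][len(first.lfp["I"]):], atol=1e-9)


def test_zero_amplitude_pulse_leaves_trajectory_unchanged():
    net = table1_ing()
    base = simulate(net, t_end=300.0, dt=0.01)
    pert = simulate(
        net, SquarePulse("I", 0.0, 0.1, 150.0), t_end=300.0, dt=0.01
    )
    assert np.array_equal(base.spike_times, pert.spike_times)


def test_runaway_voltage_guard():
    with pytest.raises(FloatingPointError):
        simulate(
            single_if(20.4),
            SquarePulse("I", 5e6, 1.0, 10.0),
            t_end=50.0,
            dt=0.01,
            max_dv=5.0,
        )


class TestSingleNeuronPRC:
    def test_inhibitory_kick_always_delays(self):
        phases = np.linspace(0.05, 0.9, 8)
        tab = single_neuron_prc(
            single_if(), lambda t: DeltaKick("I", -2.0, t), phases
        )
        assert np.all(tab[:, 1] <= 1e-9)

    def test_zero_amplitude_shift_is_zero(self):
        tab = single_neuron_prc(
            single_if(), lambda t: DeltaKick("I", 0.0, t), np.array([0.3])
        )
        assert abs(tab[0, 1]) < 1e-9

    def test_delay_matches_piecewise_closed_form(self):
        """A voltage kick dV at phase p shifts the next crossing by the
        closed-form time for the linear membrane ODE."""
        bias = 20.4
        v_inf = -55.0 + bias / 0.3
        T = 20.0 * np.log((v_inf + 60.0) / (v_inf + 50.0))
        for ph, dV in ((0.1, -2.0), (0.8, -2.0), (0.5, 1.0)):
            tab = single_neuron_prc(
                single_if(bias), lambda t, dV=dV: DeltaKick("I", dV, t),
                np.array([ph]), dt=0.002,
            )
            # voltage on the free trajectory at phase ph
            v_ph = v_inf + (-60.0 - v_inf) * np.exp(-ph * T / 20.0)
            t_rest = 20.0 * np.log((v_inf - (v_ph + dV)) / (v_inf + 50.0))
            expected = ((1 - ph) * T - t_rest) / T  # positive = advance
            assert tab[0, 1] == pytest.approx(expected, abs=0.003)

    def test_subthreshold_bias_rejected(self):
        with pytest.raises(ValueError, match="subthreshold"):
            single_neuron_prc(
                single_if(1.0), lambda t: DeltaKick("I", -1.0, t), np.array([0.2])
            )


def test_ping_icells_silent_without_e_drive():
    """With the E-population subthreshold, I-cells never reach threshold."""
    net = table1_ping(mean_current_e=0.5, cv_e=0.0)
    res = simulate(net, t_end=600.0, dt=0.01)
    assert len(res.spike_times) == 0


def test_ping_rhythm_exists_at_moderate_drive():
    f = natural_frequency(
        table1_ping(mean_current_e=6.0, cv_e=0.1),
        t_end=1200.0, transient=400.0, pop="E",
    )
    assert 20.0 < f < 80.0


def test_qif_network_tracks_mean_field_orbit():
    """N=2000 QIF spiking network stays near the reduced-system orbit."""
    from gammaprc.meanfield import MFParams, find_limit_cycle

    net = table2_ing(n=2000)
    res = simulate(net, t_end=100.0, dt=0.001, record_every=0.01)
    s = res.syn["I->I"][res.t_lfp > 50.0]
    lc = find_limit_cycle(MFParams.ing(delta_i=3.0))
    smf = lc.s_of(np.linspace(0, lc.T, 400))
    assert s.max() == pytest.approx(smf.max(), rel=0.1)
    assert s.min() == pytest.approx(smf.min(), rel=0.15)
    from scipy.signal import find_peaks

    pk, _ = find_peaks(s, height=0.5 * s.max())
    T_spk = np.mean(np.diff(res.t_lfp[res.t_lfp > 50.0][pk]))
    assert T_spk == pytest.approx(lc.T, rel=0.02)
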