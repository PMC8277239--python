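"""Volley detection, spectra and phase dispersion."""

import numpy as np
import pytest

from gammaprc import detect_volleys, lfp_spectrum, phase_dispersion
from gammaprc.metrics import VolleySeq


def synthetic_raster(volley_times, n=50, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ids, ts = [], []
    for t0 in volley_times:
        ids.extend(range(n))
        ts.extend(t0 + jitter * rng.random(n))
    return np.array(ids), np.array(ts)


class TestDetectVolleys:
    def test_synchronous_volleys(self):
        ids, ts = synthetic_raster([10.0, 35.0, 60.0])
        v = detect_volleys(ids, ts, 25.0)
        assert len(v) == 3
        assert all(x.count == 50 and x.t_first == x.t_last for x in v)

    def test_gap_criterion_splits(self):
        v = detect_volleys(np.array([0, 1]), np.array([0.0, 13.0]), 25.0)
        assert len(v) == 2
        v = detect_volleys(np.array([0, 1]), np.array([0.0, 12.0]), 25.0)
        assert len(v) == 1

    def test_double_spike_joins_same_volley(self):
        ids = np.array([0, 1, 0, 1])
        ts = np.array([0.0, 0.5, 3.0, 30.0])
        v = detect_volleys(ids, ts, 25.0)
        assert len(v) == 2
        assert v[0].count == 3 and v[0].neurons == {0, 1}
        assert v[0].t_first == 0.0

    def test_empty_and_invalid(self):
        assert detect_volleys(np.array([]), np.array([]), 25.0) == []
        with pytest.raises(ValueError):
            detect_volleys(np.array([0]), np.array([1.0]), 0.0)


class TestLfpSpectrum:
    def test_sinusoid_dominant_frequency(self):
        dt = 0.05  # ms
        t = np.arange(0, 3000.0, dt)
        x = np.sin(2 * np.pi * 40.0 * t / 1000.0)
        sp = lfp_spectrum(x, dt, transient=500.0)
        assert sp.f_dom == pytest.approx(40.0, abs=0.5)

    def test_flat_trace_flagged(self):
        sp = lfp_spectrum(np.full(50_000, -55.0), 0.05, transient=0.0)
        assert sp.f_dom is None

    def test_subharmonic_peak_listed(self):
        dt = 0.05
        t = np.arange(0, 4000.0, dt)
        x = np.sin(2 * np.pi * 40.0 * t / 1000.0) + 0.4 * np.sin(
            2 * np.pi * 20.0 * t / 1000.0
        )
        sp = lfp_spectrum(x, dt, transient=500.0)
        sub = sp.peak_below(40.0)
        assert sub is not None and sub[0] == pytest.approx(20.0, abs=0.5)

    def test_fdom_matches_inter_volley_rate(self, fig1_sim):
        """Spectral peak equals 1/(mean inter-volley interval) to a bin."""
        sp = lfp_spectrum(fig1_sim.lfp["I"], 0.05, transient=500.0)
        m = fig1_sim.spike_times > 500.0
        v = detect_volleys(fig1_sim.spike_ids[m], fig1_sim.spike_times[m], 21.0)
        f_volley = 1000.0 / v.mean_period()
        assert abs(sp.f_dom - f_volley) <= 0.5


class TestPhaseDispersion:
    def test_synchronous_is_zero(self):
        ids, ts = synthetic_raster([10.0, 35.0, 60.0, 85.0])
        v = detect_volleys(ids, ts, 25.0)
        assert phase_dispersion(v, 25.0) == 0.0

    def test_known_width(self):
        ids, ts = synthetic_raster([10.0, 35.0, 60.0, 85.0])
        ts = ts + np.tile(np.linspace(0, 5.0, 50), 4)
        v = detect_volleys(ids, ts, 25.0)
        assert phase_dispersion(v, 25.0) == pytest.approx(0.2)

    def test_needs_three_volleys(self):
        with pytest.raises(ValueError):
            phase_dispersion(VolleySeq(), 25.0)

    def test_dispersion_increases_with_heterogeneity(self, cal40):
        from gammaprc import simulate, table1_ing

        disp = []
        for cv in (0.05, 0.15):
            net = table1_ing(mean_current=cal40[cv], cv=cv)
            r = simulate(net, t_end=1200.0, dt=0.01)
            m = r.spike_times > 400.0
            v = detect_volleys(r.spike_ids[m], r.spike_times[m], 25.0)
            disp.append(phase_dispersion(v, v.mean_period()))
        assert disp[0] < disp[1]
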