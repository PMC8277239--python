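"""Iterated phase map: construction, fixed points, bifurcations."""

import numpy as np
import pytest

from gammaprc.fmprc import FmPRC
from gammaprc.phasemap import (
    bifurcation_diagram,
    build_map,
    classify_orbit,
    fixed_points,
    iterate_map,
)

T_NAT = 25.0  # ms -> 40 Hz


def make_prc(dphi_fn, n=64, T=T_NAT):
    ph = -0.5 + np.arange(n) / n
    d = np.asarray(dphi_fn(ph), float)
    return FmPRC(
        phases=ph, dphi=d, dphi_first=d.copy(),
        dphi_by_cycle=np.tile(d[:, None], (1, 8)),
        valid=np.ones(n, bool), converged=np.ones(n, bool),
        T=T, m_report=5,
    )


def test_zero_prc_zero_detuning_is_identity():
    prc = make_prc(lambda p: np.zeros_like(p))
    tab = build_map(prc, 1000.0 / T_NAT)
    assert tab.is_identity()
    assert len(tab.discontinuities) == 0


def test_drift_only_map_has_no_fixed_point():
    prc = make_prc(lambda p: np.zeros_like(p))
    f_clock = 1000.0 / T_NAT + 2.0
    tab = build_map(prc, f_clock)
    assert fixed_points(tab) == []
    # uniform backward drift by T_nat/T_clock - 1 per cycle
    drift = tab.G - tab.grid
    assert np.allclose(drift, 1.0 - T_NAT * f_clock / 1000.0, atol=1e-12)


def test_degree_one_periodicity():
    prc = make_prc(lambda p: 0.05 * np.sin(2 * np.pi * p))
    tab = build_map(prc, 1000.0 / T_NAT + 1.0)
    x = np.linspace(0, 1, 13, endpoint=False)
    assert np.allclose(tab(x + 1.0), tab(x) + 1.0, atol=1e-12)
    assert np.allclose(tab(x - 2.0), tab(x) - 2.0, atol=1e-12)


def test_fixed_point_sits_at_prc_zero_crossing():
    """At zero detuning the entrained phase is a zero of the PRC with
    stabilizing (descending) slope."""
    prc = make_prc(lambda p: 0.05 * np.sin(2 * np.pi * p))
    tab = build_map(prc, 1000.0 / T_NAT)
    fps = fixed_points(tab)
    stable = [x for x, s, st in fps if st]
    assert len(stable) == 1
    # dphi zeros sit at phi = 0 (ascending) and +-0.5 (descending); only
    # the descending one is stable, with slope 1 + dphi'(phi*)
    assert stable[0] == pytest.approx(0.5, abs=0.01)
    slope = [s for _, s, st in fps if st][0]
    assert slope == pytest.approx(1.0 - 0.05 * 2 * np.pi, abs=0.02)


def test_iterate_matches_pure_python_oracle():
    prc = make_prc(lambda p: 0.08 * np.sin(2 * np.pi * p) + 0.01)
    tab = build_map(prc, 1000.0 / T_NAT + 1.5)
    orbit = iterate_map(tab, 0.37, n_transient=100, n_keep=50)

    gx = np.r_[tab.grid, 1.0]
    gy = np.r_[tab.G, tab.G[0] + 1.0]
    x = 0.37
    ref = []
    for k in range(150):
        x = float(np.interp(x % 1.0, gx, gy))
        if k >= 100:
            ref.append(x % 1.0)
    assert np.allclose(orbit, ref, atol=1e-12)


def test_slope_beyond_minus_one_gives_period_two():
    """A map whose stable branch slope passes -1 produces a period-2
    attractor exactly where |slope| exceeds one."""
    for amp in (0.1, 0.25, 0.4):
        prc = make_prc(lambda p, a=amp: a * np.sin(2 * np.pi * p))
        tab = build_map(prc, 1000.0 / T_NAT)
        # descending-zero fixed point at Phi = 0.5 with slope 1 - 2*pi*amp
        slope = 1.0 - 2 * np.pi * amp
        orbit = iterate_map(tab, 0.49, 2048, 256)
        label = classify_orbit(orbit)
        if abs(slope) < 1:
            assert label == "fixed point"
        else:
            assert label != "fixed point"


def test_period_doubling_onset_at_slope_minus_one(prc_clock_44):
    """On the measured clock-pulse PRC the entrained fixed point
    destabilizes where its interpolated slope crosses -1."""
    f_nat = 1000.0 / prc_clock_44.T
    dfs = np.arange(0.0, 3.01, 0.1)
    last_fp_slope = None
    onset = None
    for df in dfs:
        tab = build_map(prc_clock_44, f_nat + df)
        fps = fixed_points(tab)
        stable = [(x, s) for x, s, st in fps if st]
        orbit = iterate_map(
            tab, stable[0][0] if stable else (fps[0][0] if fps else 0.5), 512, 256
        )
        if classify_orbit(orbit) == "fixed point":
            slopes = [s for _, s, _ in fps]
            last_fp_slope = min(slopes) if slopes else None
        else:
            onset = df
            break
    assert onset is not None, "no period-doubling found below 3 Hz detuning"
    assert last_fp_slope == pytest.approx(-1.0, abs=0.3)


def test_discontinuous_prc_marks_map_discontinuity():
    def jumpy(p):
        d = 0.03 * np.sin(2 * np.pi * p)
        d[(p > 0.1) & (p < 0.3)] -= 0.4  # suppression branch
        return d

    prc = make_prc(jumpy)
    tab = build_map(prc, 1000.0 / T_NAT + 1.0)
    assert len(tab.discontinuities) >= 2
    assert tab.main_discontinuity is not None


def test_bifurcation_diagram_labels_and_straddle():
    amp = 0.12

    def jumpy(p):
        d = amp * np.sin(2 * np.pi * p)
        d[(p > 0.15) & (p < 0.35)] -= 0.45
        return d

    prc = make_prc(jumpy)
    bif = bifurcation_diagram(prc, np.arange(0.0, 4.0, 0.25), n_keep=512)
    assert set(bif.columns) >= {"delta_f", "label", "straddle", "single_branch"}
    assert bif.iloc[0]["label"] == "fixed point"


def test_gappy_prc_rejected():
    ph = -0.5 + np.arange(64) / 64
    d = 0.05 * np.sin(2 * np.pi * ph)
    valid = np.ones(64, bool)
    valid[10:20] = False  # a 10-node hole
    prc = FmPRC(
        phases=ph, dphi=d, dphi_first=d.copy(),
        dphi_by_cycle=np.tile(d[:, None], (1, 8)),
        valid=valid, converged=valid.copy(), T=T_NAT, m_report=5,
    )
    with pytest.raises(ValueError, match="missing segments"):
        build_map(prc, 40.0)
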