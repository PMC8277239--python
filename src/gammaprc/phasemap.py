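"""Iterated phase map for a periodically forced rhythm.

If a network with natural period ``T`` receives one forcing pulse per
clock cycle ``T_c``, the phase of the network relative to the clock,
``Phi_n = (t_clock(n) + tau_d - t_firstspike(n)) / T_c``, obeys a
one-cycle return map derived from the macroscopic PRC: the pulse in cycle
``n`` arrives at network phase ``phi_n = wrap(Phi_n * T_c / T)`` and
shifts the rhythm by ``dphi(phi_n)``, so

    Phi_{n+1} = G(Phi_n) = Phi_n + 1 - T * (1 - dphi(phi_n)) / T_c .

``G`` is treated as a circle map (degree one: ``G(Phi+1) = G(Phi)+1``).
Strong pulses make the measured PRC discontinuous (a suitably timed pulse
suppresses an entire spike volley, slipping the cycle correspondence);
those discontinuities are carried into ``G`` and never interpolated
across.  Fixed points of ``G`` are entrained states; as the detuning
``df = f_clock - f_nat`` grows the fixed point destabilizes in a
period-doubling cascade, and eventually the attractor spreads onto both
sides of the map discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .fmprc import FmPRC, wrap_phase

__all__ = [
    "PhaseMapTab",
    "build_map",
    "iterate_map",
    "fixed_points",
    "classify_orbit",
    "bifurcation_diagram",
    "first_straddling_detuning",
    "single_branch_upper_bound",
]


@dataclass
class PhaseMapTab:
    """Tabulated return map on a dense grid over one period.

    ``grid`` covers [0, 1); evaluation interpolates linearly between grid
    nodes and extends periodically with degree one.  ``discontinuities``
    are the Phi positions where the underlying PRC jumps (plus the
    periodic seam if the map extension jumps there).
    """

    grid: np.ndarray
    G: np.ndarray
    T_nat: float
    T_clock: float
    delta_f: float
    discontinuities: np.ndarray
    main_discontinuity: float | None
    meta: dict = field(default_factory=dict)

    def __call__(self, x):
        xw = np.asarray(x, float) % 1.0
        k = np.asarray(x, float) - xw
        # periodic closure node at Phi=1 for interpolation
        gx = np.r_[self.grid, 1.0]
        gy = np.r_[self.G, self.G[0] + 1.0]
        return np.interp(xw, gx, gy) + k

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.max(np.abs(self.G - self.grid)) < tol)


def _prc_segments(prc: FmPRC, which: str, disc_jump: float):
    """Circularly ordered (phases, values) plus discontinuity midpoints."""
    ph = prc.phases[prc.valid]
    y = (prc.dphi if which == "converged" else prc.dphi_first)[prc.valid]
    if len(ph) < 4:
        raise ValueError("fmPRC has too few valid entries")
    # refuse interpolation across wide missing stretches
    gaps = np.diff(np.r_[ph, ph[0] + 1.0])
    step = np.median(gaps)
    if np.any(gaps > 3.0 * step + 1e-12):
        raise ValueError("fmPRC has missing segments wider than 2 grid steps")
    dy = np.diff(np.r_[y, y[0]])
    cut = np.flatnonzero(np.abs(dy) > disc_jump)
    disc_mid = wrap_phase(ph[cut] + gaps[cut] / 2.0)
    return ph, y, cut, disc_mid


def _prc_evaluator(ph, y, cut):
    """Piecewise monotone-cubic evaluator that never crosses a cut."""
    n = len(ph)
    if len(cut) == 0:
        ext = np.r_[ph - 1.0, ph, ph + 1.0]
        return PchipInterpolator(ext, np.r_[y, y, y]), []
    # unroll the circle starting after the first cut
    start = (cut[0] + 1) % n
    order = (start + np.arange(n)) % n
    ph_u = ph[order].copy()
    ph_u[ph_u < ph_u[0]] += 1.0
    y_u = y[order]
    seg_breaks = [np.flatnonzero(order == (c + 1) % n)[0] for c in cut[1:]]
    bounds = sorted(set([0] + seg_breaks + [n]))
    pieces = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo == 1:
            pieces.append((ph_u[lo], ph_u[hi - 1], None, y_u[lo]))
        else:
            f = PchipInterpolator(ph_u[lo:hi], y_u[lo:hi])
            pieces.append((ph_u[lo], ph_u[hi - 1], f, None))

    def ev(q):
        q = np.asarray(wrap_phase(q), float)
        qq = q.copy()
        qq[qq < ph_u[0] - 1e-12] += 1.0
        out = np.empty_like(qq)
        for lo, hi, f, const in pieces:
            m = (qq >= lo - 1e-12) & (qq <= hi + 1e-12)
            out[m] = const if f is None else f(qq[m])
        # between segment ends (the cut cells): snap to the nearer side
        done = np.zeros(qq.shape, bool)
        for lo, hi, f, const in pieces:
            done |= (qq >= lo - 1e-12) & (qq <= hi + 1e-12)
        if not np.all(done):
            rem = ~done
            ends = np.array([p[1] for p in pieces] + [ph_u[0] + 1.0])
            starts = np.array([p[0] for p in pieces] + [ph_u[0] + 1.0])
            for i in np.flatnonzero(rem):
                x = qq[i]
                prev_end = ends[ends <= x].max() if np.any(ends <= x) else ends[-1] - 1.0
                nxt = starts[starts >= x].min()
                take_prev = (x - prev_end) < (nxt - x)
                xe = prev_end if take_prev else (nxt if nxt <= ph_u[-1] else ph_u[0])
                for lo, hi, f, const in pieces:
                    if lo - 1e-9 <= wrap_phase(xe) <= hi + 1e-9 or lo - 1e-9 <= xe <= hi + 1e-9:
                        out[i] = const if f is None else float(f(np.clip(xe, lo, hi)))
                        break
        return out

    return ev, cut


def build_map(
    prc: FmPRC,
    f_clock: float,
    *,
    n_grid: int = 4096,
    which: str = "converged",
    disc_jump: float = 0.2,
    meta: dict | None = None,
) -> PhaseMapTab:
    """Construct the one-clock-cycle return map from a measured fmPRC.

    Parameters
    ----------
    prc : FmPRC
        Must cover the full cycle (no gaps wider than 2 grid steps).
    f_clock : float
        Clock frequency in Hz (the PRC's period ``T`` is in ms).
    which : {"converged", "first"}
        PRC readout variant entering the map.
    disc_jump : float
        Jump in dphi between adjacent PRC nodes flagged as a
        discontinuity (never interpolated across).
    """
    if f_clock <= 0:
        raise ValueError("f_clock must be > 0")
    T = prc.T
    T_c = 1000.0 / f_clock
    f_nat = 1000.0 / T
    ph, y, cut, disc_mid = _prc_segments(prc, which, disc_jump)
    ev, _ = _prc_evaluator(ph, y, cut)

    grid = np.arange(n_grid) / n_grid
    phi = wrap_phase(grid * T_c / T)
    G = grid + 1.0 - T * (1.0 - ev(phi)) / T_c

    # PRC discontinuities mapped into Phi (phi = wrap(Phi*T_c/T))
    dd = []
    jump_size = []
    dy = np.diff(np.r_[y, y[0]])
    for pm, js in zip(disc_mid, np.abs(dy[cut])):
        for k in range(-3, 4):
            x = (pm + k) * T / T_c
            if 0.0 <= x < 1.0:
                dd.append(x)
                jump_size.append(js)
    # periodic seam
    seam = abs((G[0] + 1.0) - (G[-1] + (G[1] - G[0]))) if n_grid > 1 else 0.0
    if abs(G[0] + 1.0 - 2 * G[-1] + G[-2]) > 5.0 * disc_jump / n_grid and seam > disc_jump * 0.5:
        dd.append(0.0)
        jump_size.append(seam)
    order = np.argsort(dd)
    dd = np.asarray(dd)[order]
    jump_size = np.asarray(jump_size)[order]
    main = float(dd[np.argmax(jump_size)]) if len(dd) else None
    return PhaseMapTab(
        grid=grid,
        G=G,
        T_nat=T,
        T_clock=T_c,
        delta_f=f_clock - f_nat,
        discontinuities=dd,
        main_discontinuity=main,
        meta=meta or {},
    )


def iterate_map(
    tab: PhaseMapTab,
    Phi0: float,
    n_transient: int = 512,
    n_keep: int = 4096,
) -> np.ndarray:
    """Orbit sample (wrapped into [0, 1)) after discarding the transient."""
    x = float(Phi0)
    gx = np.r_[tab.grid, 1.0]
    gy = np.r_[tab.G, tab.G[0] + 1.0]
    out = np.empty(n_keep)
    for k in range(n_transient + n_keep):
        x = float(np.interp(x % 1.0, gx, gy))
        if k >= n_transient:
            out[k - n_transient] = x % 1.0
    return out


def fixed_points(tab: PhaseMapTab, refine: bool = True):
    """Diagonal crossings with interpolated slope and stability.

    Returns a list of ``(Phi*, slope, stable)``; crossings inside a
    discontinuity cell are excluded.  An identity map returns an empty
    list (query :meth:`PhaseMapTab.is_identity` for the degenerate case).
    """
    if tab.is_identity():
        return []
    n = len(tab.grid)
    h = tab.G - tab.grid
    # nudge exact zeros so crossings on grid nodes register once
    h = np.where(h == 0.0, -1e-15, h)
    s = np.sign(h)
    out = []
    for i in np.flatnonzero(s[:-1] * s[1:] < 0):
        if len(tab.discontinuities) and np.min(
            np.abs(wrap_phase(tab.grid[i] - tab.discontinuities))
        ) < 2.0 / n:
            continue
        x0, x1 = tab.grid[i], tab.grid[i + 1]
        h0, h1 = h[i], h[i + 1]
        xs = x0 - h0 * (x1 - x0) / (h1 - h0) if refine else x0
        slope = (tab.G[i + 1] - tab.G[i]) / (x1 - x0)
        out.append((float(xs), float(slope), bool(abs(slope) < 1)))
    return out


def classify_orbit(orbit: np.ndarray, max_period: int = 64, tol: float = 1e-4) -> str:
    """Label an attractor sample: ``fixed point``, ``period-k`` or ``aperiodic``."""
    x = orbit[-max_period * 4:]
    for p in range(1, max_period + 1):
        d = np.abs(wrap_phase(x[p:] - x[:-p]))
        if np.max(d) < tol:
            return "fixed point" if p == 1 else f"period-{p}"
    return "aperiodic"


def _circular_hull_contains(orbit: np.ndarray, x: float) -> bool:
    """True if ``x`` lies inside the attractor's circular hull.

    The hull is the complement of the largest angular gap between
    consecutive orbit points on the circle.
    """
    pts = np.sort(np.unique(orbit % 1.0))
    if len(pts) == 1:
        return False
    gaps = np.diff(np.r_[pts, pts[0] + 1.0])
    g = int(np.argmax(gaps))
    lo = pts[g]
    hi = pts[(g + 1) % len(pts)]  # hull = [hi, lo] going through the rest
    rel_x = (x - hi) % 1.0
    rel_lo = (lo - hi) % 1.0
    return bool(0 < rel_x < rel_lo)


def _straddles(orbit: np.ndarray, d: float, window: float = 0.15) -> bool:
    rel = wrap_phase(orbit - d)
    return bool(
        np.any((rel > 1e-9) & (rel < window))
        and np.any((rel < -1e-9) & (rel > -window))
    )


def bifurcation_diagram(
    prc: FmPRC,
    detunings: np.ndarray,
    *,
    n_grid: int = 4096,
    n_transient: int = 512,
    n_keep: int = 4096,
    which: str = "converged",
    disc_jump: float = 0.2,
    straddle_window: float = 0.15,
    Phi0: float | None = None,
):
    """Attractor sample and regime label per detuning value.

    The orbit is continued across the detuning grid (each point starts
    from the previous attractor) so the diagram follows the branch that
    emerges from the entrained fixed point, as in a quasi-static sweep.

    Returns a pandas DataFrame with columns ``delta_f``, ``label``,
    ``orbit`` (array), ``straddle`` (points on both sides of the main map
    discontinuity), ``single_branch`` (attractor hull free of any
    discontinuity), ``n_fixed_points``.
    """
    import pandas as pd

    rows = []
    x = Phi0
    for df in np.asarray(detunings, float):
        f_clock = 1000.0 / prc.T + df
        tab = build_map(
            prc, f_clock, n_grid=n_grid, which=which, disc_jump=disc_jump
        )
        fps = fixed_points(tab)
        if x is None:
            stable = [p for p, s, st in fps if st]
            x = stable[0] if stable else (fps[0][0] if fps else 0.5)
        orbit = iterate_map(tab, x, n_transient, n_keep)
        x = orbit[-1]
        straddle = any(
            _straddles(orbit, d, straddle_window) for d in tab.discontinuities
        )
        single = not any(
            _circular_hull_contains(orbit, d) for d in tab.discontinuities
        ) and not straddle
        rows.append(
            dict(
                delta_f=df,
                label=classify_orbit(orbit),
                orbit=orbit,
                straddle=straddle,
                single_branch=single,
                n_fixed_points=len(fps),
            )
        )
    return pd.DataFrame(rows)


def first_straddling_detuning(bif) -> float | None:
    """Smallest detuning whose attractor straddles the map discontinuity."""
    hit = bif[bif["straddle"]]
    return None if hit.empty else float(hit["delta_f"].iloc[0])


def single_branch_upper_bound(bif) -> float | None:
    """Largest detuning below which the attractor stays on a single branch.

    Scans upward and returns the last detuning before the first point
    whose attractor leaves the branch of the (destabilized) fixed point.
    """
    ok = bif["single_branch"].to_numpy()
    if not ok[0]:
        return None
    idx = np.flatnonzero(~ok)
    stop = idx[0] if len(idx) else len(ok)
    return float(bif["delta_f"].iloc[stop - 1])
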