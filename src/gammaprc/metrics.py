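"""Rhythm descriptors: spike volleys, spectra, phase dispersion.

The collective rhythm's observable is the LFP (population mean voltage).
Its cycles appear in the raster as *spike volleys* — clusters of
near-simultaneous spikes separated by silent gaps.  Volleys are detected
by splitting the sorted spike times wherever the gap exceeds a fraction
of the expected period; the dominant frequency comes from a periodogram
of the mean-subtracted LFP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Volley",
    "VolleySeq",
    "SpectrumSummary",
    "detect_volleys",
    "lfp_spectrum",
    "phase_dispersion",
]


@dataclass(frozen=True)
class Volley:
    """One rhythm cycle's spike cluster."""

    t_first: float
    t_last: float
    count: int
    neurons: frozenset = field(repr=False)


class VolleySeq(list):
    """Ordered sequence of :class:`Volley`; behaves like a list."""

    @property
    def t_first(self) -> np.ndarray:
        return np.array([v.t_first for v in self])

    @property
    def t_last(self) -> np.ndarray:
        return np.array([v.t_last for v in self])

    @property
    def counts(self) -> np.ndarray:
        return np.array([v.count for v in self], dtype=int)

    def mean_period(self) -> float:
        if len(self) < 2:
            raise ValueError("need >= 2 volleys for a period")
        return float(np.mean(np.diff(self.t_first)))


@dataclass(frozen=True)
class SpectrumSummary:
    """Periodogram summary: grid, power, dominant frequency, local peaks."""

    freqs: np.ndarray
    power: np.ndarray
    f_dom: float | None
    peaks: np.ndarray  # (n_peaks, 2): frequency, power

    def peak_below(self, f_cut: float, margin: float = 1.0):
        """Strongest local peak strictly below ``f_cut - margin`` (Hz)."""
        sel = self.peaks[self.peaks[:, 0] < f_cut - margin]
        if len(sel) == 0:
            return None
        return tuple(sel[np.argmax(sel[:, 1])])

    def peak_above(self, f_cut: float, margin: float = 1.0):
        """Strongest local peak strictly above ``f_cut + margin`` (Hz)."""
        sel = self.peaks[self.peaks[:, 0] > f_cut + margin]
        if len(sel) == 0:
            return None
        return tuple(sel[np.argmax(sel[:, 1])])

    def power_at(self, f: float) -> float:
        """Power at the grid bin nearest ``f``."""
        return float(self.power[np.argmin(np.abs(self.freqs - f))])


def detect_volleys(
    spike_ids: np.ndarray,
    spike_times: np.ndarray,
    period_hint: float,
    gap_frac: float = 0.5,
) -> VolleySeq:
    """Group spikes into volleys by temporal gaps.

    A new volley starts wherever consecutive (time-sorted) spikes are
    separated by more than ``gap_frac * period_hint``.  A neuron spiking
    twice within a cycle contributes both spikes to the same volley;
    ``t_first`` uses the earliest.
    """
    if period_hint <= 0:
        raise ValueError("period_hint must be > 0")
    out = VolleySeq()
    if len(spike_times) == 0:
        return out
    order = np.argsort(spike_times, kind="stable")
    ts = np.asarray(spike_times, float)[order]
    ids = np.asarray(spike_ids)[order]
    gap = gap_frac * period_hint
    breaks = np.flatnonzero(np.diff(ts) > gap) + 1
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, len(ts)]):
        out.append(
            Volley(
                t_first=float(ts[lo]),
                t_last=float(ts[hi - 1]),
                count=hi - lo,
                neurons=frozenset(ids[lo:hi].tolist()),
            )
        )
    return out


def lfp_spectrum(
    lfp: np.ndarray,
    dt: float,
    transient: float = 500.0,
    prominence_frac: float = 0.01,
) -> SpectrumSummary:
    """Periodogram of the mean-subtracted LFP after transient removal.

    Parameters
    ----------
    lfp : array
        LFP samples at spacing ``dt`` (ms).
    dt : float
        Sample spacing in ms.
    transient : float
        Initial stretch (ms) discarded before the estimate.
    prominence_frac : float
        Relative prominence floor (fraction of max power) for the local
        peak table.

    A flat trace yields ``f_dom = None``.
    """
    n_skip = int(round(transient / dt))
    x = np.asarray(lfp, float)[n_skip:]
    if len(x) < 16:
        raise ValueError("trace too short after transient removal")
    x = x - x.mean()
    fs = 1000.0 / dt  # Hz
    freqs, power = signal.periodogram(x, fs=fs, window="hann")
    if not np.any(power > 0):
        return SpectrumSummary(freqs, power, None, np.empty((0, 2)))
    f_dom = float(freqs[np.argmax(power)])
    idx, _ = signal.find_peaks(power, prominence=prominence_frac * power.max())
    peaks = np.column_stack([freqs[idx], power[idx]])
    return SpectrumSummary(freqs, power, f_dom, peaks)


def phase_dispersion(volleys: VolleySeq, period: float) -> float:
    """Mean over cycles of (t_last - t_first)/T.

    Quantifies how spread out the spike volley is within the cycle;
    zero for a perfectly synchronous (homogeneous) network.
    """
    if len(volleys) < 3:
        raise ValueError("need >= 3 volleys")
    widths = volleys.t_last - volleys.t_first
    return float(np.mean(widths) / period)
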