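"""Heterogeneous tonic bias currents.

Neuronal heterogeneity is implemented as a per-neuron steady bias current
(or drive, for QIF neurons).  Two deterministic quantile constructions are
provided — Gaussian (for the IF networks, parameterised by mean and
coefficient of variation) and Lorentzian (for the QIF networks,
parameterised by center and half-width) — plus i.i.d. Gaussian draws used
when averaging over realisations of the subthreshold input to interneurons.

The quantile constructions place neuron ``i`` (1-based, of ``n``) at rank
fraction ``i/(n+1)`` of the distribution, so the generated vector is
deterministic, sorted ascending and symmetric about its center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfinv

__all__ = [
    "GaussianHeterogeneity",
    "LorentzianHeterogeneity",
    "gaussian_bias_quantiles",
    "lorentzian_bias_quantiles",
    "gaussian_bias_sample",
]


@dataclass(frozen=True)
class GaussianHeterogeneity:
    """Gaussian-quantile bias description.

    Parameters
    ----------
    mean_current : float
        Mean bias current (pA).  Must be positive: the model's tonic
        drive is excitatory.
    cv : float
        Coefficient of variation (std/mean), dimensionless, >= 0.
    n : int
        Number of neurons.
    """

    mean_current: float
    cv: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.mean_current <= 0:
            raise ValueError("mean_current must be > 0")


@dataclass(frozen=True)
class LorentzianHeterogeneity:
    """Lorentzian-quantile drive description (center, half-width, count)."""

    center: float
    half_width: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")


def gaussian_bias_quantiles(h: GaussianHeterogeneity) -> np.ndarray:
    """Deterministic Gaussian-quantile bias currents.

    Entry ``i`` (1-based) is ``mean * (1 + sqrt(2)*cv*erfinv(-1 + 2i/(n+1)))``,
    i.e. the Gaussian quantile at rank fraction ``i/(n+1)``.  The result is
    ascending and its mean equals ``mean_current`` exactly by symmetry.

    Raises
    ------
    ValueError
        If the heterogeneity is so large that some currents are negative
        (negative tonic excitation is outside the model's regime).
    """
    i = np.arange(1, h.n + 1, dtype=float)
    z = np.sqrt(2.0) * erfinv(-1.0 + 2.0 * i / (1.0 + h.n))
    out = h.mean_current * (1.0 + h.cv * z)
    if np.any(out < 0) or not np.all(np.isfinite(out)):
        raise ValueError(
            "negative bias current: cv too large for the given mean"
        )
    return out


def lorentzian_bias_quantiles(h: LorentzianHeterogeneity) -> np.ndarray:
    """Deterministic Lorentzian-quantile drives.

    Entry ``i`` (1-based) is ``center + half_width*tan(pi*(i/(n+1) - 1/2))``.
    Strictly ascending; the heavy tails mean the extreme entries grow
    without bound as ``n`` grows at fixed half-width.
    """
    i = np.arange(1, h.n + 1, dtype=float)
    return h.center + h.half_width * np.tan(np.pi * (i / (1.0 + h.n) - 0.5))


def gaussian_bias_sample(
    mean_current: float, cv: float, n: int, seed: int
) -> np.ndarray:
    """I.i.d. Gaussian bias draws, reproducible under a fixed seed.

    Negative draws (possible at large ``cv``) are rejected and redrawn:
    the bias current models tonic excitation.  Not sorted.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    out = rng.normal(mean_current, cv * mean_current, size=n)
    while np.any(out < 0):
        bad = out < 0
        out[bad] = rng.normal(mean_current, cv * mean_current, size=bad.sum())
    return out
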