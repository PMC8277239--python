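"""Network parameter containers and named presets.

The spiking models are all-to-all networks of leaky integrate-and-fire
(IF) or quadratic integrate-and-fire (QIF) neurons with delayed
double-exponential conductance (IF) or current (QIF) synapses.  Two
topologies are supported:

* ING — a single inhibitory population with I->I coupling;
* PING — an excitatory and an inhibitory population with E->I and I->E
  coupling only (no E->E, no I->I).

Named presets ship the standard parameter sets for each family
(``table1_ing``, ``table1_ping`` for the IF models; ``table2_ing``,
``table2_ping`` for the QIF models).

Units: IF networks use ms / mV / pA / nS.  QIF networks and their
mean-field reduction use the dimensionless units of the model (time in
units where the membrane time constant is 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .heterogeneity import (
    GaussianHeterogeneity,
    LorentzianHeterogeneity,
    gaussian_bias_quantiles,
    lorentzian_bias_quantiles,
)

__all__ = [
    "IFNeuronParams",
    "QIFNeuronParams",
    "SynapseParams",
    "Population",
    "ConnectionBlock",
    "NetworkSpec",
    "table1_ing",
    "table1_ping",
    "table2_ing",
    "table2_ping",
]


@dataclass(frozen=True)
class IFNeuronParams:
    """Leaky IF membrane: tau (ms), resting/threshold/reset voltages (mV)."""

    tau: float
    V_rest: float
    V_peak: float
    V_reset: float

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_peak:
            raise ValueError("V_reset must be below V_peak")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class QIFNeuronParams:
    """QIF membrane: tau dV/dt = eta + V^2 + I, with finite truncation.

    The spiking simulation truncates the divergence at ``V_peak`` (+500)
    and resets to ``V_reset`` (-500); the mean-field reduction takes both
    to infinity.
    """

    tau: float
    V_peak: float = 500.0
    V_reset: float = -500.0

    def __post_init__(self) -> None:
        if not self.V_reset < 0 < self.V_peak:
            raise ValueError("require V_reset < 0 < V_peak")


@dataclass(frozen=True)
class SynapseParams:
    """Delayed double-exponential synapse.

    ``tau1 < tau2`` are the rise/decay constants, ``tau_d`` the explicit
    delay, ``V_rev`` the reversal potential (ignored by current-based QIF
    synapses), ``W`` the dimensionless weight per presynaptic spike and
    ``g`` the conductance scale (nS; cancels for within-network currents
    but converts external currents in pA to voltage units).
    """

    tau1: float
    tau2: float
    tau_d: float
    V_rev: float
    W: float
    g: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau2 > self.tau1 > 0):
            raise ValueError("require tau2 > tau1 > 0")
        if self.tau_d < 0:
            raise ValueError("tau_d must be >= 0")
        if self.W < 0:
            raise ValueError("W must be >= 0")


@dataclass(frozen=True)
class Population:
    """One neuron population: membrane params, bias drive and conductances.

    ``bias`` is the per-neuron tonic bias vector (pA for IF, dimensionless
    eta for QIF); ``g_bias``/``g_ext`` convert bias/external currents to
    voltage units for the IF family.
    """

    name: str
    neuron: IFNeuronParams | QIFNeuronParams
    bias: np.ndarray
    g_bias: float = 1.0
    g_ext: float = 1.0

    @property
    def n(self) -> int:
        return len(self.bias)


@dataclass(frozen=True)
class ConnectionBlock:
    """All-to-all synaptic block from ``source`` to ``target`` population."""

    source: str
    target: str
    syn: SynapseParams


@dataclass(frozen=True)
class NetworkSpec:
    """Full network description (populations + all-to-all blocks)."""

    family: str  # "IF" | "QIF"
    populations: tuple[Population, ...]
    blocks: tuple[ConnectionBlock, ...]

    def __post_init__(self) -> None:
        if self.family not in ("IF", "QIF"):
            raise ValueError("family must be 'IF' or 'QIF'")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for b in self.blocks:
            if b.source not in names or b.target not in names:
                raise ValueError(f"block {b.source}->{b.target}: unknown population")

    def pop(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def with_bias(self, name: str, bias: np.ndarray) -> "NetworkSpec":
        pops = tuple(
            replace(p, bias=np.asarray(bias, float)) if p.name == name else p
            for p in self.populations
        )
        return replace(self, populations=pops)


# ---------------------------------------------------------------------------
# Presets

#: Inhibitory synapse kinetics of the IF models (ms / mV).
_IF_SYN_I = dict(tau1=0.5, tau2=5.0, V_rev=-70.0)
#: Excitatory synapse kinetics of the IF models.
_IF_SYN_E = dict(tau1=0.5, tau2=2.0, V_rev=0.0)


def table1_ing(
    n: int = 500,
    mean_current: float = 20.4,
    cv: float = 0.15,
    *,
    W: float = 3e-2,
    tau_d: float = 3.0,
    tau1: float | None = None,
) -> NetworkSpec:
    """Standard IF ING network: 500 all-to-all coupled I-cells.

    Membrane: tau 20 ms, rest -55 mV, threshold -50 mV, reset -60 mV.
    I->I synapse: rise 0.5 ms, decay 5 ms, delay 3 ms, reversal -70 mV,
    weight 3e-2 through 4 nS.  Bias currents are Gaussian quantiles with
    the given mean (pA) and CV through g_bias = 0.3 nS.
    """
    neuron = IFNeuronParams(tau=20.0, V_rest=-55.0, V_peak=-50.0, V_reset=-60.0)
    bias = gaussian_bias_quantiles(GaussianHeterogeneity(mean_current, cv, n))
    syn_kw = dict(_IF_SYN_I)
    if tau1 is not None:
        syn_kw["tau1"] = tau1
    syn = SynapseParams(tau_d=tau_d, W=W, g=4.0, **syn_kw)
    pop = Population("I", neuron, bias, g_bias=0.3, g_ext=4.0)
    return NetworkSpec("IF", (pop,), (ConnectionBlock("I", "I", syn),))


def table1_ping(
    mean_current_e: float = 4.0,
    cv_e: float = 0.1,
    *,
    n_e: int = 800,
    n_i: int = 200,
    mean_current_i: float = 3.6,
    cv_i: float = 0.167,
    i_bias_seed: int | None = 0,
    tau_d: float = 1.0,
) -> NetworkSpec:
    """Standard IF PING network: 800 E-cells, 200 I-cells, E->I and I->E.

    E membrane tau 20 ms, I membrane tau 10 ms; rest -70 mV, threshold
    -52 mV, reset -59 mV; synaptic delay 1 ms.  E-cell biases are Gaussian
    quantiles (mean/CV given); I-cell biases are random Gaussian draws
    (subthreshold on their own) unless ``i_bias_seed`` is None, in which
    case they are quantiles too.
    """
    from .heterogeneity import gaussian_bias_sample

    e_neuron = IFNeuronParams(tau=20.0, V_rest=-70.0, V_peak=-52.0, V_reset=-59.0)
    i_neuron = IFNeuronParams(tau=10.0, V_rest=-70.0, V_peak=-52.0, V_reset=-59.0)
    e_bias = gaussian_bias_quantiles(GaussianHeterogeneity(mean_current_e, cv_e, n_e))
    if i_bias_seed is None:
        i_bias = gaussian_bias_quantiles(
            GaussianHeterogeneity(mean_current_i, cv_i, n_i)
        )
    else:
        i_bias = gaussian_bias_sample(mean_current_i, cv_i, n_i, i_bias_seed)
    e_pop = Population("E", e_neuron, e_bias, g_bias=0.19, g_ext=0.19)
    i_pop = Population("I", i_neuron, i_bias, g_bias=0.3, g_ext=0.3)
    e_to_i = ConnectionBlock(
        "E", "I", SynapseParams(tau_d=tau_d, W=1.5e-3, g=0.3, **_IF_SYN_E)
    )
    i_to_e = ConnectionBlock(
        "I", "E", SynapseParams(tau_d=tau_d, W=4.5e-3, g=2.5, **_IF_SYN_I)
    )
    return NetworkSpec("IF", (e_pop, i_pop), (e_to_i, i_to_e))


def table2_ing(
    n: int = 5000,
    eta_bar: float = 20.0,
    delta: float = 3.0,
    *,
    J: float = 15.0,
    tau1: float = 0.98,
    tau2: float = 1.0,
) -> NetworkSpec:
    """QIF ING spiking network with Lorentzian-quantile drives.

    Membrane time constant 10, truncation +-500, J_II = 15, synaptic rise
    0.98 / decay 1.0, no explicit delay (the double-exponential provides
    the effective delay).
    """
    neuron = QIFNeuronParams(tau=10.0)
    bias = lorentzian_bias_quantiles(LorentzianHeterogeneity(eta_bar, delta, n))
    syn = SynapseParams(tau1=tau1, tau2=tau2, tau_d=0.0, V_rev=0.0, W=J)
    pop = Population("I", neuron, bias)
    return NetworkSpec("QIF", (pop,), (ConnectionBlock("I", "I", syn),))


def table2_ping(
    n_e: int = 5000,
    n_i: int = 5000,
    delta_e: float = 1.0,
    delta_i: float = 1.0,
    *,
    eta_bar_e: float = 5.0,
    eta_bar_i: float = -5.0,
    J_EI: float = 15.0,
    J_IE: float = 15.0,
    tau1: float = 0.98,
    tau2: float = 1.0,
) -> NetworkSpec:
    """QIF PING spiking network (E->I excitation, I->E inhibition)."""
    e_neuron = QIFNeuronParams(tau=10.0)
    i_neuron = QIFNeuronParams(tau=10.0)
    e_bias = lorentzian_bias_quantiles(LorentzianHeterogeneity(eta_bar_e, delta_e, n_e))
    i_bias = lorentzian_bias_quantiles(LorentzianHeterogeneity(eta_bar_i, delta_i, n_i))
    # s_EI: synapse onto E from I (inhibitory, strength J_EI);
    # s_IE: synapse onto I from E (excitatory, strength J_IE).
    onto_e = ConnectionBlock(
        "I", "E", SynapseParams(tau1=tau1, tau2=tau2, tau_d=0.0, V_rev=0.0, W=J_EI)
    )
    onto_i = ConnectionBlock(
        "E", "I", SynapseParams(tau1=tau1, tau2=tau2, tau_d=0.0, V_rev=0.0, W=J_IE)
    )
    return NetworkSpec(
        "QIF",
        (Population("E", e_neuron, e_bias), Population("I", i_neuron, i_bias)),
        (onto_e, onto_i),
    )
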