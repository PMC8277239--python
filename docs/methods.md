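# Methods

## Models

### IF networks (ING and PING)

Leaky integrate-and-fire membranes,

    tau dV_i/dt = -(V_i - V_rest) + I_syn/g_syn + I_ext/g_ext + I_bias/g_bias,

with reset `V_peak -> V_reset` on threshold crossing.  Synapses are
delayed double-exponential conductances: each presynaptic spike at `t*`
jumps two exponential states `A1, A2` (rise `tau1`, decay `tau2`) by the
weight `W` after the delay `tau_d`, and the current into target `i` is

    I_ij = g_syn * tau_m/(tau2 - tau1) * (A2 - A1) * (V_rev - V_i).

The `tau_m/(tau2 - tau1)` normalization makes the time integral of the
conductance per spike equal `W * tau_m`, i.e. independent of the synaptic
time constants; a spike of weight `W` then moves the target by roughly
`W * (V_rev - V)` regardless of membrane speed.  All synapses of a block
are equally strong, so the summed drive onto every target is a single
filtered population spike train — the simulator keeps one `(A1, A2)`
pair per block, which is exact, not an approximation (verified against
a per-pair reference in the tests).

The ING configuration is one all-to-all inhibitory population
(`N = 500`, `tau = 20 ms`, rest −55 mV, threshold −50 mV, reset −60 mV,
`tau1 = 0.5`, `tau2 = 5 ms`, `tau_d = 3 ms`, `V_rev = −70 mV`,
`W = 3e−2` through 4 nS).  The PING configuration is 800 E-cells and 200
I-cells with E→I and I→E blocks only (`tau_d = 1 ms`; E→I `W = 1.5e−3`
through 0.3 nS, I→E `W = 4.5e−3` through 2.5 nS; rest −70, threshold
−52, reset −59 mV).  Heterogeneity enters as per-neuron tonic bias
currents: deterministic Gaussian quantiles
`I_i = I(1 + sqrt(2)·CV·erfinv(−1 + 2i/(N+1)))` (sorted, mean exactly
`I`), or seeded i.i.d. draws (PING I-cells, subthreshold on their own,
mean 3.6 pA, CV 0.167).  Negative random draws are rejected and redrawn:
the bias models tonic excitation.

### QIF networks and their exact mean-field reduction

Quadratic membranes `tau dV/dt = eta_i + V^2 + I` truncated at ±500, with
Lorentzian-quantile drives `eta_i = eta_bar + Delta·tan(pi(i/(N+1) − ½))`.
In the infinite-network limit each population reduces exactly to

    tau r' = Delta/(pi tau) + 2 r V
    tau V' = V^2 + eta_bar + I - (pi tau r)^2,

with current-based synapses `I = ∓ tau·s`, `s = s2 − s1`,
`s_k' = −s_k/tau_k + J r/(tau2 − tau1)`.  The `1/(tau2 − tau1)`
normalization mirrors the IF convention (unit-area kernel); with
`tau1 = 0.98`, `tau2 = 1` the kernel is a sharp pulse peaking about one
time unit after the spike — an *effective* synaptic delay with no
explicit latency, which is what makes the collective phase response
type-II even in the infinitesimal limit.  Without this normalization the
effective coupling would be `J(tau2 − tau1) = 0.3` and the standard ING
operating point (`tau = 10`, `eta_bar = 20`, `J = 15`, `Delta = 3`) has a
linearly stable fixed point instead of the intended limit cycle
(period ≈ 9.85); the spiking QIF network uses the matching per-spike
jump `J/(N(tau2 − tau1))`.

## Measurements

**Rhythm metrics.**  The LFP is the population mean voltage, recorded
every 0.05 ms.  Spike volleys are clusters separated by gaps above half
the expected period; the natural frequency is taken from the mean
inter-volley interval (equal to the periodogram peak within one bin for
a clean rhythm, with far better resolution), while reported dominant
frequencies use a Hann periodogram of ≥ 2 s of post-transient LFP
(resolution ≤ 0.5 Hz).  Frequency calibration bisects the mean input on
the single-spike-per-cycle branch (default bracket 8–26 pA; above
~26 pA every neuron fires twice per volley and f(I) folds back).

**fmPRC.**  The network settles for 500 ms; one pulse is delivered at
phase `phi ∈ [−0.5, 0.5)` of a reference cycle (`phi = 0` at the first
spike of the volley, or at the peak of the synaptic variable for QIF
networks whose Lorentzian tails keep some neurons firing incessantly).
Perturbed and unperturbed runs share the integrator state up to the
pulse.  The shift `Δφ = (t_ref^unpert − t_ref^pert)/T`, wrapped into
[−0.5, 0.5) with nearest-in-time volley correspondence, is recorded at
readout cycles m = 1…8; because the perturbation transiently changes the
volley composition, the persistent shift is reported at m = 5 with a
convergence flag (|Δφ_5 − Δφ_4| < 0.002).  Phases where the perturbed
network shows no volley within 3T are marked invalid.  PING responses
are averaged over seeded redraws of the I-cell biases (default 50).

**Iterated map.**  With one forcing pulse per clock cycle, the phase
`Phi_n = (t_clock(n) + tau_d − t_first(n))/T_clock` obeys
`G(Phi) = Phi + 1 − T(1 − Δφ(phi(Phi)))/T_clock`,
`phi(Phi) = wrap(Phi·T_clock/T)`.  Jumps of the measured PRC larger than
0.2 between adjacent grid nodes (volley suppression slipping the cycle
correspondence) are treated as discontinuities: interpolation is
monotone piecewise-cubic within continuous segments and never across a
cut, and the cut positions are carried into the map.  Attractors are
classified from 4096 kept iterates (periods up to 64 by recurrence
within 1e−4, else aperiodic); a diagram point *straddles* a
discontinuity if the orbit has points within 0.15 on both sides of it,
and is *single-branch* if its circular hull contains no discontinuity.
The detuning enters only through `T_clock`; the PRC and `T` are held
fixed across the sweep, and the orbit is continued from the previous
detuning (quasi-static sweep).

**Clock forcing.**  The periodic input is a synthesized train of
double-exponential conductance events, proven identical (tested) to the
output of a perfectly synchronous homogeneous network with the same
summed weight per volley.  The per-volley total weight of the ING clock
is an explicit parameter, default 0.7: with the inhibitory kinetics
above this places the forcing in the regime that exhibits the full
bifurcation phenomenology — an entrained fixed point at small detuning,
a period-doubling cascade with periodic windows, and
discontinuity-straddling attractors beyond it — while weights an order
of magnitude larger silence the forced network at moderate positive
detuning and weights below ~0.1 cannot entrain beyond a fraction of a
hertz.  Within the admissible range (≈ 0.65–0.72) the two bifurcation
boundaries sit on a plateau (≈ 7.5 and 7.6 Hz for the CV = 0.1, 44 Hz
network), so their values are not sensitive to this choice.  The PING
clock uses the per-synapse strength 3e−4 summed over an 800-cell clock
E-population (0.24 per volley).

**Entrainment classification.**  `Phi(n)` is assigned per clock cycle
from the volley nearest the delayed clock event within half a cycle
(sentinel 2 for silent cycles; the centered window avoids spurious
silent cycles when a locked volley jitters around the cycle boundary).
Types: 1 — dominant LFP frequency ≠ clock frequency (more than 1.5
bins); 2 — equal, but a subharmonic peak holds ≥ 2 % of the clock-bin
power; 3 — equal with no subharmonic response.  var(Phi) excludes silent
cycles; the silent fraction is reported separately.

**Adjoint imPRC.**  On a stable limit cycle (found by settling, a
Poincaré section on the rising synaptic variable, and period refinement;
anchor at the interpolated `s`-peak) the adjoint system
`Z' = −Df(x(t))ᵀZ` is integrated backward with per-period
renormalization until periodic (LSODA, rtol 1e−9), then renormalized
pointwise so ⟨Z, f(x)⟩ = 1/T at every output phase (machine-exact by
construction; the convergence of the backward iteration is the accuracy
limit).  Finite perturbations deflect the mean voltage by `dV` via a
square current `dV·tau/0.02` over 0.02 time units (an instantaneous
increment is available) and read the asymptotic shift from late
`s`-peaks.  Regime maps label each parameter point oscillatory /
stationary (Hopf side, cross-checked against the fixed-point Jacobian
spectrum) / divergent (|state| > 1e4).

## Synthetic data and what passing tests show

All inputs are generated: quantile bias vectors, seeded Gaussian draws
and synthetic clock trains.  The generators emulate static, unimodal
heterogeneity and perfectly periodic forcing; they do not emulate
synaptic or channel noise, conductance heterogeneity, sparse or
distance-dependent connectivity, or drifting clock phase.  Passing tests
therefore certify the mechanism — dispersion of spike times plus delayed
self-inhibition producing a paradoxical, entrainment-widening phase
response — in the idealized all-to-all setting, not quantitative
predictions for biological tissue.

## Numerical choices

Fixed-step exponential-Euler for the IF voltage (the conductances are
frozen over one step, making the update exact for the linear membrane),
explicit Euler for QIF; default `dt = 0.01 ms` (IF; pulses of 0.1 ms
stay resolved) and `0.001` (QIF).  Threshold crossings are located by
linear interpolation inside the step and the delayed synaptic jump is
pre-decayed from the interpolated arrival to the next step boundary, so
the exponential states remain exact.  Spike-time convergence: halving
`dt` moves volley times by < 0.1 ms.  Mean-field integration uses LSODA
(rtol 1e−9..1e−10); pulse windows are integrated separately with a
bounded step.  Map evaluation uses a 4096-node tabulation with linear
interpolation (discontinuity cells snap to the nearer side).

Desk-scale problem sizes, chosen as sensible defaults for interactive
work: ING N = 500, QIF spiking N = 2000 (vs 5000 for the full-scale
runs), PING realization averaging 50 (configurable to 500), entrainment
diagrams on coarse CV×detuning grids with 4 s runs, QIF fmPRCs on 8–16
phases.  The `scale` field of experiment configs switches grid
densities only, never model equations.

## Known limitations

* The multi-spike onset (double spikes within one cycle) is a race
  between the fastest neuron's recovery and the ~3 ms inhibition
  latency; its threshold CV is sensitive at the ~0.2 ms level.  Under
  recalibration to a fixed 40 Hz the onset does not occur at all here
  (the calibrated drive falls as CV rises); at the fixed 40 Hz-scale
  input (15.8 pA) it is sharp at CV = 0.085 on a 0.005 grid.
* At QIF N = 2000 the spiking fmPRC carries a finite-size systematic of
  ~15–20 % of its peak relative to the mean-field curve (shape
  correlation ≈ 0.97); readouts beyond ~5 cycles decohere because the
  microscopic dynamics are chaotic.
* The iterated-map boundary detunings inherit the clock-weight
  convention discussed above; their plateau values (≈ 7.5 / 7.6 Hz) are
  robust within the admissible forcing range but shift with the PRC's
  bump amplitude.
* No refractory compensation for the QIF flight time above the ±500
  truncation; no finite-size corrections in the mean-field theory.
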