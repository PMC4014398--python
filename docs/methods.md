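# Methods

## The model

`axonoise` simulates action potentials (APs) travelling along thin
unmyelinated axons in which voltage-gated ion channels gate *stochastically*,
and propagates the resulting AP waveform variability through a presynaptic
transduction cascade to predict the variability of synaptic responses.

An axon is a uniform cylindrical cable of diameter *d* (µm) discretized into
compartments of length Δx, with membrane capacitance *C_m* (µF/cm²), axial
resistivity *R_a* (Ω·cm) and an ohmic leak *g_L* (mS/cm²).  Each compartment
carries integer populations of Na⁺ and K⁺ channels drawn from areal densities
(channels/µm², rounded to the nearest integer per compartment); each channel
is a continuous-time Markov chain whose transition rates depend on the local
membrane potential.  The bundled schemes are:

* **Squid giant axon (6.3 °C)** — the classic m³h Na⁺ lattice (8 states,
  conducting state m3h1) and n⁴ K⁺ chain (5 states, conducting n4) with the
  original α/β rate functions; 20 pS single-channel conductance for both
  species, densities 60 and 18 µm⁻².
* **Rat hippocampal interneuron (35 °C)** — the canonical fast-spiking
  interneuron rate functions with temperature factor φ = 5 on the h and n
  gates; 15 pS / 23 µm⁻² Na⁺ (E = +55 mV), 14 pS / 6 µm⁻² K⁺ (E = −90 mV).
  The source model treats the activation gate m as instantaneous
  (m = m∞(V)), which a discrete Markov channel cannot be.  With the raw
  α_m/β_m used as finite rates the model cannot even propagate an AP (its
  space-clamped spike fails too, which we verified against an independent
  ODE integration).  We therefore apply the model's own temperature factor
  φ = 5 to the m rates as well (`wang_buzsaki_schemes(phi_m=...)`), which
  restores propagation and yields a distal AP of ≈ +21 mV peak and
  ≈ 0.76 ms half-width on the 0.2 µm axon — close to the reference
  waveform (93.7 mV rest-to-peak, 0.7 ms).
* **Patlak-squid and C-fibre (Nav1.8)** slots accept user-supplied schemes;
  their published rate constants live in the channel literature and are not
  reprinted here.  The presets carry their passive and density parameters.

All axons nominally rest at −65 mV.  A kinetic scheme with any window
current at −65 mV is inconsistent with an arbitrary printed leak reversal,
so presets by default *solve* the leak reversal so that −65 mV is a true
fixed point of the full membrane.  For the squid parameter set this
reproduces the classic −54.4 mV exactly, which is why we treat the tabulated
leak reversals as balance values rather than independent constants.  A
numeric `leak_reversal` override is available.

## Stochastic integration: the binomial algorithm

Channel populations are advanced per time step dt by drawing, for every
occupied state, the number of channels taking each outgoing transition from
a binomial distribution with probability rate·dt — sequentially over that
state's transitions from the remaining occupancy, so per-compartment channel
totals are conserved as an exact integer identity.  The deterministic mode
applies the same sequential-depletion flow to fractional occupancies and is
therefore exactly the ensemble mean of the stochastic update (and
bit-reproducible).  Both updates are first-order in dt; the stationary
distribution of the discrete map converges linearly in dt to the equilibrium
of the continuous chain (verified in the test suite).

Validity guard: a first-order transition probability requires the total
escape probability per state per step to stay well below 1.  The reference
`stochastic_step` refuses dt whenever any state's escape probability exceeds
0.5 at the requested voltage.  The compiled cable kernel enforces the same
0.5 bound per step at the *actual* compartment voltages, restricted to
occupied states (an empty state loses no channels); when a rare voltage
excursion pushes an occupied state past the bound, that state's update is
locally subdivided into equal substeps (up to 64, else a hard error) rather
than aborting a multi-second run.  Substepping only triggers for strongly
hyperpolarized compartments that still hold activated Na⁺ channels and has
no measurable cost in normal operation.

Rates are pre-tabulated on a 0.01 mV grid over [−130, +90] mV and linearly
interpolated; this agrees with direct evaluation to better than 1e-6
relative (tested) and keeps the inner loop free of transcendentals.

## Cable integration

Operator splitting per step: (1) channel update at the current voltages;
(2) implicit (backward-Euler) voltage update solving the tridiagonal system
that couples each compartment's capacitive, ionic, leak and stimulus
currents to its neighbours through the axial conductance
g_ax = (πd²/4)/(R_a·Δx); sealed (zero-flux) ends.  The implicit cable
update is unconditionally stable and satisfies per-step charge bookkeeping
exactly (C·ΔV/dt + I_ion + I_leak − I_stim = 0 to machine precision, which
the test suite asserts in a space-clamped configuration).  Compartment
lengths must satisfy Δx ≤ λ/10 where λ = √(R_m·d/4R_a) is the passive
length constant; violating specs are refused with the computed λ.
Numerical blow-up (|V| > 200 mV) aborts with a diagnostic.

**Grid sizes.** Desk-scale defaults are dt = 5 µs and Δx = 10 µm (squid) or
20 µm (interneuron protocols); halving either changes the deterministic AP
width and height by < 1 % (squid: < 0.2 %), which the suite verifies.  The
interneuron axon's λ is 267–378 µm depending on the leak, so Δx = 20 µm is
λ/13–λ/19.

## Stimulus protocols

* **Single spike per trial** — a 0.5 ms rectangular pulse at the proximal
  end, amplitude auto-tuned by bisection on the deterministic model to 1.5×
  the propagation threshold; every trial starts from the identical
  deterministically-rounded resting state and differs only in its RNG
  stream.  Trials without exactly one detected AP at every recorded site
  are excluded (counts reported).
* **Spike train** — zero-mean Gaussian white noise, first-order low-pass
  filtered at the −3 dB corner (default 1 kHz), scaled analytically so the
  stationary SD equals the request (default 0.01 nA); realized SD is within
  2 % over 10 s.  The run proceeds in chunks with a seamless noise stream
  and channel state; the first 200 ms are simulated but excluded from all
  statistics, and APs are collected between 5 % and 95 % of the axon length
  to avoid stimulus artefacts and boundary effects.  Passive properties for
  train runs follow the cortical-like setting R_a = 70 Ω·cm,
  R_m = 20 000 Ω·cm² (the single-AP protocol keeps the tabulated leak).

## Waveform analysis conventions

APs are detected with a threshold discriminator (default rest + 40 mV,
2 ms lockout) and aligned at the rising crossing of the half-height level,
defined relative to the nominal resting potential:
level = V_rest + ½(V_peak − V_rest).  Crossings are located by linear
interpolation between samples, giving sub-sample width resolution.  Width is
the interval between the rising and falling half-height crossings; height is
reported both as the absolute peak and as peak − V_rest (all ensemble
statistics use the rest-to-peak convention).  An alternative alignment
fraction (e.g. 20 % of amplitude) is available to check that variability
profiles are not alignment artefacts.  All ensemble statistics use the
population SD (ddof = 0); at the N ≥ 300 scales used here the distinction
from the sample SD is negligible, but the convention matters for the
three-point worked examples in the tests.

Variability profiles stack aligned waveforms on a common −1…+4 ms grid and
report mean, SD, the 3×SD envelope and 1–99 % quantile bands.  Pairwise
feature changes between two sites match APs by trial id (single-AP
protocol) or by propagation order within a 10 ms window (trains).  The
diameter-scaling fit is an ordinary least-squares line in log₁₀ CV vs
log₁₀ d; its slope is the scaling exponent.

## Presynaptic cascade

The presynaptic Ca²⁺ channel is a deterministic Hodgkin–Huxley conductance
with two identical gates (open probability m²), integrated under voltage
clamp by each arriving AP waveform with the calyx-of-Held rate functions
α_m = 1.78·e^{V/23.3} ms⁻¹, β_m = 0.14·e^{−V/15} ms⁻¹ and E_Ca = +45 mV
(all configurable; only the current's waveform is used, so the conductance
scale is irrelevant).  The local Ca²⁺ transient preserves the current's
rise time, lengthens its half-width by 100 µs by dilating time after the
peak, and maps amplitude affinely onto concentration over a 50 nM resting
level; a single AP is scaled to a 12 µM peak, while an ensemble shares one
gain chosen so the *mean* peak is 12 µM (per-AP amplitude variation
survives, as it must for the peak-[Ca²⁺] CV to be meaningful).

Vesicle fusion follows the allosteric five-site model: binding n→n+1 at
(5−n)·k_on·[Ca²⁺], unbinding n→n−1 at n·k_off·b^{n−1}, and release from
state n at l₊·fⁿ with f = 31.3 and l₊ = 2×10⁻⁴ s⁻¹; the side parameters
default to k_on = 1×10⁸ M⁻¹s⁻¹, k_off = 4000 s⁻¹, b = 0.5 from the source
allosteric-model literature.  The master equation is integrated with
forward-Euler substeps capped at 5 % transition probability and midpoint
quadrature of the Ca²⁺ drive; occupancies plus the released fraction sum to
1 to machine precision, and the trajectory agrees with an independent stiff
ODE solution to < 5×10⁻⁴ absolute.  Expected vesicles released is the
cumulative released fraction times a configurable pool size (default 2000);
all reported release CVs are pool-size invariant.  A second, direct route
maps AP width to EPSC amplitude through a configurable power law
(amplitude ∝ width^k), the exponent being an experimental quantity read
from cerebellar synapse data rather than a model output.

## What the simulations do and do not show

Channel gating is the *only* stochastic element: deterministic runs of the
same configurations produce bit-identical repeats with zero waveform SD, so
every CV reported by the stochastic protocols is attributable to channel
noise.  The model does not include stochastic Ca²⁺ channels, synaptic
vesicle-pool depletion, neurotransmitter diffusion, post-synaptic receptors,
branching or myelinated morphologies, or temperature gradients; reported
synaptic CVs are therefore lower bounds attributable to axonal noise alone.

Desk-scale problem sizes (chosen once, stated here as the package's own
defaults): spike trains run until ≥ 300 APs have arrived at the distal site
and at least 10 s have been analysed (cap 60 s), instead of 10-minute
trains; single-AP ensembles use 100–250 trials; the diameter-scaling study
uses 60 trials at d ∈ {0.2, 0.5, 1.0} µm on 2 mm axons.  At these sizes a
CV of a few percent carries a relative sampling error of roughly
1/√(2N) ≈ 4–7 %.

## Known limitations

* The interneuron firing rate under the 0.01 nA / 1 kHz noise drive comes
  out near 70–80 Hz, above the ≈ 41 Hz reference value.  The rate is an
  escape process governed by the distance between rest and threshold and is
  extremely sensitive to the Na⁺ activation kinetics; with the m-gate
  treated as a finite-rate Markov gate (φ_m = 5) rather than instantaneous,
  this distance differs from the source model's.  We report the rate as
  computed rather than tuning the printed stimulus parameters.
* The cascade's stage-wise CV pattern depends on the Ca²⁺-channel
  activation speed relative to the AP and on how far the sensor saturates
  at 12 µM; with the cited calyx rates (τ_m ≈ 0.5 ms at 0 mV) the peak
  Ca²⁺-current CV comes out above, and the released-count CV below, the
  reference pattern.  Both rate sets are exposed in configuration.
* The binomial algorithm is first-order in dt; statistics carry an O(dt)
  bias that the convergence tests bound at < 1 % for the default grids.
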