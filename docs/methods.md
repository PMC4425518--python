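# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Morphology and discretisation

A model dIN has four sections: a soma cylinder whose length equals its
diameter (17.84 μm, lateral area exactly 1000 μm² — the soma-plus-dendrite
area estimate; only the area matters because the section is isopotential),
two 5 μm hillock sections tapering linearly from 2.0 μm to the axon
diameter, and a 0.4 μm × 1500 μm axon. The hillock dimensions are not
constrained by any measurement; they are chosen small enough not to load
the soma and are configurable. The default axon length (1500 μm, within
the 280–2050 μm biological range) is long compared to the axon's passive
space constant (λ ≈ 224 μm at 0.25 mS/cm² leak, ≈ 316 μm at
0.125 mS/cm²), so none of the reported quantities is sensitive to it —
the suite checks λ against √(R_m·d/(4·R_i)) to < 2 %.

Compartment lengths: 5 μm through the hillock and the first 400 μm of
axon, 100 μm beyond. Halving every bin changes the somatic input
resistance by < 1 % (tested). Arc distance is measured from the soma;
the rostrocaudal coordinate of neuron *i*'s compartment is
`10·i + arc`. Intracellular resistivity R_i = 80 Ω·cm and specific
capacitance 1 μF/cm² set the axial conductances and compartment
capacitances.

## Membrane currents

Leak (e = −52 mV), Na (m³h, e = +50 mV), fast K (n⁴) and slow K (n²)
(e = −81.5 mV) are Hodgkin–Huxley-type with rates
(A + B·V)/(C + exp((D + V)/E)); the calcium current uses the
Goldman–Hodgkin–Katz constant-field flux with an m² gate and a
permeability of 0.016 cm/s. Parameters ship in
`src/axonet/data/channels.yaml`; two details deserve note:

* **Sodium activation sign.** The opening-rate parameter E for m is
  stored as −12.56 mV. The positive value sometimes quoted for this
  kinetic set puts ~70 % of Na activation gates open at rest, which is
  inconsistent with a stable resting potential and with every phenotype
  of the cell; the negative sign gives the standard sigmoidal activation
  curve rising with depolarisation.
* **Slow-K opening rate.** Its linear numerator crosses zero a few mV
  below rest and goes negligibly negative (~1e−4 ms⁻¹). Physical
  transition rates are non-negative, so gate evaluation clips rates at
  zero; the raw rate function is left unclipped.

**GHK orientation and scale.** The flux expression as usually printed
gives a hyperpolarising value at depolarised potentials when external
calcium dominates; a leading sign flip orients it as an inward
(depolarising) current, consistent with the i = g(e − V) convention of
the other currents. The current constrains only the products
P·[Ca]ᵢ and P·[Ca]ₒ, and the concentrations are not independently fixed
by the voltage-clamp literature behind the kinetics. Pairing the quoted
permeability with millimolar external calcium produces a resting calcium
current two orders of magnitude larger than the leak and no stable
resting state, so the default external concentration is an *effective*
value, [Ca]ₒ = 1e−5 mol/L (internal 100 nM), calibrated once so that the
calcium current plays its observed roles — broadening spikes, supporting
rebound, and producing depolarisation block at strong drive — while rest
stays near −52 mV. Both concentrations are configurable; all calcium
behaviour should be read as conditional on this calibration.

The υ = 0 singularity of the GHK flux is removable and handled
analytically (continuity at 0 mV is verified to 1e−6 relative).

## Densities, noise, and the initial segment

Realised densities are ḡ_x · M_x · N(1.0, 0.05), one normal draw per
neuron, per channel, per realisation (negative draws clamp to zero).
The chosen multipliers are Na ×3 and ×1 elsewhere; the sweep grids for
all channels are in the registry. The final model raises Na ×5 and
lowers both K densities ×0.5 in the axon initial segment, 20–70 μm from
the soma (the K factor is not fixed by any measurement; 0.5 is the
package default and configurable). The final coupled model uses
g_lk = 0.125 mS/cm² — half the uniform passive value — offsetting the
junctional load on input resistance.

## Gap-junction layout

The density scheme walks 1 μm bins over [0, 50) μm of each neuron's
cable; per bin it samples up to six *more rostral* axons overlapping that
coordinate (six is the maximum number of equal cylinders that can touch
another at a point) uniformly without replacement, each forming a 600 MΩ
junction at the bin centre with probability 0.015. "More rostral" is the
reading consistent with the junction being on the caudal neuron's
proximal axon; it reproduces the published network statistics (mean
≈ 119 junctions per 30-neuron column, 5–8 contacts per axon, ≈ 23–25 %
of pairs directly coupled). Duplicate junctions between a pair in
different bins are allowed (independence across bins); the six-partner
cap is per bin, not per axon. A fixed-point variant (single Bernoulli
candidate at one arc distance) is provided for comparison; it clusters
junctions and is not the default.

## Numerics

The voltage system of each neuron is a chain, so the implicit step is a
tridiagonal solve; gap junctions add a rank-k coupling term.

* **Time stepping.** First-order implicit (backward Euler) in the
  voltage with staggered gate updates: gates relax exactly toward their
  steady state over each step (X ← X∞ + (X − X∞)·e^(−dt/τ), evaluated at
  the previous voltage), which keeps every gate in [0, 1] by
  construction. The GHK current, nonlinear in V, enters explicitly.
* **Junction coupling.** Two modes. `implicit` solves the full
  tridiagonal-plus-low-rank system exactly each step via the Woodbury
  identity. The default `semi` keeps each junction's conductance
  implicit on the diagonal but lags the partner voltage one step — an
  unconditionally stable splitting of the same first order as the
  backward-Euler step itself, severalfold faster on coupled networks.
  At dt = 0.02 ms the two agree on network spike times to < 0.1 ms
  (tested), and the splitting converges to the full solve as dt → 0.
* **Backends.** The production inner loop is a numba kernel using
  0.05 mV lookup tables for the gate steady states and relaxation
  factors (rebuilt per run for the chosen dt) and for the GHK flux; a
  pure-numpy loop with exact rate evaluation is the reference
  implementation, and the suite compares the two trajectories.
* **Steps.** dt = 0.01 ms is the library default; the measurement
  protocols use dt = 0.02 ms, at which somatic spike times are
  self-converged to well under 0.05 ms (halving-dt test), and
  dt = 0.05 ms for subthreshold (passive-regime) responses. Passive
  steady states are solved exactly (sparse LU), and the dynamic passive
  response is verified to converge to them.
* **Initial state.** V = e_lk everywhere, gates at steady state, then a
  20 ms settling period before any protocol.
* **Boundary and attachment conventions.** Sealed axon ends; junctions
  attach to the compartments containing their coordinate; spike
  detection is an upward 0 mV crossing with a 3 ms refractory.

## Measurement protocols

Coupling coefficients: constant −100 pA into a random source soma, exact
steady state, target deflection as % of source deflection (linearity and
sign-invariance are asserted, so the amplitude is immaterial); summaries
are distance-binned medians/quantiles. Input resistance: steady
deflection / current (exact solve in passive networks; for the active
model, a −100 pA, 200 ms step with the deflection read from the last
tenth of the step). Firing classification: somatic spike counts at 50,
100, 200, 300 pA × 200 ms; *single* means exactly one spike at every
suprathreshold level; *repetitive* more than one at some level;
*unstable* spikes outside the stimulus window. Rebound: −200 pA × 20 ms
riding on a depolarising background, rebound = spike within 20 ms of
pulse offset and no spike for the same pulse from rest; the background
defaults to rheobase + 30 pA because the junction-shunted rheobase
varies severalfold between realisations and a fixed background is
sub-threshold for many of them. Propagation: 400 pA × 2 ms somatic
pulse; probes at the soma, every 20 μm to 400 μm and every 100 μm to the
tip; success = spike at the most distal probe within 50 ms; conduction
velocity = slope of a distance-vs-arrival-time fit over 20–400 μm.
Population step: the same step into every soma; per-neuron frequency
from inter-spike intervals; synchrony = mean resultant length of spike
phases on the population-mean cycle (any monotone synchrony measure
would do; this one is bounded in [0, 1]).

## Sensory drive

A tIN fires n spikes at normalised skin-stimulus strength s with
p(N=1|S=95) = 0.5, p(N=1|S=100) = 1.0, and p(N=1|S>120) = 0.3,
piecewise-linear in between; sub-unity mass sits on 0 spikes below
threshold and on bursts of 2–5 spikes (weights 0.4/0.3/0.2/0.1) above
120 %. Spike k is drawn from N(5 + 10(k−1), 2²) ms and trains are
sorted. These timing and burst parameters are placeholders standing in
for unpublished distributions and are fully configurable; nothing
quantitative is claimed about them — the recruitment analysis only uses
the structure of the model (deterministic single spikes at s = 100,
graded mass below, bursts above). All 20 tINs contact every dIN with the
same difference-of-exponentials conductance (rise 1 ms, decay 5 ms,
reversal 0 mV); the per-spike peak conductance is calibrated at run time
(bisection) so the threshold stimulus just recruits the coupled
population, and the calibrated value is recorded in the experiment
manifest rather than hard-coded.

## What the generator does and does not emulate

Synthetic networks reproduce the column geometry, the stochastic
junction layout, and per-neuron density variability. They do not include
dendritic arbors, ascending axons, axo-dendritic or somatic junctions,
rectifying or voltage-gated junctions, stochastic channel gating, or
temperature effects — so passing tests show internal consistency of this
idealised column, not fidelity to every property of the biological
population.

## Known limitations

* With all printed passive parameters, the coupled somatic input
  resistance comes out near 200 MΩ (uncoupled ≈ 560 MΩ, coupling-induced
  drop ≈ 50 % at uniform leak). The published triple (≈300 / ≈600 /
  ≈50 %) cannot be met simultaneously by a fixed resistive junction
  network: the 50 % drop at the 0.25 mS/cm² leak fixes the junctional
  load, and that load does not halve when the leak halves. The model
  reports what the stated parameters give.
* The intrinsic conduction velocity of the 0.4 μm axon with these
  kinetics is ≈ 0.15–0.17 m/s (converged in dt and mesh). Junction
  removal speeds the proximal region by only ~15 %, so the coupled
  velocity matches the published ≈ 0.16 m/s but the uncoupled value
  falls well short of ≈ 0.32 m/s.
* The population current–frequency curve starts lower than published
  (~15–20 Hz at the population threshold rather than ~30 Hz) while its
  upper end (~75–80 Hz before failure) matches.
* Model action potentials are short, and all calcium-dependent behaviour
  is conditional on the effective-concentration calibration above.

## Scales used by the acceptance script

10 coupled network realisations for input resistance, rheobase and
velocity targets; 5 and 3 realisations for the population threshold and
maximum-frequency sweeps; 100 layouts for junction statistics; 20
instantiations (random stimulated neuron) for propagation success;
dt = 0.02 ms for active protocols and 0.05 ms for subthreshold
responses. These desk scales keep the full recomputation within a few
minutes on one core.
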