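# Methods

This note documents the model, the numerical methods, the shipped parameter
values, and the limits of what the package's tests demonstrate.

## Model

### Electrical cable and hotspot currents

The dendrite is a semi-infinite cylinder (diameter `d`, axial resistivity
`R_i`, membrane resistivity `R_m`, capacitance `C_m`) with space constant
`λ = sqrt(d R_m / 4 R_i)` and time constant `τ = R_m C_m`. Membrane
potential is expressed as the dimensionless deviation from rest,
`u = (V − E_r)/V_max`, on electrotonic coordinates `X = x/λ`, `T = t/τ`.
The leak equilibrium is defined to absorb the standing (rest) currents of
all channels, so `E_r` is the exact rest state; every hotspot drives the
cable with the *deviation* of its current from the resting value.

Ion channels sit in discrete clusters ("hotspots") that act as point
current sources. A cluster of `N` channels of single-channel conductance
`γ` carries `I = ε γ N̄ N m^p h^q (V − E)` (ohmic Hodgkin–Huxley driving
force; a Goldman–Hodgkin–Katz driving force can be plugged into the same
hook). Kinetics are Traub-style rate functions for Na/K channels and
steady-state/τ parameterizations for the T- and L-type calcium channels;
the T-type inactivation is set so the channel retains a window current
around rest (mid-point −72 mV, slope 5 mV), giving the low-voltage-activated
calcium entry that sustains distal transients. The back-propagating action
potential is a Dirichlet voltage clamp at `x = 0`: a sech² spike (100 mV,
1.2 ms width) followed by an after-depolarizing (ADP) tail (16 mV, 35 ms
decay), with an optional after-hyperpolarization term.

### Green's-function perturbation solver

With hotspots as Dirac sources the dimensionless cable equation becomes a
system of Volterra integral equations over the killed-end Green's function
`G(X,Y,T) = e^{−T}(4πT)^{−1/2}[e^{−(X−Y)²/4T} − e^{−(X+Y)²/4T}]`. The
solver evaluates a regular perturbation expansion truncated at first order:

* order 0: the clamp propagated inward by the boundary-flux kernel
  `−∂G/∂Y|_{Y=0}` (so `u(0,T)` equals the clamp exactly on grid nodes);
* order 1: gate variables integrated against the order-0 voltage at each
  hotspot (exponential/Rush–Larsen update, unconditionally stable), and the
  resulting currents convolved with `G`.

Higher orders are structured as an iteration hook but not implemented.

The time convolutions use a product-trapezoidal rule: the kernel is
integrated *exactly* over each panel (Gauss quadrature in the substitution
`t = v²`, which removes the Abel-type `1/√t` endpoint singularity) against a
piecewise-linear density. Kernels decay like `e^{−T}` and are truncated at
relative mass 1e−13; convolutions use FFT overlap-add. The default grid step
is `dT = 0.01` (0.1 ms at τ = 10 ms). At this step the passive solution
matches the closed-form Dirichlet step response to better than 1e−6 when
well resolved, and ~1e−4 relative sup-norm at the default step.

### Finite-difference oracle

An independent solver discretizes the untransformed system: Crank–Nicolson
in the diffusion/leak operators (banded solves), explicit channel currents,
an explicit buffer species with mass-action binding (subcycled to respect
its stability bound), and a saturating pump. Hotspot sources occupy one
cell scaled by `1/Δx`. The far boundary is clamped to rest at 10λ. The
passive problem converges at second order in `Δx`; with a discontinuous
step clamp the Crank–Nicolson start-up ringing is first-order in `Δt` and
is removed by Richardson extrapolation in the corresponding test. Against
this oracle the perturbation solver agrees to ~2e−4 (passive) and the
discrepancy of the active problem scales quadratically with hotspot
strength — at the shipped full densities it reaches tens of percent, which
is the expected truncation error of a first-order expansion; the windows
and protocol outcomes should be read as properties of the perturbative
model, not of the exact nonlinear cable.

### Calcium cable

Free calcium obeys a reaction–diffusion equation with a single buffer and a
high-affinity membrane pump. The rapid-buffer approximation (linearized at
rest, buffering factor `θ = B_T K_d/(K_d + Ca_rest)²`) reduces it to

    ∂c/∂t = D_eff ∂²c/∂x² − k_eff c + (1+θ)^{−1} Σ J(t) δ(x − x_s),
    D_eff = (D_Ca + D_B θ)/(1+θ),   k_eff = (4P_m/(d K_p))/(1+θ),

with chemical constants `λ_c = sqrt(D_eff/k_eff)` (~1 µm here) and
`τ_c = 1/k_eff` (~23 ms). Because `λ_c ≪ λ`, the calcium at a synapse is
dominated by its co-located sources; sites beyond 12 λ_c are skipped.
Calcium currents (T-type, L-type, NMDA calcium component with reversal
`E_Ca`) convert to concentration flux through `1/(2F·A)` with `A` the
cross-section. Note two deliberate modeling positions: (i) the
rest-linearized buffer is the model definition (following the framework
this package implements), although shipped-amplitude transients (~5 µM)
exceed the buffer's linear range — the oracle comparison of the reduction
is therefore performed in a small-amplitude configuration; (ii) mobile
buffering *lengthens* λ_c (it shields calcium from the pump while adding
transport); an immobile buffer leaves λ_c unchanged while stretching τ_c.

### Plasticity rule

`Ω(Ca) = 0.25 + sig(Ca − θ_p) − 0.25·sig(Ca − θ_d)` with slopes 80 and
thresholds θ_d = 0.35, θ_p = 0.55 on the normalized calcium axis, and
`η(Ca) = 1/(P₁/(P₂ + Ca^{P₃}) + P₄)` with P₁ = 0.1 s, P₂ = 1e−5, P₃ = 3,
P₄ = 1 s — the canonical calcium-control parameterization. Weights evolve
as `dW/dt = η(D)(Ω(D) − Ω₀ − λ_w W)`; the default `λ_w = 0` reduces to
per-pairing accumulation of `η(Ω − Ω₀)` (the baseline-referenced variant,
under which zero drive leaves the weight exactly unchanged).

## Drive variables and normalization conventions

The rule needs a scalar "calcium drive" per pairing. Two summaries of the
synaptic transient are supported:

* **normalized peak** — the transient's peak divided by a normalizer. For
  window scans the normalizer is the maximum raw peak of the scan at the
  *proximal reference* location, so windows at different distances share one
  scale (this is what makes distal potentiation smaller and distal
  depression broader). Parameter sweeps normalize each swept configuration
  to its own proximal scan, so global concentration scalings (for example
  the surface-to-volume factor when the diameter changes) cancel and only
  the spatial profile of calcium matters.
* **peak over integral (ratio)** — for pairing trains, each presynaptic
  cycle contributes the peak calcium within that cycle divided by the
  calcium integral over the cycle (a crest factor; the motivation is that
  receptor-trafficking outcomes integrate calcium over time, so the same
  event-locked peak counts for less on a high integrated background). The
  resulting per-cycle drive series is fed through the weight ODE. The scale
  is anchored so that the first causal pairing of a reference 2-Hz train
  sits just above θ_p (causal pairings potentiate at every frequency in the
  reference experiments); anchoring at a fixed reference frequency keeps
  results independent of the scanned grid.

## Shipped configuration

`ioniccable.default_config()` (also written out in
`examples/config_reference.yaml`): d = 1 µm, R_m = 10 kΩ·cm²,
R_i = 100 Ω·cm, C_m = 1 µF/cm² (λ = 500 µm, τ = 10 ms); densities
Na 30, K_DR 40, K_A 20, Ca_T 3, Ca_L 3 pS/µm² on a 50-µm hotspot grid;
synapse = 60 NMDA receptors (γ = 50 pS, rise 3 ms, biexponential decay
12 ms/110 ms with 65 % fast, Mg 1 mM, calcium fraction 0.1) plus
co-located clusters of 10 T-type and 10 L-type channels; probes at 50 µm
(X = 0.1, "proximal") and 300 µm (X = 0.6, "distal"). The free parameters
that the available literature leaves open (ADP size, NMDA decay mix,
synaptic cluster sizes, densities) were chosen once so that the proximal
normalized-peak window reproduces the reported phenomenology — a pre-post
depression band between roughly 40 and 100 ms and post-pre depression whose
fitted time constant grows with distance — and are not protocol-dependent.

## Known limitations

* First-order truncation: at full channel densities the perturbative
  voltage deviates substantially from the full nonlinear solution (the
  oracle comparison quantifies this); strong regenerative phenomena are
  outside the expansion's reach. Consequently a +50 % Na or T-type density
  step *translates* the distal depression band to larger lags rather than
  abolishing it within the scanned lag range.
* Pairing-frequency crossover: for repeated ±Δt pairings the −Δt train is
  structurally a +(period − Δt) train, so any drive built from the train's
  coincidence structure makes the two weight-change curves meet near
  period = 2|Δt| (50 Hz for Δt = 10 ms). The shipped model's curves cross
  at ~53 Hz; reported experimental crossovers near 40 Hz require biophysics
  outside this model (short-term plasticity, spike jitter, state-dependent
  receptor kinetics).
* The depression lobes never vanish identically: because the drive decays
  continuously to its floor, the Ω band is always traversed somewhere in
  the lag axis, with exponentially small weight changes in the tails.
* No branched morphology, spines, calcium stores, exchangers, multiple
  buffers, or an active somatic compartment; the clamp at `x = 0` replaces
  spike generation.
* The finite-difference oracle resolves the calcium cusp at a point source
  only when `Δx ≪ λ_c`; at the default grid it is a voltage oracle first
  and a small-amplitude calcium oracle on refined grids.

## What the tests do and do not show

The unit and property tests verify the mathematical structure exactly
(Green's-function identities, nondimensionalization round trips, gating
bounds, linearity in channel counts, the Ω/η sign structure under random
admissible parameterizations) and verify the solvers against independent
oracles (closed forms, quadrature, finite differences). The protocol-level
results (window shapes, distance dependence, frequency curves) are
properties of this calibrated model; they demonstrate that a spatially
extended passive cable with discrete channels is *sufficient* to produce
location-dependent STDP of the reported kind, not that real dendrites use
these parameter values.
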