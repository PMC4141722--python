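# ioniccable

Analytic cable theory for calcium-based synaptic plasticity in dendrites.

Synapses on a dendrite do not all learn the same rule: experiments show that
the spike-timing-dependent plasticity (STDP) window broadens its depression
lobe and loses potentiation with distance from the soma. `ioniccable` models
the biophysics behind that observation with nothing but a passive cable,
discrete clusters of ion channels, an NMDA-receptor synapse, a calcium
reaction–diffusion cable, and the calcium-control plasticity rule — and asks
how far spatial attenuation alone goes in reshaping the learning rule.

It is a library for computational neuroscientists: build a model from a
key/value configuration, run pairing protocols from Python (see
`examples/`), or use the thin `ioniccable` command-line wrapper.

## The model

**Electrical cable.** A semi-infinite cylinder with membrane constants
`λ = sqrt(d·R_m/4R_i)` and `τ = R_m·C_m`. The back-propagating action
potential is a Dirichlet clamp at `x = 0` (a narrow sech² spike with an
after-depolarizing tail). Na, delayed-rectifier K, A-type K, and T-/L-type
Ca channels sit in discrete hotspots and act as point current sources; in
dimensionless variables

    ∂u/∂T = ∂²u/∂X² − u − Σ_{jk} w_jk(T) δ(X − X_jk),   u(0,T) = f(T),

which is recast into Volterra convolutions against the killed-end
(method-of-images) Green's function

    G(X,Y,T) = e^{−T}/√(4πT) · [e^{−(X−Y)²/4T} − e^{−(X+Y)²/4T}]

and solved by a regular perturbation expansion truncated at first order:
gating variables are driven by the passive field, and each hotspot current is
convolved with `G`. A Crank–Nicolson finite-difference solver of the full
nonlinear system acts as an independent verification oracle.

**Chemical cable.** Free calcium diffuses, binds a fast buffer, and is
extruded by a high-affinity pump. The rapid-buffer approximation linearizes
this into a second diffusion–decay cable with its own, much shorter,
constants `λ_c`, `τ_c`; calcium enters through T-/L-type channels and the
NMDA receptor (Jahr–Stevens magnesium block, `B(V) = 1/(1 +
[Mg]/3.57·e^{−0.062V})`).

**Plasticity.** The calcium-control rule: `Ω(Ca)` (difference of sigmoids
with thresholds θ_d = 0.35 < θ_p = 0.55) sets the sign of change — none
below θ_d, depression between the thresholds, potentiation above — and the
calcium-dependent learning rate `η(Ca)` sets its speed. Single pairings use
the normalized peak calcium as the drive; pairing trains can instead use a
per-cycle peak-over-integral (temporal integration) drive.

## Worked example

```python
import numpy as np, ioniccable as ic
from ioniccable.protocols import run_stdp_window, positive_lobe_bounds

model = ic.build_model()                      # shipped default configuration
lags = np.arange(-100.0, 121.0, 5.0)
prox = run_stdp_window(model, 50.0, lags, drive_mode="peak")
dist = run_stdp_window(model, 300.0, lags, drive_mode="peak",
                       normalizer=prox.normalizer)
for w in (prox, dist):
    print(w.location_um, round(w.dw.max(), 3), round(w.tau_ltd_ms, 1),
          positive_lobe_bounds(w))
```

prints

```
50.0  0.682 17.1 (40.0, 105.0)
300.0 0.630 20.6 (25.0, 55.0)
```

i.e. at the proximal synapse the window peaks at +0.68 (potentiation at
small positive lags), decays its post-pre depression with a ~17 ms time
constant, and carries a secondary pre-post depression band between 40 and
105 ms — while 250 µm further out the potentiation peak is smaller and the
depression time constant longer, with no change to the plasticity rule
itself. `examples/` contains this and three other narrative scripts
(pairing-frequency curves, calcium transients, oracle verification).

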