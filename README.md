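# starpddp

Multistability analysis of a **star network of Kuramoto-type phase
oscillators with plastic coupling**.  A hub oscillator (phase θ₀, natural
frequency ω₀) is bidirectionally coupled to N leaves (θⱼ, ω₁ < … < ω_N);
each direction of every link carries its own synaptic weight, Aⱼ
(leaf → hub) and Bⱼ (hub → leaf), bounded in [0, α]:

```
θ₀' = ω₀ + Σₖ Aₖ sin(θₖ − θ₀),      θⱼ' = ωⱼ + Bⱼ sin(θ₀ − θⱼ)
```

The weights evolve slowly (rate ε ≪ 1) under **phase-difference-dependent
plasticity (PDDP)** — a continuous-time analogue of spike-timing-dependent
plasticity driven by the wrapped phase difference φⱼ = θ₀ − θⱼ, with
exponential learning windows τ₊ (potentiation) and τ₋ (depression, τ₋ > τ₊)
and a boundary function F (power x^μ, sigmoid tanh(x/μ), or hard Heaviside)
that pins the weights inside the box.

Such a network is *massively multistable*: depending only on the initial
conditions it freezes into one of **2^N distinct asymptotic wiring
configurations**, each describable by a length-N code over
{0, 1_H, 1_L} (leaf unsynchronized / driving the hub / driven by the hub).
The package provides, as a library plus a `starpddp` command-line tool:

* `starpddp.model` — the governing ODEs (full and phase-difference form),
  boundary families, validated parameter containers;
* `starpddp.reduction` — the two-oscillator fast–slow reduction: locked
  branch with φ* = arcsin(Δ/K), period-averaged drifting branch, analytic
  fixed points A* = B* = F⁻¹(q) with
  q = τ₊(1−e^(−π/τ₊)) / (τ₋(1−e^(−π/τ₋))), μ→0 asymptotics, basin grids;
* `starpddp.codes` — the configuration-code algebra: encode/decode the
  2^N predicted states for any hub-frequency interval, materialize their
  weight vectors, classify simulated endpoints;
* `starpddp.survey` — ensemble drivers: basin-probability census,
  perturbation-convergence protocol, saturation detection (compiled
  fixed-step RK4 kernel; adaptive RK45 validation path).

It is aimed at researchers in nonlinear dynamics and computational
neuroscience studying adaptive oscillator networks and
plasticity-mediated multistability.

## Worked example

Two oscillators (ω₀ = 1, ω₁ = 0.5, α = 1, sigmoid boundary μ = 0.2,
ε = 10⁻³), started inside the phase-locked basin:

```python
import math
import starpddp as sp
from starpddp import survey, reduction

p = sp.NetworkParams(omega0=1.0, omega=[0.5], alpha=1.0, epsilon=1e-3,
                     boundary=sp.BoundarySpec("sigmoid", 0.2))

# full system from (A1, B1) = (0.2, 0.9), phase at its locked value
phi0 = math.asin(0.5 / 1.1)
traj = survey.integrate_network(p, ([phi0], [0.2], [0.9]), t_end=2e4)
phi, A, B = traj.final()
print(f"A1 = {A[0]:.6f}, B1 = {B[0]:.3f}")

q = reduction.q_factor(0.15, 0.3)
fp = reduction.stationary_state(reduction.TwoOscParams.from_network(p))
print(f"q = {q:.3f}; drifting fixed point A* = {fp.A:.3f}, B* = {fp.B:.3f}")
```

prints

```
A1 = 0.000000, B1 = 0.994
q = 0.500; drifting fixed point A* = 0.086, B* = 0.138
```

The leaf→hub weight has switched off and the hub→leaf weight has grown to
the bound (B₁ → α; it passes 0.994 at t = 2·10⁴ on its way to 1): the
oscillators end up unidirectionally coupled, locked at the faster
oscillator's frequency.  Had the run started below the K = Δ line it
would instead have drifted to the low-weight fixed point (A*, B*) near
the origin — the same system is bistable, and for N leaves the analogous
count is 2^N, enumerable as codes:

```bash
starpddp codes --N 3 --omega0 0.85 --omega 0.55,0.7,1.0
```

```
n,code,state_vector
0,0 0 0,0 0 0 0 0 0
1,0 0 1H,0 0 1 0 0 0
...
7,1L 1L 1H,0 0 1 1 1 0
```

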