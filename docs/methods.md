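# Methods

## Model

`starpddp` simulates a star network of `N + 1` Kuramoto-type phase
oscillators: a hub with phase `θ0` and natural frequency `ω0`, and leaves
`θj` with frequencies `ω1 < … < ωN` (strictly ascending, none equal to
`ω0`).  Each hub–leaf link carries two plastic weights, `A_j` (leaf → hub)
and `B_j` (hub → leaf), confined to `[0, α]`:

    θ0' = ω0 + Σ_k A_k sin(θk − θ0)
    θj' = ωj + B_j sin(θ0 − θj)

The weights follow a phase-difference-dependent plasticity (PDDP) rule, a
time-continuous analogue of spike-timing-dependent plasticity in which the
hub–leaf phase difference `φj = θ0 − θj` (wrapped to `[−π, π)`) replaces
the spike-timing difference:

    φj ∈ [−π, 0):  A_j' =  ε F(α − A_j) exp( φj/τ+),  B_j' = −ε F(B_j) exp( φj/τ−)
    φj ∈ [0,  π):  A_j' = −ε F(A_j) exp(−φj/τ−),      B_j' =  ε F(α − B_j) exp(−φj/τ+)

When the leaf leads the hub (`φj < 0`) the leaf→hub synapse potentiates
and the hub→leaf synapse depresses, and vice versa.  Potentiation always
carries the window `τ+`, depression `τ−`; consequently negating every
`φj` exchanges the A- and B-equations at fixed windows (this, rather than
a `τ+ ↔ τ−` swap, is the branch symmetry the property test asserts).

Parameters (defaults are the reference values used throughout):

| parameter | meaning | default |
|---|---|---|
| `α` | weight bound (units of coupling strength) | 1 |
| `τ+`, `τ−` | potentiation / depression windows (rad) | 0.15, 0.3 (τ− > τ+: depression dominates) |
| `ε` | weight/phase time-scale ratio | 1e−3 |
| `F`, `μ` | boundary function and sharpness | sigmoid `tanh(x/μ)`, μ = 0.01 |

Boundary families: `power` (`x^μ`, soft at μ = 1), `sigmoid`
(`tanh(x/μ)`), `heaviside` (hard; convention `H(0) = 0` so that `F(0)=0`
holds for every family and the synchronized state below is an exact
equilibrium).  `μ → 0` is the hard-boundary limit.

The solver state is the phase-difference form `(φ, A, B)` (3N equations);
the full `(θ0, θ, A, B)` form is retained for validation and the two
right-hand sides are cross-checked in the tests.

## Two-oscillator reduction

For `N = 1` the fast phase obeys `φ1' = Δ − K sin φ1` with `Δ = ω0 − ω1 > 0`
and `K = A1 + B1`.  Exploiting `ε ≪ 1`:

* **Locked branch, `K > Δ`** — `φ1` rests at `φ* = arcsin(Δ/K)` and the
  weights flow monotonically to the synchronized attractor `(A1, B1) =
  (0, α)` (exists iff `α > Δ`).  That point, with `φ* = arcsin(Δ/α)`, is an
  *exact* equilibrium of the unreduced system for any `ε, μ`.
* **Drifting branch, `K < Δ`** — `φ1` rotates with period
  `T(K) = 2π/√(Δ² − K²)`; averaging the weight equations over one rotation
  yields four kernel integrals of `G±(K, φ) = exp(φ/τ±)/(Δ − K sin φ)`.
  The averaged flow has a stable low-weight fixed point; in the small-`K`
  regime it solves `F(A*)/F(α − A*) = q` with

      q = τ+ (1 − e^{−π/τ+}) / (τ− (1 − e^{−π/τ−}))   (= 0.50 at the defaults)

  giving `A* = B* = q^{1/μ}` (power) and `A* = B* = μ·atanh q` (sigmoid):
  the drifting state disconnects completely in the hard-boundary limit.

Numerical choices: the kernel integrals use adaptive quadrature
(`scipy.integrate.quad`, `epsabs 1e−10`, with a split point at `φ = π/2`
where the denominator is smallest); branch switching during reduced-flow
integration is handled by terminal events on `K − Δ = 0` with a `1e−7`
nudge across the line, and within a `1e−9` band of the line the locked
form with `φ* = π/2` is used (the averaged equations are singular there,
`T → ∞`).  Stationary states are found by bracketed root finding; the
weight equation is bisected in log space because the root is
exponentially small in `μ` for the power family.  `stationary_state`
scans `K ∈ [0, Δ)` for sign changes of `K − A(K) − B(K)` and returns the
smallest root (the stable node) together with the number of sign changes
found (a second root, the saddle just below the `K = Δ` line, is typical).
For basin labeling of the reduced flow the four integrals are
pre-tabulated on a `K`-grid refined toward `Δ` and interpolated with
PCHIP; the quadrature path remains the default and the oracle.  A
reduced-flow trajectory is labeled "synchronized" as soon as `B > Δ`
(on the locked branch `B` only grows, so `K > Δ` is then invariant) —
this decides slowly-committing trajectories near the line rigorously.

With the soft boundary (power, μ = 1) at the reference detuning `Δ = 0.5`
the drifting fixed point does not exist (`f1 + f2 > K` on all of
`[0, Δ)`): the system is then monostable and `stationary_K_power` raises.

## Configuration codes

In the double limit `ε → 0, μ → 0` every leaf ends either unsynchronized
(`0`, both weights → 0) or synchronized through exactly one saturated
link: `1H` (leaf drives the hub; requires the leaf to be the fastest
synchronized oscillator above the hub) or `1L` (hub drives the leaf).
With the hub frequency in interval `k` (`k = 1`: below all leaves, `k =
N+1`: above all), the `n`-th configuration code is the binary expansion
of `n` (`s1` = most significant bit) with the rightmost 1 at position
`≥ k` subscripted H and all other 1s subscripted L.  This yields `2^N`
admissible codes per hub interval; `encode`/`decode` are exact inverses
and `code_to_state_vector` materializes the predicted weight vector
`R_n = (A*, B*)` with entries in `{0, α}`.

## Ensemble protocols and the synthetic study conditions

All inputs are generated in-package; there is no external data.  Random
initial states draw weights i.i.d. uniform on `[0, α]` and phases uniform
on `[0, 2π)` (`numpy.random.default_rng`, fully seeded).

**Integrator.** Ensembles use a fixed-step RK4 kernel (numba) on the
phase-difference form, `dt = 0.01` by default (`0.02–0.025` in the large
surveys; the fastest phase rate is `≲ Δ + (N+1)α` and endpoint weights
change by `< 1e−6` between `dt = 0.025` and `dt = 0.005`).  Weights are
clipped to `[0, α]` and phases re-wrapped after every step.  An adaptive
RK45 path (`rtol 1e−8`, `atol 1e−10`) exists for validation; the two
agree to `~1e−11` in the weights over hundreds of time units.

**Basin survey.** Each initial condition is integrated for `40/ε` time
units and the trailing-window mean weights (window 30, a few fast
periods, which removes the `O(ε)` ripple of drifting states) are
classified with threshold `α/2`.  A run is *resolved* when its code is
admissible and no weight sits in the ambiguous band `(0.3α, 0.7α)`;
unresolved runs are extended in chunks of `10/ε` up to 10× the base
horizon.  The extension matters because capture of a hub-driving link is
exponentially slow near its threshold (`A_j ≈ Δ_j` puts the locked phase
near `−π/2`, suppressing potentiation by `e^{−π/(2τ+)} ≈ 3e−5`); a few
ICs per 200 need ~10× the typical saturation time.  Saturation is
reported per run via a windowed-drift criterion (drift of the
ripple-smoothed weights over `10/ε` below `10^{−3} α`).  Probabilities
are aggregated over classified admissible runs; anomalies (unclassifiable
or inadmissible endpoints) are reported, never dropped.

**Perturbation protocol.** For every `n` the predicted state `R_n` is
displaced by a fixed Euclidean distance (weight coordinates only,
default 0.05) along an isotropic direction reflected coordinate-wise into
the box — for corner targets this reflection realizes exactly the
conditional law of reject-and-redraw sampling without its `2^{−2N}`
acceptance rate.  Synchronized leaves start at their locked phases
(cluster frequency = the hub-driving leaf if present, else the hub),
unsynchronized leaves at random phases.  Distances to the target are
reported as trailing-window means at each checkpoint.

**Problem sizes.** The shipped tests run the census at `ε = 5e−3`
(200 ICs per survey, horizon `40/ε`) for the two-leaf star in all three
hub placements of the frequency set `(0.55, 0.85, 1)` and for the
three-leaf star `(0.55, 0.7, 1.0)` with hub `0.85`; the perturbation
protocol runs a five-leaf star with equidistant frequencies on
`[0.6, 1]`, hub second-fastest, sigmoid `μ = 0.01` versus Heaviside,
checkpoints at `t = 60` and `8000` (slow times 0.3 and 40).  These sizes
were chosen as the smallest ensembles at which the `2^N` multistability
and perturbation-convergence results are cleanly resolved; all drivers
accept larger `counts`, smaller `ε` and longer horizons unchanged.

## Command-line outputs

Configuration is a single JSON file validated by pydantic models
(`starpddp.config`); CLI flags override config values.  Every command
writes a `manifest.json` (command, full config, SHA-256 of the canonical
config, seeds, package/numpy/scipy versions) sufficient to reproduce the
run bit-exactly.  Stable file schemas: `trajectory.csv`
(`t, phi_1..phi_N, A_1..A_N, B_1..B_N`), `fixed_points.csv`
(`class, A, B, K, stable`), `mu_sweep.csv`
(`mu, A_star, small_mu_prediction`), `survey_runs.csv`
(`run, saturated, t_total, A_j.., B_j.., n, code`),
`survey_aggregate.json` (`k, count, probabilities, n_distinct,
n_anomalies, anomalies`), `perturbation.csv`
(`n, code, initial_distance, distance_t<checkpoint>..`).  All files are
written atomically (temp file + rename).

## What the tests do and do not show

The generators emulate the idealized model exactly — deterministic phase
dynamics, identical plasticity on every link, no noise, delays,
inhibition, or topology beyond the star.  Passing tests therefore
validate the mathematics of the model and its reduction, not the
robustness of `2^N` multistability in biological neural tissue; noise,
propagation delays and richer topologies are outside scope.  Known
limitations: reduced-flow integration assumes a smooth boundary family
(the Heaviside reduced flow has a discontinuous right-hand side; the
full-model kernel handles it via clipping); the averaged branch is
inaccurate within `O(ε)` of the `K = Δ` line where its derivation
breaks down; basin probabilities at scaled `ε` differ by a few per cent
from the slow-adaptation limit, so only robust ordinal statements about
them are asserted; and the strict ordering of few-per-cent basin
probabilities is below Monte-Carlo resolution at 200 samples.
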