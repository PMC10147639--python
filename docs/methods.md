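# Methods

## Model

Each neuron is a theta-neuron, the normal form of a class-I excitable cell: its
state is a single phase `θ_i ∈ [−π, π)` and a spike is the crossing of `+π`.
The network couples N = N_E + N_I neurons through electrical gap junctions with
a diffusive sinusoidal coupling:

    dθ_i/dt = (1 − cos θ_i) + (1 + cos θ_i) [ η_i + (g/N) Σ_j κ_ij sin(θ_j − θ_i) + I_i(t) + ξ_i(t) ]

* `η_i` — excitability; for constant drive the intrinsic period is `π/√η_i`.
* `g` — global coupling strength (default 1).
* `κ_ij` — plastic weight from pre-synaptic j onto post-synaptic i. Dale's
  principle is enforced columnwise: excitatory columns live in [0, 1],
  inhibitory columns in [−1, 0]; in the "unlabelled" control variant every
  entry may take either sign in [−1, 1].
* `I_i(t)` — stimulus currents (0 or 3 by default), applied only to
  excitatory neurons.
* `ξ_i(t)` — independent Gaussian white noise, treated in the Stratonovich
  sense because it enters multiplicatively through the `(1 + cos θ)` factor.

Integration uses the Euler–Heun predictor–corrector (Euler–Maruyama predictor,
corrector averaging the diffusion coefficient between current and predicted
state), which converges to the Stratonovich solution for scalar multiplicative
noise; with zero noise it reduces to the plain Euler scheme. The step is
dt = 0.01. Spikes are detected on the unwrapped increment crossing `+π` from
below; downward crossings of `−π` under strong noise are wrapped but not
counted. With these choices the noise-free single-neuron inter-spike interval
reproduces the closed form `π/√η` to well under 0.1 % already at dt = 0.01.

### Parameter table and the (mean, std) reading

The canonical parameter set is N = 100 (80 E / 20 I), g = 1, I ∈ {0, 3},
ε₁ = 10⁻⁵, ε₂ = 0.1, dt = 0.01, excitabilities normally distributed around
1.5 and noise centred on 0. The distribution notation `N(a, b)` for the
excitabilities and the noise does not state whether `b` is a variance or a
standard deviation. We resolved this empirically, before freezing any
acceptance checks, by which reading reproduces the reported network states:

* noise std 0.316 (variance reading) leaves the resting network far from
  synchrony (R₁ ≈ 0.55–0.76 instead of ≈ 1) and abolishes the two-cluster
  end state of the two-stimulus protocol (R₂ ≈ 0.1);
* excitability std 0.1 destroys cluster maintenance in every experiment
  (consolidated R₂ ≈ 0.3, single phase cluster);
* reading both entries as (mean, std) — noise std 0.1, excitability std
  0.01 — reproduces the reported phenomenology throughout (rest R₁ ≈ 0.92,
  consolidated R₂ ≈ 0.9 with R₁ ≈ 0.13).

The defaults are therefore `noise_variance = 0.01` and `eta_variance = 10⁻⁴`
(the config fields store variances).

## Plasticity

Weights evolve with the instantaneous phase difference Δθ = θ_j − θ_i through
a Hebbian kernel Λ(Δθ): potentiation near Δθ = 0, depression near ±π. Two
kernels are implemented: the symmetric cosine Λ₀ = cos Δθ, and the asymmetric
piecewise-exponential Λ₁ whose potentiation lobe decays over 0.1 rad and whose
depression lobe decays over 0.5 rad — a 5:1 window ratio mirroring cortical
STDP measurements — while attaining the same extrema as Λ₀ to within 2·10⁻³.
Λ₁ is even, 2π-periodic and continuous at its branch joins; its potentiation
lobe ends exactly at Δθ = π/6 (zero crossing).

Two learning timescales act simultaneously: a slow, always-on rate ε₁ and a
fast rate ε₂ gated per synapse by the presence of a sufficiently strong
stimulus (|I_j| > 0.1) at the pre-synaptic neuron, active only between two
excitatory neurons. Under Dale's principle the signed weight obeys
soft-bounded dynamics

    dκ_ij/dt = [ε₁ + ε₂ H(|I_j| − 0.1)] · |κ_ij| (1 − |κ_ij|) · Λ(Δθ),

so a positive kernel drives every weight upward within its bound interval:
E→E synapses between co-active neurons saturate towards 1, while inhibitory
synapses onto in-phase targets decay towards 0 and onto anti-phase targets
grow towards −1. This is the mechanism by which the inhibitory wiring
self-organises into the consolidated feedforward architecture: each inhibitory
group ends up driven by its own cluster and suppressing all the others. (An
alternative reading that applies the derivative to the magnitude |κ| instead
inverts the inhibitory organisation and erases that architecture; we verified
in simulation that it prevents inhibitory self-organisation.) The unlabelled
variant instead relaxes the weight linearly towards the kernel value,
dκ/dt = ε (−κ + Λ₀(Δθ)), with the same gating.

The soft bounds make 0 and ±1 absorbing. Because forward Euler can overshoot
onto a bound and freeze a weight there — and because the idealised pre-trained
matrices used by the stability experiments are exactly {−1, 0, 1}-valued —
every update clamps the magnitude into [ε_num, 1 − ε_num] with ε_num = 10⁻⁶,
preserving the soft-bound character while keeping all weights adaptable.
Weight updates are applied after the phase update of each step, using the
post-update phases; with dt = 0.01 and rates ≤ 0.1 the ordering effect is
O(dt²). Self-weights are fixed at 0: `sin(θ_i − θ_i) = 0` makes them inert,
and adapting them would only saturate them meaninglessly.

The long-simulation driver runs a compiled (numba) loop that evaluates the
kernel from a 65536-point interpolation table and exploits the evenness of
both kernels (one evaluation per unordered pair); the pure-numpy reference
path (`core.step` + `plasticity.update_weights`) is cross-checked against the
compiled loop in the test suite to 10⁻⁸ over shared noise streams.

## Protocols and experiments

**Entrainment** (`run_main_experiment`): an initial rest of 200 time units
(transient; the network settles close to synchrony), then 50 stimulation
blocks of 20 time units, each targeting one of n equal groups of excitatory
neurons (chosen uniformly at random; strictly alternating with a short gap for
the overlap protocol) at amplitude 3, then a consolidation phase of
spontaneous activity with only the slow rate active. Weight snapshots are
taken at the phase boundaries T0–T3.

**Desk-scale consolidation.** With the literal ε₁ = 10⁻⁵ consolidation spans
~10⁵ time units. Desk runs multiply the slow rate by ρ = 100 (ε₁ → 10⁻³) and
use a 2000-unit consolidation, preserving ε₁ ≪ ε₂ and the nominal number of
plasticity e-folds; full-fidelity settings remain available through
`ConsolidationParams(rho=1, duration=...)`. Two caveats of this rescaling are
documented under Limitations: processes whose outcome depends on the slow
rate being adiabatically slow (rather than on accumulated e-folds) are
distorted, and processes needing many more e-folds than the learning phase
imprinted (e.g. re-growth of deeply pruned weights) do not complete.

**Stability trials** (`run_stability_trial`): an idealised consolidated
network is built (`build_pretrained_matrix`): M saturated excitatory modules,
each inhibitory neuron assigned round-robin to one module, receiving
feedforward excitation from it and inhibiting the exclusive excitatory
members and inhibitory neurons of all other modules; optional hub neurons
belong to every module, excite all modules' members and inhibitory neurons,
and receive no inhibition. Phases start random; the network evolves
spontaneously with the rescaled slow rate. The surviving-module count is the
smaller of (i) the connected components of the strong E–E graph
(|κ| ≥ 0.5, OR-symmetrised) and (ii) the modal phase-cluster count (circular
gaps > 0.5 rad split clusters) over snapshots from the final 500 time units —
both restricted to the modules' exclusive members, because hubs bridge
modules by construction. A module that has lost its independent dynamics is
counted as merged even while the (slow) weights still show the stored
structure. Each grid cell of a stability map runs 3 seeds and reports the
modal count; infeasible cells (more modules than excitatory neurons, or no
exclusive members) are marked non-accessible.

**Memory recall** (`run_recall_experiment`): starting from a consolidated
two-module network whose E–E block has been re-randomised uniformly on [0, 1]
(`scramble_excitatory_weights`; all connections involving inhibitory neurons
keep their learned values), each stored pattern is probed with a 5-unit,
amplitude-3 pulse after a 200-unit rest. The recall score between two neuron
groups is `(1 − cos Δψ)/2` with Δψ the difference of the groups' circular
mean phases: 0 when in phase, 1 in perfect anti-phase. A successful recall is
a transient rise of the pulsed pattern's score against the complementary
pattern well above its pre-pulse baseline (observed: baseline ≈ 0.001, peak
≈ 0.99; a zero-amplitude pulse changes nothing).

## Synthetic data scope

All inputs are generated: random initial states, stimulus schedules and
idealised pre-trained matrices. The generator emulates the study conditions
(N = 100, 80/20 E/I split, uniform random initial weights, normal
excitabilities, alternating 20-unit stimulus blocks at amplitude 3) and not
features of biological recordings: no transmission delays, no chemical
synapses, no heterogeneous degree structure, no measurement noise. Passing
tests therefore demonstrate the internal consistency of the model and the
reproducibility of its collective phenomena, not fidelity to physiological
data.

## Numerical and design choices

* Order parameters `Z_n = (1/N) Σ e^{inθ}` are computed over the whole
  population; cluster-resolved statements use explicit index sets.
* The structural-module threshold 0.5 sits midway between saturated (≈1) and
  pruned (≈0) weights; component counting uses OR-symmetrisation of the
  binarised E–E graph.
* Phase-cluster counting uses a 0.5-rad circular gap tolerance; tight
  clusters in an M-splay are separated by 2π/M ≫ 0.5 for the M studied here.
* The T1 snapshot ("early in learning") is taken after ⌈n_blocks/5⌉ blocks.
* One seeded `numpy.random.Generator` drives each run; the documented draw
  order is initial phases, excitabilities, weights, then schedule
  randomisation and per-chunk noise. Runs are bit-reproducible given a seed.
* Problem sizes for the shipped checks: N = 100 networks; 2000-unit
  consolidations (2·10⁵ steps, ≈ 10 s each on one core); stability grids of
  15 cells × 3 seeds; 5 seeds per stochastic claim.

## Limitations

* **Hub (mixed-selectivity) capacity.** With the symmetric pre-trained hub
  wiring, hubs settle midway between the two clusters (the sum of two equal
  sinusoidal attractions has a single stable point there; we verified that an
  "adopted" initial condition relaxes back to midway). The segregation
  boundary is then N_I ≈ N_H + 1 — hub pull ≈ N_H·sin(s/2) against inhibitory
  repulsion ≈ N_I·sin(s)/2 — rather than N_I = 2N_H + 1, which presumes hubs
  phase-locked to a single cluster. Hub adoption is a slow structural
  symmetry-breaking (depression of the hub's links to one cluster at rate
  ε₁|Λ(s/2)| with |Λ(s/2)| ~ 10⁻²) that desk-scale e-fold budgets cannot
  complete. Measured at desk scale: merged for N_I ≤ 8, segregated from
  N_I ≈ 10 with N_H = 8 (and boundary ≈ N_H + 1 across N_H = 4–12).
* **Multi-module capacity beyond M = 2.** The M−1 rule reproduces exactly
  for M = 2. For M ≥ 3 the map is correct in most cells but individual cells
  flip between seeds: with sinusoidal coupling the repulsion from two
  anti-phase inhibitory groups cancels to first order, so a module without
  its own inhibitory neuron is only weakly pinned and, with single inhibitory
  neurons out of N = 100, pinning forces are comparable to the noise.
  Desk-scale horizons cannot average these out.
* **Full structural forgetting/reorganisation.** Re-growth of cross-module
  E–E weights after deep learning-phase pruning (excitatory-only control),
  and the complete re-association of inhibitory neurons after multi-stimulus
  learning (which would even out the three-cluster splay and push R₃ towards
  1), require ≥ 5 slow e-folds beyond the rescaled budget; at desk scale the
  forgetting and the three-cluster state are evident dynamically
  (R₁ ≈ 0.99 resynchronisation; three excitatory phase clusters) before they
  are fully expressed in the weight matrix.
* The connected-component module count can be bridged by a handful of relic
  links from the tail of the initial uniform weight distribution; the counts
  reported by the experiments are therefore read together with the dynamical
  verdicts.
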