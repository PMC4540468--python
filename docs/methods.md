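# Methods

This note documents the model, the discrete-time scheme, the synthetic-input
generators, and the numerical and design choices behind `sheetsampler`.

## Generative model and network equivalence

The model couples K binary latent variables `z` to N observed variables `y`.
The prior is a Boltzmann machine, `p(z) ∝ exp(½ zᵀ(Ŵ^exc+Ŵ^inh)z + zᵀb̂)`,
with symmetric zero-diagonal couplings; the likelihood factorizes over
inputs, each governed by its single active parent (or a default hypothesis)
in natural exponential-family form.  Lateral inhibition is represented as a
finite coupling of −100 rather than the idealized −∞.  This one choice is
used *everywhere* — simulator, enumerated posterior, conditional log-odds —
so the membrane potential and the enumerated conditional log-odds agree to
machine precision over all 2^K states, including the (astronomically
suppressed) states with co-active competitors; the leakage probability of
such states is bounded by K² e^(−100) ≈ 10^(−41) K².  The hard constraint
(valid-state enumeration) is used only where a restricted state space is the
point: state counting, prior-bias calibration at K > 16, and log-likelihood
sums.

Parameter translation follows the exponential-family normalizers: for
Bernoulli channels `V_ki = logit(π_ki) − logit(π_0i)` and
`A_ki = log[(1−π_0i)/(1−π_ki)]`; Poisson and Gaussian channels use the
corresponding `log λ` and `μ/σ²` forms.  Excitabilities for exact inference
are `b_k = b̂_k − A_k`; during learning `b` is free and homeostasis absorbs
the normalizers.

All probability arithmetic is in log space with log-sum-exp normalization.

## Discrete-time simulation

Time step δt = 1 ms, PSP/refractory time τ = 10 ms, so τ̃ = 10 steps.  A
spike sets the unit's state to 1 for exactly τ̃ steps; a re-spike in the
last active step continues the active state without an off step.  Per step:

1. **Inputs.**  Each input spikes with probability `p_i = 1 − (1−x_i)^{1/τ̃}`
   derived from its piecewise-constant target activation `x_i(t)`, so the
   long-run mean of the input state equals `x_i`.  Inputs update before
   network neurons, so neurons see the current input state within the step.
2. **Network neurons** are visited in a fresh uniformly random order; state
   transitions are visible to subsequently updated neurons within the same
   step.  A neuron that is inactive or in its last active step spikes with
   probability `σ(u_k − log τ̃)` computed from the current (partially
   updated) state.
3. **Plasticity** (if enabled) applies one Euler step of each active rule on
   the end-of-step states.  The wake-sleep companion sampler — an input-free
   network sharing the learner's recurrent weights by reference, with its own
   homeostatically driven biases — takes exactly one step per wake step,
   before the weight update.

One shared RNG stream per run is consumed in a fixed documented order
(inputs by index, wake visit order, wake spike draws, then the sleep
sampler's draws), so a seed determines the trace bit for bit.  The compiled
kernel is cross-checked against a pure-Python reference that replays the
identical stream; the two must agree exactly, which pins down every
bookkeeping detail (countdown semantics, eligibility, draw order).

Zero synaptic delay; rectangular non-additive PSPs are implied by the state
variables themselves — no separate PSP buffer exists.

## Plasticity rules and timescales

* Afferent Hebbian: `ΔV_ki = δt η_V z_k (y_i − ∂A_ki/∂V_ki)`; the derivative
  is the channel expectation (σ(V+V0) for Bernoulli).  Applied only to
  synapses inside the afferent field; clipped at 0 by default (excitatory
  synapses), with a sign-free mode available since the theory supports both.
* Homeostatic intrinsic: `Δb_k = δt η_b (m_k − z_k)` drives each neuron's
  long-term activity to `m_k`; this implements the variational E-step, with
  the network sampling the closest distribution to the exact posterior that
  satisfies the activity constraints.
* Wake-sleep recurrent: `ΔW_kj = δt η_W (z_k z_j − z'_k z'_j)` per unordered
  pair, mirrored, preserving symmetry exactly.  The sleep bias update is
  `Δb̂_k = δt η_b (z_k − z'_k)` with the learner's homeostatic rate.
* Heuristic recurrent: `ΔW_kj = δt η_W [z_k z_j − m_k m_j −
  tan(½π W_kj/W_max)/γ]`.  W is clamped to `[0, W_max(1−10⁻⁶)]` to keep the
  tangent finite; the divergence of the LTD term at `W_max` bounds weights by
  construction.  `(W_max, γ)` are fitted per task by least squares on the
  (converged wake-sleep weight, coactivation covariance) pairs, using only
  synapses with weight above 0.01 — weights pinned at zero by the
  nonnegativity clip carry no information about the curve.

Reliable learning needs τ ≪ input-pattern duration ≪ 1/η_b ≪ 1/η_V (a factor
of roughly 5–20 per relation); the configuration reports violations as
warnings, not errors, since shorter separations often still work.

## Experiment protocols and synthetic inputs

The generator defaults are the study conditions; all produce piecewise-
constant activation schedules from which Poisson-like spike trains are drawn.

* **tracking** (6-neuron chain, 18×6 inputs, fields 6×6 shifted by 3,
  nearest-neighbor inhibition, three excitatory pairs at weight 1, b̂ = −1):
  per-neuron preferred patterns drawn uniform on (0.2, 0.55) over a 0.2
  background.  The precise on/off schedule of patterns is not fully
  prescribed by the protocol; segments of 50–250 ms activate a random
  non-conflicting subset of locations with probability 0.4 each.  Repeated
  runs share the input at spike level, and a 100 ms window at each end is
  discarded (burn-in and smoothing-boundary artifacts).
* **experts** (7×3 neurons, 21×6 inputs on a torus, m = 0.065, η_b = 1,
  η_V = 0.2): per location, three patterns `0.5·Dirichlet(0.3,0.3,0.3)+0.1`;
  three on/off chains with Gamma(10, 10 ms) inactive and Gamma(10, 20 ms)
  active phases (200 ms mean), each activation picking a uniform pattern and
  a location that does not overlap any co-active chain — resolved
  event-chronologically, so a free location always exists.
* **cues** (7 disjoint populations of 3, all-to-all excitation, m = 0.95/3,
  η = 0.1/0.1/0.005, ϑ = (1.41, 31.6)): width-2 vertical stripes at 0.4/0.1;
  outer locations are independent cues, inner locations show the unique
  pattern differing from both distinct cues for 500 ms, or each of the two
  valid patterns for 250 ms under equal cues; the nine ordered cue
  combinations cycle so all get equal time.
* **sheet** (12×12 neurons over 24×24 inputs, fields shifted by 2,
  inhibition range 2 in the neuron grid — identical to the overlap-derived
  range — 25% reciprocal excitation, m = 0.025, η = 10/2/1,
  ϑ = (2.7049, 733.69)): three binary motifs (grid lines, width-2 diagonal
  stripes, 2×2 checkerboard) at 0.5/0.1, footprint diameter drawn uniform in
  [8, 12] input units (always exceeding the 6×6 field), two motifs at
  non-overlapping random torus locations redrawn every 100 ms.
* **nested** (2-neuron WTA over one 6×6 field, m = 0.32, η_b = 1.5,
  η_V = 0.3): a strong pattern (4 of 6 rows active at 0.8), a weak pattern
  strictly contained in it (2 rows), and background, cycled in equal 1 s
  shares.  The ablation variant freezes b = −2 and disables homeostasis.

What these generators emulate: rate-coded Poisson spiking input with
rectangular synaptic interactions, locally exclusive pattern presentation,
and controlled higher-order correlation structure.  What they do not:
temporal structure within patterns, additive/conductance PSPs, spike-timing
(rather than state-based) plasticity, plastic or soft inhibition, and any
non-stationarity of the environment.  Passing tests therefore demonstrate
correctness of the sampling and learning dynamics under the model's own
assumptions, not robustness to real neural data.

## Analysis conventions

Tuning labels assign each neuron the pattern template best correlated with
its afferent weights over its field (for motifs: maximized over the motif's
torus phases).  "Converged" weights are the time-average over the final 10%
of a run.  The cue-task pair groups are: inner–inner pairs with equal
tuning; cue–inner pairs with differing (hence compatible) tuning; the two
cue neurons with equal tuning; and all remaining pairs.  Input
reconstruction maps a response window back through the likelihood,
`⟨y_i⟩ = mean_t σ(V_0i + Σ_k z_k(t) V_ki)`.  The log-likelihood of held-out
inputs restores the full channel pmf (base measure included) so values are
absolute; prior biases for it are calibrated offline by damped fixed-point
iteration `b̂ ← b̂ + ½(log m − log⟨z⟩)` against the enumerated prior
(tolerance 10⁻⁶ on the marginals).

## Problem sizes in tests and the acceptance script

Sampling-correctness checks enumerate K ≤ 4 posteriors against 10⁶-step
runs over 3 seeds (total variation < 0.02).  The transient-tracking check
uses 200 repetitions of a 1.7 s protocol.  The cue task runs its full
25,000 s — the weakly driven weight groups (cue–cue pairs and the decaying
"other" pairs) plateau last, and the converged group means are read from
the final 2,500 s.  The ablation runs its full 5,000 s.  The local-expert
sheet trains for 3,000 s (homeostatic equilibrium is reached within a few
hundred seconds at η_b = 1) before the 100 s column-silence measurement;
the motif sheet runs 600 s (η_b = 10 reaches its equilibrium rate within
tens of seconds) with the final 200 s measured.  These sizes are the
package's standard test conditions; the full 10,000–25,000 s protocols are
available through the same configuration objects.

## Known limitations

* The heuristic recurrent rule has no convergence guarantee under recurrent
  dynamics; its parameters are task-specific by construction.
* Exact inference is enumeration-based and capped (2^K for K ≤ 20,
  valid-state enumeration for K ≤ 24); larger networks can be simulated but
  not validated exactly.
* The prior is a single-layer, symmetric Boltzmann machine: directed or
  hierarchical priors, plastic inhibition, and temporal models are out of
  scope.
* The log-likelihood trace restores the base measure h(y); analyses that
  drop it differ by a constant offset per sample.
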