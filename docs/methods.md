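# Methods

## Model and assumptions

The detector assumes the observed series is generated by a dynamical
system whose evolution law is stationary except for a single abrupt change
at an unknown time `t_p` (a parameter jump or a structural rewiring). A
leaky echo state network (ESN) with fixed random internal matrix `A`
(sparse, entries uniform on [−1, 1] before rescaling to a prescribed
spectral radius) and fixed random input matrix `W` (entries uniform on
[−s, s], `s` the input scaling) embeds the series into an `n`-dimensional
state. The window-local linear readout `W_out(t)` — the ridge solution of
the one-step prediction problem on the trailing window `[t − T_w, t)` —
serves as a fingerprint of the local evolution law: on stationary
segments it is approximately invariant under window translation, and its
change across the tipping point is (to first order) monotone in the
parameter change. The supervised map `f` from the flattened difference
`ΔW_out(t) = W_out(t+T_w) − W_out(t)` to a change score inherits this
structure, which makes the scan curve unimodal over
`[t_p − T_w, t_p + T_w]` and justifies locating the change at the peak.

State/observation alignment: `states[i]` has absorbed inputs up to
`x_{i−1}`, and the readout regresses `states[i] → x_i`. This makes the
state evolution, the readout definition and closed-loop forecasting
mutually consistent (the forecast feeds `x̂_{i+1} = W_out r_{i+1}` back as
the next input).

Two exactly equivalent window estimators are provided: direct ridge via
the regularised normal equations, and recursive least squares restarted
from `P₀ = I/γ` at each window start (`γ = 0.01` by default, and RLS with
`γ` equals ridge with `β = γ`; this equivalence is the module's primary
test oracle). The restart-per-window variant costs `O(T_w n²)` per window
but keeps every `W_out` strictly window-local.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `n` | 100 (general), 20 (detection presets) | reservoir nodes. Small reservoirs concentrate the change signal in few readout coordinates; measured detection quality on all three testbeds was best at n ≈ 20, and large n mainly added fit variance. Forecasting uses n = 100–300. |
| `leakage l` | 0.9 (0.5 for the network preset) | state memory per sample; tuned to the effective sampling step. |
| `spectral_radius` | 0.9 | echo-state regime (< 1 ⇒ state forgets its initialisation). |
| `density` | 0.05 | sparsity of `A`. |
| `input_scaling` | 0.1 | drive amplitude into tanh **after standardisation** (below); keeps the nonlinearity unsaturated. |
| `washout` | 50 samples | discarded so states forget `r₀`; training switch times are placed ≥ `T_w + washout` from the run start. |
| `T_w` | 300 samples | fingerprint window; the scan feature spans `2 T_w`. |
| `β` | 0.1 | window ridge penalty; smaller values let rank-deficient windows (laminar attractor episodes) produce wild readouts, larger values crush the parameter signal. |
| scan stride `δt` | 10 (must divide `T_w`) | anchor spacing; the position-error floor scales with `δt`. |
| negatives/run | 20–50 in presets | change-free training anchors; the null-score tail of the scan shrinks monotonically with their number. |
| detector family | Random Forest (classification; 200 trees, all features per split, balanced class weights) / ridge with LOO-cross-validated penalty (regression) | both seeded; families and hyperparameters overridable. |

**Standardisation.** Observed channels are shifted/scaled by per-channel
training-set statistics before entering the reservoir (the transform is
stored with the trained model and applied at scan time). Without it a
single input-scaling default cannot serve systems whose amplitudes differ
by an order of magnitude (Lorenz coordinates span ±20, the KS field ±3),
leaving tanh either saturated or effectively linear.

**Peak location.** `locate_tipping` defaults to the plain (earliest-tie)
argmax of the curve — the contract used by the unit tests. The benchmark
pipeline enables a two-stage locator that exploits the known geometry of
a true detection: a moving-average matched filter at the bump width
`2 T_w/δt` selects the response region, then the peak is refined by local
argmax on a 3-point median-smoothed curve within `T_w/2` samples of the
region centre. Fitting artefacts spike on one or two anchors and are
rejected by the matched span; the refinement restores single-anchor
resolution. The signed score at the chosen anchor is the intensity
estimate.

**Ensembles for networked systems.** For the coupled-oscillator testbed
one classifier is trained per 3-channel oscillator and the scan signal is
the pointwise mean of the per-oscillator probability curves. A structural
change that leaves oscillator k's own incoming edges untouched would give
classifier k a mislabeled positive, so such runs are excluded from that
classifier's training set (flag `subsystem_label_filter`).

## Synthetic testbeds

All three generators integrate with fixed-step methods (RK4 for the ODE
systems, Kassam–Trefethen ETDRK4 with 2/3-rule dealiasing for the PDE),
add i.i.d. Gaussian observation noise after integration, and record the
ground truth (switch index, parameters before/after, signed intensity).
Every draw descends from one root seed through a spawned per-run seed
tree, so benchmarks regenerate exactly; the batch generator integrates
all runs of a benchmark simultaneously (vectorised over the run axis) and
is tested to agree with the per-run reference simulators.

* **Lorenz63**: `σ(y−x), ρx−y−xz, xy−ζz` with `ρ=28, ζ=8/3`; `σ` switches
  between two values uniform in [5, 15]; dt = 0.02, one step per sample;
  inits uniform in [0, 1]³; 1,000-sample training runs, 5,000-sample test
  runs; switch placed in `[T_w + washout, N_tr − T_w]` (training) and
  `[2T_w, N_te − 2T_w]` (test).
* **Coupled Lorenz network** (m = 5): `dx_k = −10(x_k − y_k) +
  c Σ_l a_kl (y_l − y_k)`, `dy_k = 28(1+h_k) x_k − y_k − x_k z_k`,
  `dz_k = −8/3 z_k + x_k y_k`; binary adjacency with 6 random directed
  edges, rewired (edge count preserved) or densified (+8 edges) at the
  switch; `c = 1`, `h_k` uniform in [−0.2, 0.2]; dt = 0.002 sampled every
  6 steps; inits uniform in [−10, 10].
* **Forced Kuramoto–Sivashinsky**: `u_t = −u u_x − u_xx − u_xxxx +
  μ cos(2πx/λ)`, `λ = 12`, domain length L = 60 (a multiple of λ; the
  standard chaotic regime), Q = 128 grid points with every 4th observed
  (32 channels); dt = 0.01 sampled every 20 steps; `μ` switches within
  [−1, 1]; observation noise variance 0.2 (σ ≈ 0.447); a 50-time-unit
  transient is discarded so sampling starts from developed spatiotemporal
  chaos; initial condition a small-amplitude smooth random field.

What the generators do **not** emulate: dynamical (process) noise,
multiple or gradual changes, missing data, non-stationary baselines, and
the sensor artefacts of real physiological or industrial recordings.
Passing tests on these benchmarks therefore demonstrate the mechanism —
readout fingerprints separate evolution laws — not field performance on
real data.

## Benchmark scales and observed behaviour

The error metrics are means of `|t̂_p − t_p|` in **sample indices** (the
effective sampling step differs per system) and of `|Δĥ − Δh|` in the
parameter's own units, averaged over all test runs with no exclusions.
`scripts/acceptance.py` runs Lorenz63 at its full study scale
(500 training / 100 test runs) and the other testbeds at desk scale
(network: 300/30 per change type; PDE: 300/15); measured detection error
had plateaued in training-set size at these scales (doubling the network
training runs did not improve the mean).

Observed behaviour at these settings: the large majority of test runs
localise the switch to within a few `δt` of the truth — often better than
ten samples — while a minority fail catastrophically and dominate the
mean (see Limitations). The regression route is consistently better than
the classification route, raw-data baselines are far worse than readout
features under matched conditions, and the densification change of the
network testbed is easier to detect than random rewiring.

## Numerical choices

* Ridge solves use the Cholesky path of `scipy.linalg.solve` on the
  regularised Gram matrix; `β = 0` falls back to least squares.
* The RLS gain matrix is re-symmetrised after each rank-one update.
* The spectral radius is computed by dense eigendecomposition (reservoirs
  are small; iterative eigensolvers would add start-vector
  nondeterminism).
* ETDRK4 scalar coefficient integrals use the 32-point contour method.
  Non-finite fields abort with a blow-up diagnostic.
* Ties in peak location break to the earliest anchor (favours early
  warning); `t_p` values off the anchor grid are matched to the nearest
  anchor within `δt/2` during labeling.
* KS step-halving agreement is ~1e-9 relative; Lorenz RK4 step-halving
  agrees to 1e-3 only within the chaotic predictability horizon
  (~0.3 time units at dt = 0.02) — beyond it the comparison measures
  chaos, not integrator error.

## Limitations

* **Small switches near the null floor.** When the parameter jump is
  small (Lorenz |Δσ| ≲ 1), the true response bump can fall below the
  spurious fluctuations of the index curve; the argmax then lands
  anywhere, producing a heavy tail of catastrophic position errors that
  dominates the mean even though the median error is a few samples.
* **Relaxation delay.** After a large jump the trajectory takes time to
  settle on the new attractor; the index response can be delayed by
  hundreds of samples, biasing `t̂_p` late for those runs.
* **Classification is the weaker route.** The change signature in
  `ΔW_out` is a direction spread across many coordinates; axis-aligned
  tree splits see it only weakly, so Random Forest class probabilities
  separate changes much less sharply than the linear regression route.
  (Consistently, the norm `‖ΔW_out‖` alone carries almost no contrast —
  the supervised map is essential.)
* One change per series is assumed; the scan reports a single peak.
  Probability calibration of the classification score is out of scope.
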