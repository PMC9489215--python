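# Methods

`oscreen` asks a design question about small transcriptional circuits:
which signed two- and three-node network topologies can not only
oscillate, but keep oscillating *accurately* when the biology is noisy —
and what structural features (motifs) and dynamical features (period,
amplitude) explain the difference.  This note records the models, the
estimators, the numerical choices and the problem sizes the package
uses, and what its synthetic benchmarks do and do not show.

## The deterministic model

Nodes are gene products; links are transcriptional activation (+1) or
inhibition (−1), with competitive-inhibition logic: all transcription
factors regulating a gene compete for the same binding sites, so a
single Hill-form ratio pools every regulator of gene *j*:

    dx_j/dt = k_basal + [ Σ_act v_ij (x_i/K_ij)^3 + δ_j ]
              / [ 1 + Σ_act (x_i/K_ij)^3 + Σ_inh (y_i/K_ij)^3 ]  −  r_j x_j

* `v_ij` — maximal production rate of gene *j* driven by activator *i*
  (concentration/time);
* `K_ij` — binding affinity of protein *i* for gene *j* (concentration);
* `δ_j` — activator-independent production, nonzero exactly when gene
  *j* has no activating input;
* `r_j` — first-order degradation (1/time);
* `k_basal` — leaky basal production, well below every other production
  term;
* the Hill exponent is fixed at 3 (three cooperative binding sites).

The cubic Hill form arises from a quasi-equilibrium treatment of three
sequential TF-binding steps; the model deliberately does not decompose
production into elementary promoter reactions.

## Noise models

**Extrinsic noise** perturbs every kinetic parameter `v_ij`, `δ_i`,
`r_i` multiplicatively by `(1 + ε z(t))`, one independent
Ornstein–Uhlenbeck channel per parameter with relaxation time
`τ_noise = 1` and drive amplitude `σ`, so each channel has zero mean and
stationary variance `σ²/2`.  Defaults: `ε = 0.1`, `σ = √2` (unit channel
variance).  Channels advance by the update

    z(n+1) = z(n) − z(n)Δt + σ δW + ½σ²((δW)² − Δt)

(the second-order term is retained deliberately even though the OU
diffusion is constant; a `milstein=False` switch gives plain
Euler–Maruyama, and at the step sizes used the two differ by a few
percent of channel variance).  Concentrations advance by an explicit
Euler step of the perturbed vector field.

**Intrinsic noise** converts concentrations to copy numbers through a
cell volume `V` (default 100 copies per concentration unit) and treats
production/degradation as birth/death events.  Two engines:

* **Gillespie (SSA)** — exact simulation of the 2n reactions with
  Hill-type birth propensities and linear death propensities;
* **chemical Langevin (CLE)** — `dX = (prod − rX) dt +
  √(prod + rX) dW`, with a small Milstein correction `(r/4)((δW)²−Δt)`
  (the state-derivative of the squared diffusion through self-regulating
  production terms is neglected — it is second order in the step) and
  copy numbers clipped at zero, the standard remedy for CLE negativity.

Only one noise source is active at a time.  Every engine consumes a
single pseudorandom stream per run in a fixed channel order, so runs are
bit-reproducible given (seed, step, config); replicate *k* derives its
seeds from `master_seed + k`.

## The accuracy metric

A noisy oscillation is scored by the dimensionless correlation time
τ/T: the trajectory autocorrelation decays as
`C(t) = exp(−t/τ) cos(2πt/T)`, so the coefficient `c = C(T)` at a lag of
one noise-free period gives `τ/T = −1/log c`.  The estimator is
FFT-based, mean-removed, variance-normalized, with the unbiased
(divide-by-(n−k)) lag normalization, and `c` is linearly interpolated at
the exact deterministic lag T.  Per trajectory the metric is computed on
every node series and the largest value kept.  Degenerate cases:
`c ≤ 0` scores 0 (decorrelated within one period); `c ≥ 1` is capped at
`1 − 10⁻¹²` — doubling an already long correlation time barely moves
`c`, so the cap only affects numerically perfect runs.

A topology's robustness is the 90th percentile (linear-interpolation
convention) of τ/T over its oscillatory parameter sets, averaged over
replicate simulations.

## The two-step screen

The kinetic ranges of the original screen are not published, so the
built-in sampler defines the study conditions and is itself versioned
code: log-uniform `v, δ ∈ [0.1, 10]`, `K ∈ [0.1, 10]`, `r ∈ [0.01, 1]`,
with `k_basal = 0.01` fixed.  The basal rate is the one value that took
calibration: positively autoregulated genes start from the zero state
and can only ignite if their off-state level `k_basal/r` is within reach
of the self-affinity `K`; at `k_basal ≤ 10⁻³` the activator-inhibitor
family and the repressilator-with-autoregulation family never fire at
all, while at `k_basal ≥ 0.05` the leak stabilizes the repressilator
family.  `k_basal = 0.01` — an order of magnitude below the smallest
sampled production rate — keeps every core-motif category discoverable.

Step 1 draws random parameter sets per topology, integrates from the
all-zero state over [0, 1000] and calls oscillation on the [700, 1000]
window: every node must be non-steady (max−min above 10⁻³ of its mean),
and every node's peaks (≥4, found with 1%-of-range prominence and
quadratic apex refinement) must have relative SD < 5% with no decaying
trend (last peak ≥ 95% of the first) — this excludes both steady states
and damped oscillators.  A topology passes with ≥80 oscillatory sets per
10,000 draws, relaxed to ≥10 per 10,000 when it contains a repressilator
(repressilator-containing topologies oscillate rarely but matter; at
other draw counts the thresholds scale proportionally, rounded up).
Periods longer than ~75 time units cannot show four peaks in the window
and are therefore not counted as oscillatory — a deliberate property of
the protocol, not an accident.

Step 2 collects oscillatory parameter sets per passing topology,
recording the noise-free period T, the amplitude (maximal peak over all
nodes) and the full state at node B's highest peak, which seeds the
stochastic runs.  `T_opt` and `A_opt` are the expectations of the
best-fit exponential distributions of the collected periods and
amplitudes — i.e. their sample means, computed once from the noise-free
system and shared by both noise modes.

Category comparisons use one-tailed Wilcoxon rank-sum tests on adjacent
categories (direction: the higher-median category tested as greater),
raw p-values as in the source figures (a multiple-testing switch is out
of scope), Spearman rank correlations of robustness against `T_opt` and
`A_opt`, and a median-betweenness check for combined categories against
their component categories.  Categories with fewer than three scored
topologies are excluded from tests.

## Numerical integration choices

The screen must integrate hundreds of thousands of ODE draws, so the
deterministic engine is a compiled fixed-step RK4 operating on batches
of parameter sets (SIMD over the batch).  Correctness and efficiency
safeguards:

* per-draw step size from a conservative Jacobian-rate bound
  (activating Hill slopes ≤ ~0.9·v/K, pooled inhibitory slopes ≤
  ~1.6·prod_max/K), chosen from {0.05, 0.025, 0.0125, 0.00625} so that
  (rate)·Δt stays inside RK4's stability region;
* integration proceeds in 100-unit segments with an early exit for
  draws whose per-node range over a segment falls below 10⁻⁹ relative —
  strict enough that slow saddle passages or plateau transients are
  never misclassified as steady;
* the evaluation window is recorded on a 0.1-spaced grid (3001 points,
  well above the 2000-point floor needed for peak resolution);
* `simulate_deterministic(..., method="lsoda")` provides the
  stiff-capable reference path (rtol 10⁻⁶, atol 10⁻⁹); the RK4 and
  LSODA paths agree to better than 0.2% on the fixtures and the
  cross-check is part of the test suite.

Stochastic runs use an Euler (extrinsic) or Milstein-form (CLE) step
that is deliberately *period-independent* — extrinsic Δt = 0.05, CLE
Δt = 0.02 — tightened per run only by the explicit-stability bound 1/λ
(λ the same Jacobian-rate bound) and by a 200-steps-per-period floor
for very fast cycles.  A period-proportional step would hand
short-period topologies a slightly weaker discretized OU noise (the
discrete channel variance grows with Δt) and bias every cross-topology
comparison; with the fixed step the few-percent variance excess at
Δt = 0.05 acts as a uniform, slightly larger effective noise amplitude
instead.  Gaussian increments are pre-generated in blocks with numpy's
PCG64 generator.

## Phase-diffusion analytics

For a stable limit cycle `x_s(t)` the variance of the phase deviation
grows linearly, `Var(α(t)) = c·t`, with

    c = (1/T) ∫₀ᵀ v₁ᵀ(t) B(x_s) Bᵀ(x_s) v₁(t) dt ,

where `v₁` is the adjoint Floquet mode of the zero exponent normalized
by `v₁·ẋ_s ≡ 1`.  Implementation: limit cycles are located by transient
integration plus Poincaré-section (peak of node B) returns (LSODA at
rtol 10⁻¹⁰; closure residual < 10⁻⁸ required); the monodromy matrix is
integrated jointly with the orbit; `v₁(T)` is the left eigenvector of
the unit multiplier (identified as the eigenvalue closest to 1, with a
degeneracy guard) and the adjoint equation is integrated backward over
one period — the stable direction for the adjoint — with the
normalization identity checked pointwise to 10⁻⁶ and then enforced
exactly.  `c` is invariant to grid refinement beyond 2000 points per
period to better than 10⁻³ relative.

The extrinsic OU channels are colored, while the phase-diffusion formula
assumes white drive; each channel is replaced by white noise matched to
its zero-frequency spectral density `ε²σ²`.  This reduction is accurate
when the adjoint-weighted noise coefficient `v₁ᵀB(x_s(t))` is dominated
by harmonics well below `1/τ_noise` — i.e. for near-sinusoidal cycles
whose period is long against `τ_noise = 1`.  On spiky relaxation
oscillators the high harmonics see the OU spectrum's roll-off and the
white formula overestimates `c` by tens of percent; the validation
therefore runs on a frozen near-sinusoidal activator-inhibitor set
(`phase_oscillator`, harmonic distortion ≈ 2%), where the Monte-Carlo
oracle — the slope of the crossing-time variance over 150-200
stochastic runs, with phase read off as linearly interpolated upward
mean-crossings of node B — agrees with the analytic `c` within 20%.  Intrinsic noise needs no reduction: the CLE
diffusion gives `BBᵀ = diag(V(prod_j + r_j x_j))` in copy space, and
with the copy-space adjoint `v₁/V` the coefficient is
`c = (1/(TV)) ∫ Σ_j v₁_j² (prod_j + r_j x_j) dt`.

Two rescalings separate period from amplitude causally.  Folding a
timescale `M` into the parameters (`v, δ, r, k_basal → /M`) multiplies
the period by `M` at fixed amplitude; because extrinsic noise magnitudes
track the parameters, extrinsic `c/T` falls as `1/M` (log-log slope −1),
while intrinsic `c/T` is unchanged.  The substitution `x → Nx`
(implemented as `K, v, δ, k_basal → ×N`, `r` unchanged) multiplies the
amplitude by `N` at fixed period; extrinsic accuracy is invariant while
intrinsic `c/T` falls as `1/N`.  The package recomputes both sweeps
numerically rather than asserting the algebra, so they double as
end-to-end validations of the Floquet machinery.

## The synthetic NF-κB scenario

The in-silico counterpart of a synthetic RelA–IκBα yeast circuit:
node B = RelA (positively autoregulated activator), node A = IκBα
(activated by RelA, inhibiting RelA), node C = the MAPK arm (inhibited
by RelA via the phosphatase Msg5, and inhibiting IκBα).  With the C⊣A
affinity `K_CA` effectively infinite the model is the plain
activator-inhibitor; a finite `K_CA` closes the repressilator
A⊣B⊣C⊣A on top of it.  Sweeping `1/K_CA` upward from ~0 with a frozen
oscillatory base parameter set, the period, the amplitude and τ/T under
both noise modes are recorded (mean ± SD over repeated stochastic
simulations per point).  The exact wiring of the published circuit
diagram is reconstructed from its description and is configurable; the
qualitative claim tested — strengthening the added repressilator arm
lengthens the period, raises the amplitude and improves accuracy — does
not depend on the frozen parameter choice in our experiments, but the
quantitative gains do.

## Problem sizes

The full-scale protocol (10,000 step-1 draws per topology, 1000
oscillatory sets, 100·T noise horizons, five replicates, the whole
1955-topology universe) is what `ScreenScale()` defaults encode, and is
the configuration a cluster run would use.  The package's own benchmark
suite runs a reduced profile chosen to keep a complete desk run in
minutes: 500 step-1 draws, 50 oscillatory sets per topology (resampling
capped at 20,000 draws; topologies at the cap are scored on the sets
found, and dropped below 10 sets), 30·T horizons, three replicates, ten
topologies per base category (six for the combined C13 category) taken
in stable-id order among step-1 passers.  Two categories cannot field
ten members at any budget: the whole universe contains only 16 C2 and
24 C4 topologies.  The acceptance script runs a further-compacted
profile (six per category, 30 sets, 25·T, two replicates) for the same
statistics.

## What the synthetic benchmarks show — and what they do not

The generator emulates the screen's study conditions, not any measured
organism: kinetic constants are log-uniform and independent, noise is
either pure parameter fluctuation or pure reaction stochasticity, cells
neither grow nor divide, and the unpublished ranges of the original
screen are replaced by the documented defaults above.  Passing tests
therefore demonstrate that the *algorithms* implement the stated models
and that the *qualitative* design principles (repressilator plus
positive autoregulation beats activator-inhibitor; long period buffers
extrinsic noise; high amplitude buffers intrinsic noise) re-emerge at
reduced scale under these conditions.  They do not certify quantitative
robustness values for real circuits, and full-scale summary numbers
(e.g. the exact count of oscillatory topologies or full-scale Spearman
coefficients) depend on the unpublished kinetic ranges.  At desk scale
the per-category samples are small (3–10 topologies; category C1's
oscillatory parameter sets are genuinely rare — the relaxed
repressilator threshold exists precisely because of that rarity), so
adjacent-category rank tests sit at the edge of statistical power;
median orderings are reported alongside the tests.

## Known limitations

* Hill exponents other than 3, >3-node topologies and mixed
  extrinsic+intrinsic noise are out of scope.
* The CLE clips at zero rather than switching to an exact sampler at
  low copy number; at the default V = 100 the clip is rarely active.
* The oscillation call is window-based and blind to periods beyond ~75
  time units.
* The adjoint machinery assumes a single attracting limit cycle;
  multistable or chaotic parameter sets are rejected, not analyzed.
* Noise-induced oscillation outside the deterministic oscillatory
  regime is deliberately not counted.
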