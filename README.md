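# oscreen

Screening signed transcriptional network topologies for oscillation
that stays **accurate under biological noise**.

Biochemical oscillators — circadian clocks, NF-κB pulses, synthetic
ring oscillators — must keep time despite two very different noise
sources: *extrinsic* noise (kinetic parameters fluctuating with the
cellular environment) and *intrinsic* noise (the stochasticity of
discrete birth/death reactions at low copy number).  `oscreen`
implements a complete computational pipeline that asks which two- and
three-node signed regulatory topologies oscillate robustly against
each source, and why:

1. **Topology space** — enumerate all 3⁹ = 19,683 labeled
   configurations, remove relabeling-symmetric duplicates and
   under-connected networks, leaving a canonical universe of **1955**
   two-+three-node topologies; classify each by its core oscillator
   motifs (repressilator with/without positive autoregulation, the
   activator–inhibitor family, delayed negative feedback → categories
   C1…C5 and combined labels like C13).
2. **Dynamics** — competitive-inhibition Hill ODEs (cubic Hill
   coefficient, pooled regulator denominator), integrated from the zero
   state over [0, 1000] with oscillation called on the [700, 1000]
   window (steady states and damped oscillators excluded).
3. **Noise engines** — Ornstein–Uhlenbeck parameter fluctuations
   (extrinsic), and chemical-Langevin or exact Gillespie simulation of
   copy numbers (intrinsic), all compiled and bit-reproducible.
4. **Accuracy metric** — the dimensionless correlation time
   **τ/T = −1/log c**, where c is the trajectory autocorrelation at a
   lag of one noise-free period; per-topology robustness is the
   replicate-averaged 90th percentile of τ/T over oscillatory
   parameter sets.
5. **Statistics** — one-tailed Wilcoxon rank-sum comparisons of
   adjacent categories, Spearman correlations of robustness with the
   characteristic period (T_opt) and amplitude (A_opt), combined-
   category betweenness.
6. **Phase-diffusion analytics** — Floquet/adjoint computation of the
   phase-noise slope c in Var(α(t)) = c·t, with timescale (M) and
   amplitude (N) rescalings that separate the causal roles of period
   and amplitude: long period buffers extrinsic noise (c/T ∝ 1/M),
   high amplitude buffers intrinsic noise (c/T ∝ 1/N).
7. **In-silico NF-κB circuit** — an activator–inhibitor RelA–IκBα core
   that acquires a repressilator arm as the C⊣A inhibition strength
   1/K_CA grows, reproducing the period/amplitude/accuracy gains of
   the synthetic-biology experiment this model mirrors.

See `docs/methods.md` for the model equations, estimator conventions,
numerical choices and problem sizes.

## A worked example

```python
import oscreen as oc
from oscreen.screen import fixture_library
from oscreen.phase import find_limit_cycle, phase_diffusion_extrinsic

# the classic two-node activator-inhibitor with a frozen oscillatory
# parameter set found by the built-in sampler
t, p = fixture_library()["activator_inhibitor"]
print(oc.assign_category(t).label)

traj = oc.simulate_deterministic(t, p)          # [0, 1000], x(0) = 0
feats = oc.detect_oscillation(traj)
print(f"T = {feats.period_T:.2f}, amplitude = {feats.amplitude:.2f}")

x0 = oc.state_at_b_peak(traj)                    # noise runs start here
tau = oc.measure_tau(t, p, feats.period_T, x0, "extrinsic", seed=1)
print(f"tau/T (extrinsic) = {tau:.2f}")

lc = find_limit_cycle(t, p)
res = phase_diffusion_extrinsic(t, p, lc=lc)
print(f"c/T = {res.c_over_T:.2e}")
```

prints

```
C3
T = 39.47, amplitude = 30.66
tau/T (extrinsic) = 8.86
c/T = 3.63e-03
```

— the topology is the C3 (activator–inhibitor) category; its noise-free
period is ~39.5 time units with amplitude ~31; under the default
extrinsic noise (ε = 0.1, unit-variance OU channels) the
autocorrelation at one period is still high (τ/T ≈ 9, i.e. the clock
stays coherent for roughly nine periods); and the analytic phase-noise
slope per period c/T ≈ 4·10⁻³ quantifies the same accuracy from Floquet
theory.

The command line exposes the batch stages:

```bash
oscreen enumerate -o results          # topologies.json + counts
oscreen screen    -o results          # two-step screen + category report
oscreen nfkb-sweep -o results         # the 1/K_CA sweep table
```

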