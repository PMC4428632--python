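# Methods

## Model and assumptions

The quorum-sensing circuit is modeled as an information channel
ρ → a ⇄ m ⟲: cell density ρ sets the autoinducer (AI) concentration a
through the population's summed output, and each cell encodes a in the
abundance m of a monitor protein (MP) that feeds back on both AI production
(f_ext) and its own expression (f_int).  The analysis rests on:

1. **Quasi-static, well-mixed AI.**  The AI escape time τ_a (default 10 s,
   the diffusion time L²/D for L = 100 μm and D = 10³ μm²/s) is far shorter
   than the MP lifetime τ_m (default 1800 s), so a is an algebraic function
   of the instantaneous state, a = τ_a ρ ⟨f_ext(m_i)⟩.  No ODE for a is
   integrated anywhere, including the simulator.  A warning is raised if a
   parameter set violates τ_a ≤ τ_m/10.
2. **Self-averaging AI.**  In a large population the propagation of MP noise
   into a averages out, so a is a deterministic function of ρ and MP
   fluctuations are independent across cells.  This is assumed in the
   linearized statistics and validated only empirically by the simulator,
   which does couple cells through the shared a.
3. **Small-noise Gaussian encoding.**  At fixed ρ, p(m|ρ) ≈
   N(m̄(ρ), Σ²(ρ)) with m̄ from the fixed-point relations
   a̅ = τ_a ρ f_ext(m̄), m̄ = τ_m f_m(a̅) f_int(m̄) and
   Σ² = F*(m̄)·m̄, where F* = F·(1 − m f_int′/f_int)⁻¹ is the
   feedback-modified Fano function.  Monotonicity of both mean mappings is
   enforced (f_int′/f_int < 1/m); multistable channels are rejected with an
   explicit error rather than a silent branch choice, the fixed-point solver
   scanning a 256-point residual grid for multiple sign changes.
4. **Noise evaluated at the mean.**  The Langevin amplitude σ_m(m̄) =
   √(F(m̄) m̄ / (κ τ_m)) depends on the deterministic mean, not the
   fluctuating state; the simulator integrates a deterministic companion
   trajectory for this purpose.  The noise term is √2·σ_m·dW, the reading
   under which the stationary variance is τ_m σ_m² and the simulated Fano
   factor reproduces F — the simulation tests enforce exactly this
   consistency.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| ρ₋, ρ₊ | detection/saturation densities | 10⁻⁴, 1 | cells/μm³ |
| a₋, a₊ | AI detection/saturation thresholds | 0.1, 10⁶ | nM |
| m₋, m₊ | basal/peak MP abundance | 100, 600 | nM |
| τ_a, τ_m | AI escape time, MP lifetime | 10, 1800 | s |
| T | growth-period duration | ln(ρ₊/ρ₋)·τ_m | s |
| f_int,− , f_int,+ | self-regulation at low/high density | 2, 1/2 | — |
| K, h | Hill constant and coefficient of f_m | 15 nM, 2 | |
| b | transcriptional burst size | 20 | proteins/mRNA |
| v | mean cell volume | 1 | μm³ |

Only the ratio ρ₊/ρ₋ = 10⁴ enters any information quantity; the absolute
values put full confluence at 1 cell/μm³.  The default T makes γτ_m = 1,
i.e. the dilution-limited regime τ_m = T_d/ln 2; T affects only growth-mode
simulation, never the information results (which depend on the growth law
only through p(ρ) ∝ 1/ρ).  Non-exponential growth is supported by supplying
a tabulated density trajectory (`TabulatedGrowthProfile`).

**Units (κ).**  The Fano functions carry 1/volume units, so Σ² = F·m is
consistent only under a convention linking nM to molecules/μm³.  All curves
are kept in nM and the convention enters as a single variance scale,
Σ² = F·m/κ: κ = 1 in `"raw"` mode (nM values treated as pure numbers, the
cell volume absorbing the conversion) and κ = 0.6022 in `"number_density"`
mode (strict molecules/μm³ bookkeeping).  The two differ by
½·log2(1/0.6022) ≈ 0.37 bits in every information value; `"raw"` is the
preset default and is the convention under which the reference four-entry
table is reproduced.  The reproduction report emits both.

**Bare-rate calibration.**  f_m(a) = β₀ + β₁ aʰ/(Kʰ+aʰ) is fixed by the two
boundary conditions τ_m f_m(a±) f_int,± = m±, a linear 2×2 solve; negative
basal or amplitude raises a calibration error.  The **no-feedback baseline**
uses the same construction with f_int ≡ 1, so the baseline channel spans the
same fixed MP range (m₋, m₊) as the feedback channel — the comparison is at
fixed output bandwidth, and the baseline AI course is linear in ρ, anchored
at a₋ (it cannot reach a₊ with a constant output rate; this is inherent,
not an error).  Consistently, the sRNA saturation scale m∞ =
max(m₊, m₊/f_int,+) is a property of the channel at hand: m∞ = m₊/f_int,+
for a channel with high-density self-repression, m∞ = m₊ for the
no-feedback baseline.

## Information computations

* **Discretized channel.**  512 log-spaced density points (so the 1/ρ input
  is uniform on the grid) × 512 linear MP bins; rows are bin-integrated
  Gaussians (differences of normal CDFs), keeping row sums exact.  Default
  truncation `"hard"` restricts the grid to the mean curve's range and
  renormalizes; `"none"` extends the grid by 6 standard deviations so rows
  are effectively untruncated.  Both modes are reported where the choice
  matters; every reported value carries a grid-doubling check (< 10⁻³ bits
  drift for both grids at the defaults).
* **Small-noise MI** is the 1-D quadrature
  H_ρ + ∫ p log2(m̄′/(√(2πe)Σ)) dρ, flagged as an approximation; it is a
  lower bound because it neglects the noise contribution to the output
  entropy, and the suite asserts it never exceeds the exact value.
* **Small-noise capacity** C = log2 ∫ dρ/(√(2πe) δ_ρ) with resolution
  δ_ρ = Σ/m̄′, achieved by p*(ρ) ∝ 1/δ_ρ; the equivalent MP-domain integral
  is computed as a cross-check.
* **Blahut–Arimoto** returns the lower Arimoto bound with the upper bound in
  the diagnostics; default tolerance 10⁻⁶ bits on the bracket.  On these
  nearly continuous channels convergence is sublinear, so capacity
  comparisons at the 10⁻²-bit scale use a 10⁻⁴-bit tolerance, reached in
  ~10⁴ iterations at the default grids.

## Optimal feedbacks

Maximizing the small-noise MI over (f_ext, f_int) decouples: the internal
feedback sets the noise profile of the detection channel, and the external
feedback matches the input to it.  The stationary solution has
Σ*(m) = F(m)/(√κ c) with c² = ln(m₊ f_int,− / (m₋ f_int,+)) / ∫dm/F, giving
f_int*(m) = f_int,− (m/m₋) exp(−c² ∫_{m₋}^{m} dm′/F) (the stability factor
is then m c²/F > 0 automatically) and the optimum
I* = ½ log2( ln(m₊ f_int,−/(m₋ f_int,+)) · κ ∫ dm/(2πe F) ).
The optimal mean response is generalized histogram equalization,
m̄*(ρ) = Q⁻¹(P(ρ)) with Q the normalized cumulative of 1/Σ*; the output
density is then q(m) ∝ 1/Σ*(m), reducing to classical equalization when Σ*
is constant (TF regulation: m̄* linear in time).  The AI course and external
feedback follow by inverting the self-consistency relation.  All integrals
have closed forms for the two Fano models and are verified against
quadrature.

Because this closed form is a derivation, it is validated by an independent
**variational oracle**: a multi-start L-BFGS maximization of the small-noise
functional over (i) ln f_int values on a 16-knot MP grid with pinned
endpoints and (ii) monotone, boundary-pinned mean mappings parameterized by
positive increments on an input-quantile grid.  Written on the quantile
grid the functional is ⟨log2((dm/dP)/(√(2πe)Σ))⟩_P, with no explicit
density terms.  At b = 1 the oracle agrees with the closed form to better
than 10⁻³ bits for both regulation models, and its optimized Σ(m) is
proportional to F(m) within knot-discretization error.

## Simulator

Euler–Maruyama with default dt = τ_m/500 (refusing dt > τ_m/100);
trajectories are clipped at zero — a reflecting-boundary stand-in whose
bias is negligible except where Σ/m̄ approaches ~0.5 (e.g. the TF model at
m ≈ m₋, where the clipping shifts the mean by ~1%).  Strongly nonlinear
feedbacks (f_int ∝ 1/m at 20% relative noise) also shift the stationary
mean by a few SE via drift curvature, while leaving the Fano factor within
a few percent of the linearized prediction — the validation suite therefore
checks means on the low-noise sRNA baseline and Fano ratios on the TF
model.  Stationary statistics use an exponential fit to the pooled
autocorrelation function (lags above ACF = 0.2) and an effective sample
size N·T_seg/(2τ̂) for standard errors.

## What the tests do and do not show

The synthetic study conditions are exactly the preset above: deterministic
exponential growth, a homogeneous AI pool, Gaussian gene-expression noise
summarized by two idealized Fano functions, and feedbacks that are smooth
functions of MP abundance alone.  Passing tests show internal consistency
of the theory, its closed-form optimum, and the simulator — not that real
*V. harveyi* circuits achieve these numbers.  Not modeled: receptor-level
kinase cascades, cell-division partitioning noise, spatial AI gradients,
finite-population (extrinsic) AI noise, multiple AIs/MPs, and fitness
interpretations of the information values.

## Known limitations

* The "operates at capacity" statement is a small-noise result.  The exact
  (Blahut–Arimoto) capacity of the optimal-feedback channel at b = 20
  exceeds the 1/ρ-input MI by ≈ 0.14 bits, and by ≈ 0.07 bits even at
  b = 1: a bounded-support edge effect of order Σ/(m₊−m₋) that does not
  vanish with burst size, because the optimal Σ* is set by the feedback
  budget rather than by b.  The corresponding acceptance check asserts the
  0.05-bit matched-input bound as specified and is expected to fail at the
  preset; the capacity-dominance check (no input beats Blahut–Arimoto)
  passes.  The same edge effect is why the exact MI approaches the
  small-noise capacity only when the noise amplitude itself is scaled to
  zero, which is how the convergence property is tested.
* Growth-mode simulation tracks the quasi-static fixed points to ~1% only
  for γτ_m ≪ 1; near γτ_m = 1 the lag reaches ~20% where the external
  feedback is positive (lag is self-amplifying there).
* The Blahut–Arimoto input grid is the 512-point density grid; its capacity
  is that of the discretized channel, which upper-bounds what the continuous
  1/ρ input achieves but is itself grid-dependent at the ~10⁻³-bit level.
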