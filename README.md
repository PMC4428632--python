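# qscensus

Information-channel analysis of bacterial quorum sensing.

Bacteria such as *Vibrio harveyi* estimate their local cell density ρ by
producing and detecting diffusible autoinducers (AI), and represent the
result internally in the abundance *m* of a monitor protein (MP, e.g. LuxR).
The MP typically feeds back both on AI production (an **external feedback**
f<sub>ext</sub>(m), the per-cell AI output rate) and on its own expression
(an **internal feedback** f<sub>int</sub>(m), a self-regulation factor).
`qscensus` treats this circuit as a noisy information channel
ρ → a ⇄ m ⟲ and answers, quantitatively, how many bits about density a
single cell can read out of its MP level — and which feedbacks maximize
that number.

## The model

Over a growth period the density rises exponentially from ρ₋ to ρ₊, so the
input distribution is p(ρ) ∝ 1/ρ.  The AI concentration is quasi-static,
a = τ_a ρ ⟨f_ext(m)⟩, and each cell's MP follows a Langevin equation

    dm = ( −m/τ_m + f_m(a) f_int(m) ) dt + √2 σ_m dW ,

with f_m a Hill activation curve (constant K, coefficient h) and expression
noise summarized by the Fano function F(m) = τ_m σ_m²/m̄: F = (1+b)/v for
direct transcription-factor (TF) regulation and F(m) = (1 + b·m/m∞)/v for
regulation through a small RNA (sRNA), with burst size b and cell volume v.
At fixed density the channel is Gaussian, p(m|ρ) ≈ N(m̄(ρ), Σ²(ρ)), where
m̄(ρ) solves the mean-field fixed-point relations and the internal feedback
rescales the noise, F*/F = (1 − m f_int′/f_int)⁻¹.

The package computes the mutual information I(m; ρ) three ways — a
small-noise quadrature lower bound, the exact discretized-channel value, and
the Blahut–Arimoto channel capacity — and constructs the
information-optimal feedbacks in closed form: the optimal noise profile
satisfies Σ*(m) ∝ F(m), and the optimal mean response is a generalized
histogram equalization that matches the input CDF to the channel's inverse
noise.  A direct multi-start variational optimizer over knot-parameterized
curves serves as an independent check of the closed form.  A stochastic
population simulator (Euler–Maruyama, shared quasi-static AI) validates the
linearized statistics.

## Worked example

```
$ python examples/information_table.py
regulation  feedback   MI (bits)  states
tf          none          1.142  2-3
tf          optimal       1.308  2-3
srna        none          1.372  2-3
srna        optimal       2.113  4-5
```

Each row is the exact mutual information between cell density (input
p(ρ) ∝ 1/ρ spanning ρ₊/ρ₋ = 10⁴) and the MP readout, at the built-in
preset (a₋ = 0.1 nM, a₊ = 1 mM, m₋ = 100 nM, m₊ = 600 nM, K = 15 nM,
h = 2, b = 20, v = 1 μm³, self-regulation boundary levels
f<sub>int,−</sub> = 2, f<sub>int,+</sub> = 1/2).  2^MI is the number of
density ranges a cell can distinguish: optimal feedback barely helps TF
regulation (the positive feedback needed to escape the noisy low-expression
regime cancels its own benefit) but buys the quieter sRNA channel ~0.7 bits,
doubling the resolvable density stages from two to four.

Other examples: `optimal_feedbacks.py` (the optimal f_int*/f_ext* curves),
`capacity.py` (small-noise capacity vs exact MI vs Blahut–Arimoto),
`population_simulation.py` (simulated Fano factor vs the feedback
prediction).

A thin CLI wraps the same functions:

```
qscensus table1   --out out/           # the table above, all conventions
qscensus optimize --out out/           # optimal curve exports (CSV)
qscensus sweep    --out out/ --model srna   # MI over (b, f_int,+)
qscensus simulate --out out/ --seed 1  # trajectory CSVs + manifest
```

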