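# polwave

Genome-wide RNA polymerase II elongation dynamics from drug time-course
GRO-seq, as a tested Python library.

When transcription is blocked at initiation (Triptolide) or at
promoter-proximal pause escape (Flavopiridol), polymerases already in the
gene body keep elongating and leave behind a 5′ "inhibition wave": a cleared
region whose front advances at the local elongation rate. `polwave`
implements the computational machinery around this idea:

* **Wave-front calling** — a two-state hidden Markov model over binned
  treated/control read-count ratios, digitized to 41 levels on [0, 2] at
  step 0.05 and modeled as binomial emissions *B(n, e)*. The topology is
  unidirectional (*affected → unaffected*); Baum–Welch estimates
  (e₁, e₂, p₁₁) and the transition point is the posterior-0.5 crossing.
  The same machinery with binary *B(2, e)* emissions calls transcription
  units genome-wide (Viterbi) and transcription-unit ends.
* **Elongation rates** — v = Δx/Δt between wave fronts in the early
  (5–12.5 min), mid (12.5–25 min) and late (25–50 min) windows; the
  acceleration constant *a* with v_end = v_start · a^Δt; exon-density
  correction and the additive per-exon delay; the density-vs-inverse-rate
  (D vs v⁻¹) flux test; log–log LOESS production-rate slopes.
* **Pausing kinetics** — promoter peak calling (maximal 10-bp window →
  250-bp peak), pausing index, spike-normalized fold changes with Fisher
  exact significance, and bootstrap fits of first-order decay
  R_t = R_WT·e^(−λt) (half-life ln2/λ, 1000 resampled nonlinear fits per
  gene).
* **Saw-tooth relative rates** — intronic RNA-seq gradients aligned at the
  3′ splice site; steeper (normalized) gradients mean slower polymerases.
* **Kinetic Monte Carlo simulator** — polymerases enter at rate *r*, move by
  Poisson(v·Δt) steps with v(x, A) from cubic Bézier surfaces, terminate at
  k_t(x, A), collide (the leading polymerase terminates); model families
  {acceleration, termination, mixed, regional_termination} are discriminated
  by the (Δv_a/Δx, ΔD⁻¹/Δx) slope plane.
* **Rate determinants** — rank-based inverse-normal (rank-z) feature
  transforms, multivariate least squares with a nested R² ladder, 6-mer
  enrichment, and the iterative dependency analysis (a secondary feature is
  a proxy when a primary explains >66% of its correlation).
* **Synthetic data** — generators for every input (wave tracks, decay
  series, saw-tooth coverage, feature tables with planted effects), each
  with a recorded ground truth, so the whole pipeline is testable offline.

## Worked example

`examples/wave_elongation_rates.py` plants five genes at 1.5 kb/min,
generates drug time-course coverage, calls the fronts and derives rates:

```
planted rate 1.5 kb/min; true fronts (bp): {12.5: 18750, 25.0: 37500}
gene0: front  19000 ->  38000 bp, v = 1.52 kb/min
gene1: front  18000 ->  38000 bp, v = 1.60 kb/min
gene2: front  19000 ->  36000 bp, v = 1.36 kb/min
gene3: front  18000 ->  36000 bp, v = 1.44 kb/min
gene4: front  18000 ->  38000 bp, v = 1.60 kb/min
```

Each front is the HMM's posterior-0.5 crossing on 1-kb (12.5 min) and 2-kb
(25 min) ratio bins; rates are front displacement over the 12.5-min window
and scatter around the planted value within the one-bin calling resolution.
The other examples cover pausing half-lives (`pause_decay_half_life.py`,
mean recovered half-life 6.88 min against a planted 6.9), saw-tooth slopes,
simulator model discrimination, and the determinant model (R² ladder
0.157 → 0.239 → 0.296 for a 0.30-variance plant).

## Layout

```
src/polwave/        genomic_io, synthetic_data, pause_dynamics, wave_hmm,
                    elongation_rates, sawtooth_rates, pol2_simulator,
                    rate_determinants, orchestrator, cli
examples/           one narrative script per capability
tests/              unit + property + end-to-end acceptance tests
docs/methods.md     model assumptions, parameter choices, limitations
```
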