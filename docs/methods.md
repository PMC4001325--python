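# Methods

This note documents the models implemented in `polwave`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## Coordinate and format conventions

All intervals are 0-based half-open. Coverage is held as bedGraph-style
run-length arrays (one file/track per strand), so write-then-read
round-trips are exact and region sums are computed without re-binning
artifacts. Gene-anchored offsets ("+1 kb from the TSS") are
transcription-direction coordinates: the TSS is 0 and positions grow toward
the polyA site on either strand. Densities divide by *mappable* bp; bins
that are fully unmappable carry an undefined (NaN) density rather than 0.
Spike-in normalization is a single-reference ratio: scale_i =
spikes[ref]/spikes[i], the simplest scheme consistent with scaling libraries
to exogenous spike-in reads.

## Inhibition-wave HMM

Per gene and timepoint, treated and control coverage is binned from the TSS
over a 60-kb analysis span (150 kb at 50 min), with bin sizes 500 bp, 1 kb,
2 kb and 5 kb at 5, 12.5, 25 and 50 min so a gene contributes roughly 30–40
bins. Bin ratios treated/control are normalized by the mean of the last
five 3′ bins (the wave has not reached there), clipped to [0, 2] and
digitized at step 0.05, giving integer states 0..40. Bins with zero control
counts are dropped; a gene with >20% such bins is discarded.

Emissions are binomial *B(n, e_s)* with n = 40 by default so the support
covers all 41 states; n is configurable (the binary TU variant uses n = 2).
The two hidden states are *affected* (low ratios, e₁) and *unaffected*
(e₂ ≈ 0.5, i.e. ratio ≈ 1); transitions are unidirectional
(p₂₁ = 0). Baum–Welch updates (e₁, e₂, p₁₁) with emission initialization
e₁ = 0.1, e₂ = 0.5 and p₁₂ = 1/n_bins; convergence is a maximum parameter
change below 10⁻⁶ within 200 iterations (1000 for genome-wide TU calling);
non-convergent or degenerate (all-identical observations) fits drop the
gene. The log-likelihood is non-decreasing across iterations and this is
asserted in tests.

The initial distribution puts mass 0.999 (not 1.0) on the affected state: a
treated gene starts cleared at its 5′ end, but exact unit mass would force
the first bin's posterior to 1 and make an entirely unaffected gene
(wave front at 0) unrepresentable.

The transition point is the 3′ edge of the last bin whose posterior
P(affected) ≥ 0.5 (forward–backward); a Viterbi-changepoint mode is
available and the two agree on clean data, as does an exhaustive
two-segment maximum-likelihood scan (three-way oracle test). Replicate
transition points must agree within max(1 bin, 20% of their mean).
Genome-wide TU calling uses binary 200-bp occupancy bins, full two-way
transitions and Viterbi decoding; divergent TU pairs are sense/antisense
units starting within 2 kb. TU-end calling runs the unidirectional chain
started in the *active* state from the TSS to 50 kb past the annotated 3′
end; genes ending before the analysis span are flagged premature.

## Pausing kinetics

Peak search windows are [−500, +500) bp around the TSS (sense) and
[−1000, +500) (divergent, antisense); 10-bp windows are centered on
multiples of 10 bp and ties go to the most 5′ window, so the caller is
deterministic. The peak is the 250-bp region centered on the maximal
window (shifted inward at chromosome edges). The pausing index divides the
peak density by the gene-body density (+1 kb to the polyA site), with a
pseudo-count of 1 read added to each region count so the index is finite.

Fold changes between treated and control use pseudo-counted, spike-scaled
densities; significance is a Fisher exact test on the raw 2×2 table
[region reads vs rest-of-library reads] × [treated vs control]. The margins
choice (region vs rest-of-library, not vs flanks) is a documented decision.
Raw p < 0.05 defines increase/decrease calls; no multiple-testing
correction is applied, mirroring the source analysis, and this is a
deliberate non-goal.

Decay fitting resamples the available (time, count) datasets n-of-n with
replacement 1000 times and fits R_t = R_WT·e^(−λt) by nonlinear least
squares; λ is the mean over converged draws, its sd the bootstrap sd, and a
fit is high-confidence when sd < 0.5·λ. A gene is rejected when fewer than
half the draws converge. The fitter is a vectorized Gauss–Newton (all
bootstrap draws solved simultaneously; log-linear initialization,
relative-step tolerance 10⁻⁸, λ clamped to [−0.5, 5] /min), validated
against `scipy.optimize.curve_fit` in a unit test; this keeps 500 genes ×
1000 draws inside a few seconds.

## Elongation rates and kinematics

Rates are v = (x₂−x₁)/(t₂−t₁) between consecutive wave fronts; windows are
early (5–12.5), mid (12.5–25) and late (25–50 min). A front that moves
backward is rejected as non-physical. The acceleration constant is read
multiplicatively, v_end = v_start·a^Δt with Δt the gap between window
midpoints (a literal product a·Δt is dimensionally inconsistent); a linear
alternative sits behind a flag.

Exon correction regresses rate on exon density (exons/kb) over the per-gene
transition regions with density > 0 and subtracts the trend around the
cohort mean. The additive per-exon delay is the slope of traversal time per
kb (60/v seconds) on exon density: under a time budget of
60/v = 60/v₀ + δ·d, δ is exactly the seconds added per exon, and a planted
30-s delay is recovered to machine precision. (Regressing total region
traversal time on exon count is degenerate for wave-derived rates, because
a transition region is traversed in exactly the window duration by
construction.)

The D-vs-v⁻¹ test normalizes both series at the most-downstream measured
point and calls a profile acceleration-consistent when v⁻¹ ≥ D − tol at all
positions from the average 5-min front (2.3 kb) on; the default tolerance
is one pooled standard error of the density profile. Production-rate
analysis uses log–log LOESS (span 0.75) with slopes from central
differences of the fit, averaged over the lower and upper predictor halves.

## Saw-tooth relative rates

Introns ≥ 10 kb are selected, split at annotated alternative exons, grouped
in 10-kb length bins (10–50 kb used for estimation), aligned at their 3′
splice sites and profiled in 100-bp windows; pooled window densities are
normalized by the group's density over the last kb before the 3′SS. The
distance coordinate increases 3′SS → 5′, so a steeper *positive* slope
means slower Pol II. For the generative model used in testing (expected
intronic density c·(1 + d/(v·τ)), dwell constant τ = 60 s), the exact
invariant after normalization is slope/intercept = 1/(v·τ); halving v
doubles it, and cohort slopes order by planted rate quartile.

## Kinetic Monte Carlo simulator

Each template evolves in Δt = 1 s steps. Entries occur with probability
1−e^(−rΔt) (blocked when position 0 is occupied); each polymerase carries
an activity percentile A ~ U(0, 100) fixed at entry; termination fires with
probability 1−e^(−k_tΔt); movement advances k ~ Poisson(v·Δt) bases. The
Poisson draw is defined by the inverse CDF applied to a uniform number; the
kernel uses numpy's native Poisson sampler (identical law) and a faithful
`poisson_inverse_cdf` helper is provided and tested. A trailing polymerase
that would land on or pass the one ahead removes the *leading* polymerase;
the footprint is 1 bp. Event conservation (entries = terminations +
run-offs + residents) and strict per-template ordering are asserted
invariants.

Rate surfaces v(x, A) and k_t(x, A) interpolate anchors with cubic Bézier
segments whose control points sit at 1/3 and 2/3 of each span holding the
endpoint values — a smooth monotone ease curve that hits every anchor.
Presets: acceleration (v: 5 bp/s at x = 0 → 40 bp/s at 60 kb, k_t = 0),
termination (v a function of A alone, k_t falling from k_t(A=0) ∈
[0.0005, 0.002]/s to 0 at A = 100), mixed (product of the two v surfaces,
termination's k_t), and regional termination (k_t additionally scaled up
with x so slow polymerases survive only near the 5′ end; the x-profile is a
documented parametric choice, not a fidelity claim).

Defaults are desk-scale: 200 templates (flag for 1000), 100-kb genes,
10,000 s equilibration, snapshots every 100 s during a 3,000-s wave phase
driven by entry decay r(t) = r₀e^(−t/τ_r), τ_r = 60 s (entries < 1% of
initial by 5 min). The default entry rate r₀ = 0.02/s gives realistic
occupancy (~1 polymerase/kb at 20 bp/s); the steady-state flux law D = r/v
is verified in the dilute regime (r = 0.005/s), where collision losses are
~2% — at higher occupancy the recurrent-random-walk collisions of the
movement model deplete density measurably, which is physics of the model,
not an estimator bias. Snapshot/steady-state ratios are analyzed by the
same regional HMM as real data; apparent rates v_a come from consecutive
fronts, and the (Δ(1/D)/Δx, Δv_a/Δx) slope pair — least-squares fits on the
x = 5, 15, ..., 55 kb grid — separates acceleration from termination
ensembles (nearest-centroid classification, >90% leave-one-out accuracy in
the acceptance test at 40 templates/run).

## Rate determinants

Features are transformed with rank-based inverse-normal z-scores,
z_i = Φ⁻¹((rank_i − 0.5)/n); the (i−0.5)/n convention avoids infinite
extremes, and ties are ordered by a seeded random permutation so the output
is always a permutation of a fixed quantile set. Multivariate fits are
ordinary least squares on z-scores with a nested R² ladder; per-feature PCA
directions are the leading eigenvectors of the 2×2 correlation with the
rate. The dependency analysis fits rate ~ primary, re-rank-z-transforms the
residuals, fits them to the secondary, and reports
1 − R²(residual ~ 2°)/R²(rate ~ 2°); a secondary is dependent above 0.66.
One pipeline seed governs all tie-breaking. 6-mer enrichment counts all 4⁶
k-mers on the transcribed-sense sequence with a pseudo-count of 1 per
k-mer per group and reports slow/fast ratios in RNA alphabet.

## Synthetic data: what it does and does not emulate

Generators are deterministic under a fixed seed and ship a JSON truth
sidecar. Noise is Poisson per bin everywhere, matching count data. Wave
tracks place the front at the deterministic kinetic prediction x(t) from
dx/dt = v(x) with flux-conserving control coverage (~uniform for constant
v) and Poisson reads at a configurable depth; default test depth (50–100
reads/kb) matches the sparsity regime of ~30–40 informative bins per gene.
Replicate structure is two per timepoint with an option to drop one.
Feature tables plant a three-coefficient linear model; when a target
explained variance is requested, the noise is projected orthogonal to the
design and scaled against the realized sample variance of Xβ, so the
planted variance decomposition holds exactly in the cohort (under a
population calibration the sample R² at n = 938 fluctuates with sd ≈ 2.5
percentage points, which would swamp the ±3-point recovery check the model
is held to).

Not emulated: mappability biases, PCR duplicates, library-prep artifacts,
fractional drug uptake kinetics, between-gene rate heterogeneity within one
track set (rates are planted per cohort), and genuine ChIP-seq feature
distributions (feature tables are Gaussian by construction). Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to every artifact of real libraries.

## Pipeline

`orchestrator.run_pipeline` executes io → wave → rates → pause → sawtooth →
determinants from a JSON/YAML config, filling missing inputs from the
synthetic presets, and writes every output with a sha256 manifest;
identical config + seed reproduce the manifest byte-for-byte. Per-stage
seeds derive from the global seed by hashing stage names (crc32), all below
2³¹.

## Known limitations

* The HMM assumes one monotone wave per gene; internal initiation or
  enhancer transcription must be filtered upstream (TU pairing does this).
* Binomial emissions treat digitized ratio states as B(40, e) draws — a
  computational device, not a count model; its adequacy is established by
  recovery tests, not theory.
* The bootstrap decay sd underestimates uncertainty when timepoints are few
  and counts large (resampled sets often coincide).
* Simulator collisions make the strict D = r/v law dilute-regime only.
* LOESS slopes depend mildly on the span (0.75 default); production-rate
  conclusions are directional, not absolute.
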