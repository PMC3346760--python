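# Methods

This note documents the models and procedures implemented in `lfp2spike`,
the defaults chosen where the design was open, and what the synthetic
benchmark does and does not establish.

## Signals and preprocessing

A recording bundle holds one LFP trace (uniformly sampled), the sorted spike
times of one unit, and stimulus onset times with integer location labels.
Raw wideband traces can be band-pass filtered (zero-phase forward–backward
Butterworth, 4th order per pass; the band edges are the only tuning knobs)
and downsampled with polyphase anti-aliasing; the reference settings are
1–100 Hz and 0.5 kHz for the LFP band.

Model inputs are built from the full-length trace and only then cut into
trials, so derivative and phase estimates carry no per-trial edge artifacts:

* `x1` — the LFP, optionally convolved with the spike-triggered average
  (STA). The STA half-window default is 20 ms, bracketing the 15–20 ms
  evoked latency; whether the kernel is applied at all is a configuration
  flag (`use_sta`), because on synthetic ground-truth data the STA would
  have to be computed from the very spikes being generated.
* `x2` — the time derivative of `x1` (central differences, one-sided at the
  edges, scaled to units/s).
* `x3` — the instantaneous Hilbert phase of `x2`, radians in (−π, π].

Each feature is z-scored globally — mean and population (divide-by-N)
standard deviation over all trials and bins jointly — so the three inputs
are dimensionless and comparable. Spike trains are binarized on half-open
2-ms bins aligned to stimulus onset; multiple spikes in a bin clip to 1.
The PSTH is the across-trial mean of this matrix.

## Stimulus-coding metrics

**Spike responsiveness (mutual information).** Spike counts are collected in
a post-stimulus window and a pre-stimulus window of equal duration, giving
two equiprobable categories; the plug-in MI

    I = Σ_s p(s) Σ_n p(n|s) log2 [ p(n|s) / p(n) ],   p(s) = 1/2

is bounded by 1 bit. Finite trial counts bias the plug-in estimate upward,
so the category labels are permuted over the pooled counts `n_rep` = 100
times; the mean shuffled MI estimates the bias and is subtracted, and the
standard deviation across repetitions is reported as the estimate's
intrinsic noise. An estimate is flagged *reliable* when that noise is below
5% of the smaller marginal entropy, min(H(s), H(n)). The window search runs
5–50 ms in 5-ms steps per stimulus location and keeps the largest reliable
value; ties break toward the smaller window, then the lower location label.
The exact bias-correction algebra is isolated in one function
(`corrected_mi`) so an alternative estimator can be swapped without touching
callers. Two estimator caveats are documented by tests: with very few trials
whose counts are all distinct, every shuffle separates the categories
perfectly and the shuffle spread is exactly zero; and the per-table
magnitude comparison |corrected| < |plug-in| on null data holds in roughly
85–90% of tables, not more — when the plug-in estimate happens to fall below
its expected bias, the corrected value overshoots negative. The estimator's
*aggregate* bias on null data is near zero, which is the property the
correction is for.

**LFP responsiveness.** From the trials × delays response matrix `r` with
per-delay means `m_t` and grand mean `m̄`:

    V_sig  = mean_t (m_t − m̄)²          (evoked variance)
    V_noise = mean_{k,t} (r_kt − m_t)²   (trial-to-trial fluctuation)
    R_LFP  = sqrt( max(0, V_sig − V_noise/N_tr) / V_noise )

The `V_noise/N_tr` subtraction removes the residual contribution of
stimulus-independent fluctuations to the trial average (for pure noise,
E[V_sig] ≈ V_noise/N_tr, so R_LFP ≈ 0); a deterministic response returns an
infinite sentinel. R_LFP is invariant to offset and positive rescaling of
the trace.

**Spectral Ratio.** Welch PSDs (2-s segments, 50% overlap) of the
spontaneous and stimulated trace segments are interpolated onto a fixed
131-point grid (1.0 to 40.0 Hz in 0.3-Hz steps) and SR is the arithmetic
mean of the per-frequency power ratios: exactly 1 for identical spectra,
unbounded above, so a strong narrowband enhancement can drive SR orders of
magnitude past 1.

## The predictive model class

A genome is an operator triple `(j1, j2, j3)` indexing an operator set `U`
plus convex weights `(w1, w2, w3)` (nonnegative, summing to 1). The default
`U` holds four odd, sign-preserving unary functions of a z-scored input —
identity, signed square x·|x|, cube, signed square root — spanning
compressive and expansive nonlinearities; |U| = 4 gives 64 structures. The
set is configuration, not dogma, and all recovery tests use synthetic data
generated by a genome of this same class.

The continuous model output is thresholded to a binary prediction with a
rank-based Heaviside: θ is the (n_sp+1)-th largest output value, with ties
resolved by earlier (trial, bin) position, so the prediction emits exactly
the observed number of spikes n_sp. θ is recalibrated on whatever data
subset a genome is evaluated on (training n_sp for training costs,
validation n_sp for validation costs). Because the threshold is rank-based,
predictions are invariant under any strictly increasing transform of the
model output.

## Cost functions

All three objectives are minimized and anchored so 0 = perfect, 1 = chance.

**Spike Match.** H is the count of mismatched bins over the flattened
trials × bins array (length T, k ones in the truth). A count-matched
prediction placed uniformly at random overlaps the truth in k²/T bins on
average, so its expected Hamming distance is E[H] = 2k(1 − k/T); SM =
H / E[H]. The closed form is verified against exhaustive enumeration of all
placements for every T ≤ 8 in the test suite. Degenerate truths (k = 0 or
k = T) score 0 on an exact match and a large finite sentinel (10³)
otherwise, so such genomes are dominated without NaN propagation.

**PSTH Fit.** PF = RMSE(PSTH_pred, PSTH_true) / sqrt(E[MSE_chance]), where
the chance mean squared error has a closed form: the distance between the
flat PSTH at the truth's mean rate and the true PSTH, *plus* the
hypergeometric sampling variance of a random count-matched prediction's
PSTH, (k/T)(1−k/T)(T−N_tr)/(N_tr(T−1)) per bin. Dividing by the flat-PSTH
distance alone — the more obvious choice — violates the chance anchor: the
Monte-Carlo chance mean comes out near 1.3 rather than 1 because a random
prediction's PSTH scatters around flat. With the variance term included,
E[PF²] = 1 exactly at chance and the Monte-Carlo mean of PF sits within
about 2% of 1 at practical response sizes. A flat-PSTH prediction therefore
scores slightly below 1: it carries none of the sampling variance a random
placement would. SM = 0 forces PF = 0 (identical responses have identical
PSTHs).

**Complexity Order.** CO = H(w)/log2 3, the normalized base-2 entropy of the
weight triple: 0 for one-hot weights (single-feature model), 1 for uniform
weights. Any strictly Schur-concave function would preserve these anchors;
the choice is isolated in one function.

## Optimization

The search is an elitist NSGA-II over the mixed discrete/continuous genome:
fast non-dominated sorting, crowding distance, binary tournament on
(rank, crowding), offspring count equal to the population, merge-and-
truncate by rank then crowding. Two departures from the textbook algorithm:

* **Restricted mating** — crossover is allowed only between parents sharing
  an operator structure (each weight copied from a uniformly chosen parent,
  then renormalized to the simplex; an all-zero draw is re-tossed). When the
  tournament winner's structure is a singleton in the population, the
  offspring is a mutated clone.
* **Stratified initialization** — the reference protocol sizes the
  population so each structure is represented (320 = 5 × 64); the
  initializer deals structures out in a shuffled balanced deck rather than
  sampling with replacement, which at small populations would leave ~1/e of
  the structures uncovered at generation 0. Weights start uniform on the
  simplex (flat Dirichlet).

Mutation is per-gene: each operator slot independently switches to a
different operator with probability 0.1, and each weight independently
receives a Gaussian(0, σ²) nudge (σ = 0.1 by default) with the same
probability, followed by clip-at-zero and renormalization. Defaults follow
the reference protocol: population 320, 50 generations, mutation probability
0.1. Trials are split 50/50 by alternation (even-indexed trials train,
odd-indexed validate); the final training Pareto front is re-scored on the
validation half and its validation-non-dominated subset returned. The whole
run is a pure function of the data and the seed. `above_chance` applies the
mean(PF) − std(PF) < 1 rule (population std) to the validation front, and a
knee-point selector (nearest front member to the origin in (SM, PF)) is
provided as a labelled convenience extension.

**Known limitation — structure recovery at small budgets.** With the default
operator set all four operators are strictly monotone, so on data with a
strong evoked component every structure attains a Spike Match within a few
percent of the optimum at its own best weights; distinguishing structures
requires refining weights within each structure. At a scaled-down budget
(population 64 ≈ one individual per structure, 20 generations), restricted
mating has nothing to recombine, truncation drives most structures extinct
within a few generations, and the search typically converges to a
near-equivalent wrong structure: across 10 seeded noise-free runs the exact
generating structure was recovered with all weights within 0.1 in 0–2 runs
(and in 1 of 3 runs even at the full 320/50 budget). A planted true genome
does survive to the validation front, so selection and front logic are
sound; the budget simply cannot refine 64 structures in parallel. Exact
structure identification at desk scale should not be expected from this
algorithm class; what the fits do deliver reliably is a validation front
whose best Spike Match approaches the attainable optimum (0.005–0.07 above
it in the runs above).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
defaults matching the reference stimulation protocol:

* **Protocol** — pulses in couplets: first pulses on an exact 500-ms grid,
  each second pulse following by a uniform 50–250 ms delay; 5-ms pulses;
  labels cycle over 5 locations couplet by couplet; 500 couplets (1000
  pulses, 200 repetitions per location) by default, after a 5-s spontaneous
  lead-in used for the spontaneous spectrum. Analysis trials are the first
  pulses only: they are 500 ms apart, so 50-ms pre/post windows never
  overlap a neighbouring trial, whereas a second pulse can follow its first
  by as little as 50 ms.
* **LFP** — unit-variance 1/f^α background (α = 1) scaled by a background
  amplitude (1.0), plus a negative-going difference-of-exponentials
  deflection (5-ms rise, 15-ms decay) starting 17 ms after each pulse,
  consistent with the observed 15–20 ms latency of evoked responses. The
  per-event gain is lognormal with mean equal to the evoked amplitude
  (3× the background SD by default) and σ = 0.5, producing the
  trial-to-trial variability the responsiveness ratio measures.
* **Spikes** — the ground-truth genome (default: signed-square of the LFP
  with weight 0.5, identity derivative 0.3, identity phase 0.2) is applied
  to features extracted exactly as the analysis pipeline does (without STA),
  thresholded to a 20 Hz in-window rate; each in-window bin is flipped with
  probability `spike_noise` (default 0.1; 0 in noise-free tests); spike
  times sit at bin centers so re-binarization is exact; background Poisson
  spikes (2 Hz default) fill the record outside the analysis windows.

All randomness derives from one master seed through named substreams
(protocol / LFP / spikes), and every bundle carries a manifest from which it
can be regenerated bit-for-bit.

What passing synthetic tests show — and what they do not. The generator
produces the couplet timing, evoked-LFP amplitude variability, and
model-generated spikes the analysis assumes; it does not model oscillatory
brain states, spike-history dependence (refractoriness, bursting),
electrode drift, or any causal LFP↔spike structure beyond the imposed
instantaneous mapping. Ground-truth recovery on these bundles demonstrates
the correctness of the pipeline plumbing and the realizability of the
optimum, not that real cortical data admit such models; conversely, the
background-rate and flip-noise dials reproduce, at mechanism level, the
empirical pattern that poorly responsive units are poorly predictable.

## Numerical choices and degenerate inputs

* Bins are half-open [t, t + 2 ms); a spike exactly on an edge belongs to
  the bin opening there. Overlapping trial windows raise an error rather
  than silently reassigning spikes.
* z-scoring a zero-variance feature, phase of an all-zero trace, PSD of a
  trace shorter than 2 s, spectral ratio with any zero spontaneous power,
  and fitting a spikeless response all raise errors rather than returning
  sentinels.
* Threshold ties are resolved by earlier (trial, bin) position, making the
  spike-count match deterministic even on constant value matrices.
* Test problem sizes: unit and end-to-end tests run on 40–100-couplet
  bundles and scaled GA budgets (population 16–64, 3–20 generations), sizes
  at which every tested property is already stable; the recovery analysis
  above reports the full-scale numbers alongside.
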