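# Methods

This note documents the models implemented in `divs`, the estimation
procedures, the synthetic ground-truth conditions, and the numerical choices
made where the design was genuinely open.

## Stimulus protocols

The canonical stimulus is a full-field flickering spot: Gaussian noise with
no power above 30 Hz, mean luminance normalized to 1, and temporal contrast
(SD/mean) alternating between 0.3 (HC) and 0.1 (LC) in 10-s blocks. Each
block consists of 7 s of fresh noise (used for fitting) and a 3-s segment
whose normalized waveform is reused in every cycle (used for
cross-validation); within a contrast, repeats are bit-identical, and across
contrasts they share the waveform and differ only in scale. Band-limiting is
exact: white Gaussian noise is masked in the Fourier domain above the cutoff
and rescaled, so each segment has exactly the requested SD. Everything is
generated directly at the 1-ms analysis resolution.

The two-channel variant modulates a center spot and a surround annulus with
independent sample-and-hold Gaussian noise updated at 60 Hz (17 bins per
frame at 1 ms).

Recordings are continuous: one current trace or spike train spans the whole
protocol; "trials" are the response slices aligned to the repeat windows.

## Function bases

* **Temporal filters** are coefficients on an orthonormalized family of
  sinusoids `sin[πn(2t/tF − (t/tF)²)]`, n = 1..N, over `tF = 200` ms at the
  working bin width. The raw functions vanish at 0 and `tF` and compress time
  toward short latencies; orthonormalization is ordered Gram–Schmidt (thin QR
  with positive diagonal) at the working `dt`, so projection and expansion
  are transposes of one another. Default N = 12 (structure down to ~8 ms);
  the spiking and kinetic recovery configurations use N = 8 (see
  *Estimator dimensions* below).
* **1-D nonlinearities** are piecewise-linear functions on a tent (hat) basis
  with 21 knots by default, placed symmetrically over ±(|mean| + 3 SD) of the
  generator-signal distribution observed at initialization. A symmetric grid
  with an odd knot count always contains x = 0 exactly (the middle knot is
  forced to 0.0 in floating point), which anchors the suppressive constraints
  at a knot. Evaluation outside the grid clamps to the boundary knot.
* **2-D nonlinearities** use a 15 × 15 vertex grid over the same ranges; each
  square is split into two triangles and each vertex carries a piecewise-
  planar pyramid function. The basis is an exact interpolator and reproduces
  planes exactly; at most three functions are nonzero at any point.
* **Spike-history filters** use 8 raised-cosine bumps, log-spaced over lags
  1–100 ms (fine at 1–2 ms for absolute refractoriness, coarse at tens of ms
  for relative refractoriness). Lag 0 is excluded: a spike never influences
  its own bin.

## Current-response models

All current models minimize MSE between prediction and the observed trace on
the unique segments (repeat windows and the first 200 ms are excluded from
the loss; convolution runs over the continuous stimulus, so there are no
interior burn-in gaps). Fitting is block-coordinate descent:

* nonlinearity weights are linear parameters; each update solves a
  bound-constrained least-squares problem reduced to its normal equations
  (monotone functions are parameterized by nonnegative inter-knot
  increments; suppressive units fix the x = 0 knot and bound the rest);
* filter coefficients are updated by L-BFGS with analytic gradients, followed
  by renormalization to unit L2 norm and an immediate refit of the paired
  nonlinearity; a joint update of both filters runs each outer iteration to
  break coordinate-wise stalls;
* every block update is accepted only if the training MSE does not increase,
  so the recorded MSE path is non-increasing by construction. Convergence is
  declared when the relative MSE improvement over an outer iteration falls
  below `rel_tol` (default 1e-6; at most 100 outer iterations).

Constraints (held exactly at every iterate): DivS `f_s ∈ [0, 1]` with
`f_s(0) = 1`; AddS `f_s ≤ 0` with `f_s(0) = 0`; `f_e` monotone increasing
with `f_e = 0` at the leftmost knot; 2-D surface monotone non-decreasing
along the excitatory axis (this pins down the otherwise-free mixing of the
two filters). Filters are unit-norm, so all gain lives in the nonlinearities;
the multiplicative scale freedom between `f_e` and `f_s` is resolved by the
`f_s(0) = 1` anchor, and the offset freedom between `c0` and `f_e` by the
anchored left knot. The LN model keeps `c0 = 0` and lets its unconstrained
nonlinearity carry the offset. Suppressive-filter sign is canonicalized to
positive correlation with the excitatory filter; the LN filter to an
on-average increasing nonlinearity.

**Initialization.** The excitatory filter starts at the ridge-regularized
regression of the response on the basis design (whitened reverse
correlation). The suppressive filter starts from a copy of that kernel
delayed by 8 ms, plus `n_random_inits` seeded random unit vectors (default
5); the suppressive nonlinearity starts as a shallow symmetric bowl. The best
restart by training MSE wins. (A covariance-eigenvector initialization was
evaluated and retired: it stalls at measurably worse optima than the
delayed-copy strategy.) For the 2-D model the filters come from a DivS fit
and may optionally be refined jointly (default on; surface refit after every
filter step).

## The LNK model

The kinetic model passes the stimulus through an LN front-end whose
nonnegative output `u(t)` (1/s) is the R→A transition rate of a three-state
pool: resting (R), active (A), inactivated (I), with constant rates
`k_AI` (A→I) and `k_IR` (I→R). The current is `gain · A(t) + offset`.
Integration uses per-bin linear transition probabilities `p = rate · dt`
with a hard stability precondition (every probability < 0.2, else an error).
This scheme conserves R + A + I exactly and — unlike exponential per-bin
probabilities — has the continuous-time steady state
`A* = u k_IR / (u k_IR + u k_AI + k_AI k_IR)` as its exact fixed point at any
stable step size. The no-depression LN limit is *fast* kinetics (large
`k_IR`, so I never accumulates; `A` becomes a ~`1/k_AI` low-pass of the
drive), approached at fine `dt`.

Fitting optimizes filter coefficients, input-nonlinearity increments and log
rate constants jointly (bounded L-BFGS, finite differences, the drive capped
at the stability bound) with the output gain and offset profiled out by
linear least squares at every objective evaluation; multi-start over drive
scales and rate pairs. The chain is simulated over the full recording so
state dynamics carry across segment boundaries; the loss is masked to the
unique segments. The fourth (slow-adaptation) state of the original kinetic
scheme is deliberately omitted.

The spot/annulus extensions are simulation-only: rectified per-channel
drives feed either one shared kinetic stage (weighted sum before the pool)
or one stage per channel with summed outputs. The `center_fraction` of a
two-channel filter is the norm of its center-channel kernel over the norm of
the full kernel.

## Spiking models

Spikes are an inhomogeneous Poisson process at 1-ms bins with rate
`r(t) = F[g(t)]`, `F[g] = log(1 + exp(g))` fixed, and
`g = Σ ζ_i[s] + h·R − θ`. Subunits ζ are either a linear filter (LN / LN+RP)
or one DivS unit (spiking DivS) under the same constraints as for currents.
Parameters maximize the Poisson log-likelihood `Σ_t [n_t log r_t − r_t]`
(0·log 0 = 0) on the unique segments. During fitting the history term is
driven by the observed train; cross-validated simulations regenerate it
causally from the simulated train's own spikes, bin by bin (Poisson draw per
bin; within-bin spike times are spread uniformly so times are strictly
increasing).

The GLM is concave in all parameters and fit in one quasi-Newton run. The
spiking DivS model alternates concave bound-constrained updates of the two
nonlinearities and of the history/threshold block with L-BFGS filter updates
(individual and joint), accepting only LL-non-decreasing steps; restarts are
the copy and delayed-copy initializations (the latter starting from
`f_s ≡ 1`, i.e. exactly the LN+RP solution, which guarantees the fitted
model is never worse than the GLM) plus seeded random draws. DivS−RP removes
the history term and re-optimizes all remaining parameters from the full
model's solution. The model cannot be fit robustly without the history term,
which is therefore on by default.

## Covariance analysis

One code path serves spike-triggered and current-weighted analysis: with
weights `w(t)` (binned counts or current) and the mean-centered stimulus lag
vectors `s_t` (200 lags), the mean kernel is `(1/T) Σ w_t s_t` and the
covariance difference is `(1/T) Σ w_t s_t s_tᵀ − mean(w) · C0`, where `C0`
is the prior (unweighted) stimulus covariance. A constant response gives a
zero matrix exactly; an identically zero response raises. Eigen-pairs are
sorted by magnitude with the largest element of each eigenvector made
positive; significance can be assessed against response-shuffled surrogates.

Two practical points, both verified in the test suite: (i) the frozen
repeat waveform, reused every cycle, biases the second moments persistently,
so subspace analyses should run on the unique segments (the `mask`
argument); (ii) a band-limited stimulus carries no information about kernel
structure above its cutoff, so subspace comparisons between fitted and
covariance filters are made after projecting both onto the ≤ 30 Hz band
(`bandlimited`). Within the passband, fitted DivS filters and the top-2
covariance eigenvectors of DivS-generated data span the same subspace.

## Evaluation statistics

* **Predictive power.** With n trials, trial mean m and per-trial variances,
  the signal power is `P_sig = (n·Var(m) − mean_i Var(y_i)) / (n − 1)`, and
  the statistic is `corr(pred, m)² · Var(m) / P_sig`: the fraction of
  *explainable* variance captured — 1 for the true signal at any noise
  level, ≈0 for an unrelated prediction.
* **Coherence.** Magnitude-squared coherence between the prediction and each
  trial (Welch, 1-s tapered segments, 50% overlap), averaged across trials
  and clipped to [0, 1]; the noise-corrected bound repeats the computation
  with the leave-one-out trial mean as the ideal predictor. Frequencies are
  reported in Hz and rad/s.
* **Contrast adaptation.** Per contrast, a whitened reverse-correlation
  filter (regression on the temporal basis over that contrast's bins,
  windows crossing a block boundary excluded) and a quantile-binned
  nonparametric nonlinearity. The two nonlinearities are aligned by an
  x-scale (grid search over log-scale plus bounded refinement; the y-offset
  solved in closed form at each scale) and the scale is folded into the LC
  filter, so `contrast_gain = SD(k_LC)/SD(k_HC)` after alignment; values > 1
  mean reduced gain at high contrast. The biphasic index is |min/max| of an
  aligned filter.
* **Event analysis.** Events are runs of PSTH activity separated by ≥ 8 ms
  of silence (zero summed counts at 1-ms bins, no pre-smoothing), then split
  recursively (depth ≤ 3) wherever a two-component Gaussian mixture on the
  pooled spike times (EM, deterministic initialization at the 25th/75th
  percentile times) separates its means by more than twice the sum of the
  component SDs. Windows are midpoints between neighboring event centers.
  Events with spikes on ≤ 50% of trials are flagged excluded. Low-contrast
  trains are scored inside the high-contrast windows and inherit the
  high-contrast inclusion decision (they are additionally dropped only if
  they contain no spikes): at the sparse LC rates of the synthetic
  conditions, re-applying the 50% rule to LC data directly would exclude
  essentially every event. Per event: SD of each trial's first spike
  (first-spike jitter), SD of all spike times (event time scale), and the
  variance/mean ratio of per-trial counts (Fano factor).

## Synthetic ground truth

Canonical generator conditions (fixed; `overrides` exist for experiments):

* kernels: zero-integral biphasic waveform (difference of fifth-order gamma
  lobes, τ = 10 and 16 ms), unit-norm, positive peak near 45 ms after
  projection onto the temporal basis; the suppressive kernel is the same
  waveform delayed 10 ms.
* excitatory nonlinearity: softplus with scale 0.5·σ_g for current models
  (gently rectifying) and 0.25·σ_g for spiking drive (strongly rectifying),
  where σ_g is the generator SD on a fixed seeded high-contrast probe.
* suppressive nonlinearity: `f_s(x) = 1/(1 + (x/1.5 σ_g)²)` — symmetric
  (ON-OFF), 1 at zero input.
* LNK: drive up to 40 1/s at 3 SD, `k_AI = 25`/s, `k_IR = 4`/s (recovery
  ~250 ms), so the inactivated pool is substantially occupied at high
  contrast.
* spike history: −8 at lags ≤ 2 ms plus a −1.5·exp(−(t−2)/15 ms) relative
  component, projected on the history basis.
* spiking calibration: drive SD is normalized to 1.5 and the threshold is
  calibrated (bisection on the softplus mean, then a short simulation loop
  to account for refractory losses) so the realized rate is ~5 spikes/s;
  with these two choices peak instantaneous rates are a few hundred Hz,
  typical for these cells. Earlier, peakier drives produced unphysiological
  multi-spike bins.

Current recordings add iid Gaussian noise sized so that
Var(signal)/Var(noise) on the repeat windows equals the requested SNR
(default 10); spiking recordings are one continuous simulated train
(intrinsic Poisson variability only).

What the generator does *not* emulate: cell-to-cell parameter variability,
slow (tens of seconds) adaptation, photoreceptor and bipolar-cell
nonlinearities upstream of the single filter stage, spatial structure beyond
the two-region spot/annulus abstraction, and recording artifacts
(electrode drift, access-resistance changes). Passing recovery tests
therefore demonstrates estimator correctness and identifiability under the
stated protocol, not robustness to every property of real recordings.

## Estimator dimensions and validation problem sizes

The validation suite fits current models to 70 s of the high-contrast
protocol at SNR 10 (3 seeds, median reported) and spiking models to 300 s at
~5 spikes/s (3 seeds); the kinetic-to-DivS transfer uses 5 seeds of 70-s
noiseless LNK simulations. For the spiking-DivS and LNK recovery
configurations the fits use 8 temporal basis functions and 13 knots rather
than the 12/21 defaults: the smooth canonical kernels are fully representable
in 8 functions, and at ~1500 spikes the maximum-likelihood estimate under the
full parameterization scatters substantially (verified with truth-started
fits), i.e. the reduction trades no bias for much lower variance. Recovery
delays are measured as the peak cross-correlation lag between suppressive
and excitatory kernels, which is exact for a shifted copy and robust to the
lobe ambiguity of peak-latency differences.

## Known limitations

* The spiking DivS likelihood is non-convex; the restart strategy is
  effective on the synthetic conditions but global optimality is not
  guaranteed.
* LNK fitting uses finite-difference gradients through the kinetic
  recurrence; it is the slowest fit in the package and profits from the
  reduced estimator dimensions above.
* The 2-D surface and covariance analyses assume a single stimulus channel
  for the covariance path (channel 0 is used when given a multi-channel
  stimulus).
* Spot/annulus kinetic circuit variants are simulation-only by design; they
  are not fit to data.
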