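# Methods

## Statistical model

Per-trial activity of a neuron pair is modeled as bivariate Gaussian
with mean (μₓ, μᵧ) and covariance Σ.  The covariance (the noise
structure of interest) is constant over the session; the means (the
baseline signal) are an arbitrary nuisance that drifts over trials.
The only structural assumption is that two *consecutive* trials share
the same mean, at least approximately — reasonable whenever the drift
is continuous and slow relative to the trial spacing.  Formally the
trial-pair distribution is a mixture over an unknown signal
distribution k(μₓ, μᵧ), a semiparametric model with a finite parameter
of interest (Σ) and an infinite-dimensional nuisance (k).

The pairwise estimator removes the local (pair) mean and pools within-
pair deviations:

    Σ̂₁₁ = (1/N) Σ_t Δx_t²,  Σ̂₁₂ = (1/N) Σ_t Δx_t Δy_t,  Δx_t = x_{2t−1} − x_{2t}

over N trials (N/2 pairs), with ρ̂ = Σ̂₁₂/√(Σ̂₁₁Σ̂₂₂).  Key properties,
each verified in the test suite:

- **Unbiasedness**: E[Σ̂ᵢⱼ] = Σᵢⱼ for *every* signal distribution k
  (within-pair centering cancels the mean exactly; the 1/N rather than
  2/N normalization supplies the 1-degree-of-freedom correction per
  pair).
- **Minimum variance**: Var of the single-pair covariance statistic is
  Σ₁₁Σ₂₂ + Σ₁₂², the Cauchy–Schwarz lower bound for estimators
  unbiased under arbitrary drift; the N-trial average scales it by
  2/N.
- **Second-order drift bias**: if consecutive means actually differ by
  2ε, the variance estimate inflates by exactly 2ε² (and the covariance
  analogously) — quadratic in the within-pair drift, hence negligible
  for slow drift even when the total excursion over a session is
  large.
- **Scale/location equivariance**: ρ̂(ax+b, cy+d) = sign(ac)·ρ̂(x, y).

ρ̂ is reported **unclipped**: it is a ratio of unbiased covariance
estimates, not a Cauchy–Schwarz-bounded sample correlation, and values
outside [−1, 1] occur in finite samples.  Clipping would distort the
Monte-Carlo null built from the same statistic, so it is deliberately
avoided.  When a variance estimate is zero (a neuron silent or constant
within every pair) the estimate is undefined and propagates as NaN;
undefined pairs are excluded from population summaries.

Pairing starts at trial 1 ({1,2}, {3,4}, …); an odd final trial is
dropped with a debug log.  Trials of one stimulus are treated as a
contiguous series even though other stimuli intervene in session time —
drift on those intermediate timescales is assumed negligible, which is
the same slow-drift assumption made once more at a coarser scale.

Trial-shifted correlograms advance one series by τ trials and truncate
the non-overlapping ends (no wrap-around, which would fabricate
adjacency between session start and end).  The shift grid steps by 2
for the pairwise estimator — an odd shift would scramble its pair
structure — and by 1 for Pearson.

## Monte-Carlo significance test

Because ρ̂ is location/scale free, its null distribution for
independent Gaussian series depends only on the trial count N.  It is
tabulated by brute force: `reps` draws (default 10⁶; 10⁴–10⁵ suffice
for test-suite work) of two iid standard-normal length-N series mapped
through the estimator, sorted, and cached by (N, reps, seed), optionally
on disk as plain text.  The two-sided p value is 2·min(F̂(ρ̂), 1−F̂(ρ̂))
with midpoint tie handling in the empirical CDF, floored at 2/reps.
The asymptotic-normal alternative (variance (1+ρ̂²)/(N/2)) is exposed
as `method="normal"` but is not the default; at N = 40 its tails are
visibly off, which is precisely why the tabulated null exists.

Calibration is the operative criterion: p values must be uniform both
for white noise and for trial-shifted drifting pairs (which cannot
carry simultaneous correlation).  Both are asserted by
Kolmogorov–Smirnov checks at the 1 % level over 10⁴ pairs.

## Nonstationarity test

A neuron is screened for baseline drift by (1) averaging its
session-long firing-rate series over consecutive blocks of 16 trials —
in the reference design each block presents every stimulus once, so
block averaging removes the stimulus structure and 640 trials reduce to
40 block means — then (2) testing the lag-1 serial correlation r₁ of
the block series against the randomness null.  The exact classical
reference formula being unavailable, the implemented standardization is

    z = (r₁ + 1/n) · n / √(n − 2),  p = 2·Φ(−|z|),

chosen from the standard candidates by a 2·10⁵-draw white-noise
calibration at n = 40 *before* any other result was computed; it gives
the most uniform null p distribution (KS statistic 0.004), which is the
test's published validity criterion.  The level is 0.01, uncorrected —
deliberately conservative in the direction of calling neurons
nonstationary.

Pairwise short-term tests across a session use Bonferroni correction:
level 0.01 / (16 · M(M−1)/2) for M neurons and 16 stimuli.

## Comparator methods

**Moving averages.**  Window 2 is the pairing-based variant: residuals
are deviations from non-overlapping pair means, i.e. ±Δ/2.  Its
residual variances and covariance are *half* the pairwise estimates
(true (1, 1, 0.2) is read as (0.5, 0.5, 0.1)), but the residual
correlation — computed uncentered, the residuals already having zero
pair means — equals ρ̂ to machine precision.  Odd windows ≥ 3 use
centered windows with truncated edges (no partial windows) and Pearson
correlation of the interior residuals.  Under a trend shared by the
pair, wider windows leave more common trend in the residuals and push
the correlation away from the truth toward the spurious trend-driven
value; the tested invariant is that |bias| is monotone non-decreasing
in window size.

**State-space (Kalman) detrending.**  A scalar latent trend
μ_{t+1} = F μ_t + η, η ~ N(0, q), observed as X⁽ⁱ⁾_t = Gᵢ μ_t + ξᵢ,
ξᵢ ~ N(0, rᵢ), fitted by maximum likelihood via the prediction-error
decomposition.  The scalar state makes the innovation covariance
diagonal-plus-rank-one, so the filter runs in O(m) per step via
Sherman–Morrison.  Initialization: F = 1, Gᵢ = SD(Xᵢ), rᵢ = half the
first-difference variance, q from the remaining variance; variances are
optimized on the log scale with floor 10⁻⁸ by L-BFGS-B (≤ 200
iterations).  Note (G, q, μ) is identified only up to a common scale;
the likelihood ridge is harmless because residuals are invariant along
it.  Trend removal uses the *filtered* (one-sided) state estimate
Gᵢ·m_t.  With two neurons the filter attributes much of the correlated
noise to the "shared trend", so the residuals approach ±(x−y)/2 and
their correlation collapses (often below zero) with large
across-realization variability — the documented failure mode that the
pairwise estimator avoids; adding trend-sharing neurons restores it
toward the truth.

## Synthetic data

Generators are additive: activity = trend + Gaussian noise, independent
across trials (intertrial intervals of seconds wash out temporal noise
correlation).  Defaults define the benchmark operating conditions:

| parameter | default | rationale |
|---|---|---|
| sinusoid amplitude | 0.5 (noise-SD units) | per-trial trend step ≈ 0.16 × noise SD at 7 cycles / 100 trials — inside the slow-drift regime the model assumes, while the excursion stays visible against the noise |
| sinusoid cycles | 7 | benchmark standard; 4–10 behave alike |
| ARIMA(0,2,1) θ | 0.6 | benchmark standard |
| ARIMA innovation SD | 0.01 (noise-SD units) | trend excursion ≈ noise SD over 40 trials, several SDs over 100 — prominent drift that still changes slowly between consecutive trials |
| noise correlation | 0.3 | benchmark standard |
| session design | 16 stimuli × 40 blocks | each block a seeded permutation of all 16 stimuli |
| trial duration | U(1.0, 1.7) s | matches the reference recording protocol |
| tuning curves | circular Gaussian, baseline 10 Hz, amplitude 10 Hz, width 2 stimuli | moderately tuned mid-rate cortical responses |

Sessions discretize counts as round(max(rate, 0) × duration); the
pair/population benchmarks use raw real-valued activities (the Gaussian
setting in which the optimality statements hold exactly).  All
randomness flows from one integer seed through named child streams
(CRC-32 of the stream name as a `SeedSequence` spawn key), so every
experiment is bitwise reproducible and streams never collide.

What the generators deliberately do **not** emulate: Poisson or
multiplicative (rate-scaled) noise, spike timing within trials,
refractoriness, stimulus-dependent covariance, or drift in the
covariance itself.  Passing tests therefore certify the estimator's
behavior under additive Gaussian noise with drifting means — the
model's stated scope — not under every failure mode of real recordings;
with weak violations (counts are near-Gaussian at moderate rates) the
estimate degrades gracefully and its sign remains meaningful.

## Decoding analysis

Multi-class LDA with pooled within-class covariance and equal priors
(the design is balanced), regularized by ridge·(trace/p)·I with ridge
10⁻⁶ — 16 classes × 20 training trials with many neurons can make the
pooled covariance near-singular.  Features are firing rates.  The four
schemes isolate drift effects: former/former is leave-one-out within
the first half of each stimulus' occurrences (the natural
cross-validation when train and test must share a period);
former/latter trains and tests across the session halves;
the detrended variant subtracts each period's own per-neuron grand mean
first (removing an additive common drift while preserving tuning
differences); even/odd interleaves and so samples both halves.  Trial
shuffling permutes trial order per neuron *within* stimulus,
preserving all single-neuron marginals and tuning while destroying
simultaneity.  Success rates are computed per session and compared
across sessions by paired t tests, never pooled.  Whether intact
short-term correlations help or hurt decoding depends on the planted
covariance geometry relative to the tuning geometry; the package
reports the comparison rather than asserting a direction.  Tuning-curve
PCA stacks per-neuron, per-half 16-point mean-response vectors,
centers without variance standardization (so weakly responsive neurons
are not inflated), and projects onto the top two principal axes.

## Problem sizes

Defaults used by the test suite and the acceptance script: 100
realizations for the three estimator benchmarks, 10⁴ realizations for
the window-2 moment means, 10⁵ draws for the variance-bound check,
10⁵-rep nulls with 10⁴ test pairs for the calibration checks, and 12
six-neuron sessions for the decoding pattern.  These sizes put the
Monte-Carlo standard errors well inside the assertion tolerances (e.g.
SE ≈ 0.011 for a 100-realization benchmark mean with per-realization
SD 0.11, against a ±0.05 band).

## Known limitations

- The estimator needs ≥ 2 trials and discards an odd trailing trial;
  with N = 40 per stimulus its sampling SD is ≈ 0.22, so single-pair
  estimates are noisy and inference should go through the Monte-Carlo
  test, not the point value.
- The serial-correlation normalization is asymptotic; below ~20 block
  means its null p values drift from uniform.
- The state-space comparator fits a single shared trend; neurons with
  heterogeneous drifts need a richer latent structure that is out of
  scope here.
- `former_former` leave-one-out was chosen where the scheme's original
  description ("trained by former, tested by former") leaves the fold
  structure open.
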