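# stcorr

Drift-robust estimation, testing, and decoding analysis of **short-term
spike-count noise correlations** in trial-structured neural recordings.

## The problem

The noise correlation of two neurons — the correlation of their
trial-to-trial response fluctuations to a repeated stimulus — is a key
quantity for population coding, but it is notoriously sensitive to
nonstationarity.  If both neurons' baseline firing drifts slowly over a
session (arousal, anesthesia depth, electrode drift), the ordinary
Pearson correlation of their per-trial responses picks up the
*co-drifting baselines* and reports a spurious "long-term" correlation
even when the within-trial noises are independent.

`stcorr` implements a pairwise local-detrending estimator that is
**unbiased under arbitrary baseline drift**.  Model the responses on
trials 2t−1 and 2t as bivariate Gaussians sharing an unknown mean
(μₓ, μᵧ) — the drifting baseline, a nuisance that may change from pair
to pair — with a constant noise covariance Σ.  Writing
Δx_t = x_{2t−1} − x_{2t} for within-pair differences over N trials,

    Σ̂₁₁ = (1/N) Σ_t Δx_t²,   Σ̂₁₂ = (1/N) Σ_t Δx_t Δy_t,
    ρ̂   = Σ̂₁₂ / √(Σ̂₁₁ Σ̂₂₂),

is unbiased for Σ whatever the drift, and attains the minimum variance
Σ₁₁Σ₂₂ + Σ₁₂² (per trial pair) achievable by any estimator that is
unbiased for all drifts.  Significance is assessed against a
Monte-Carlo null: the exact finite-sample distribution of ρ̂ for
independent white-Gaussian series of the same length, tabulated by
simulation (10⁶ draws by default), with two-sided percentile p values.

Around the estimator the package provides:

- **Nonstationarity screening** — a lag-1 serial-correlation test on
  block-averaged activity classifies neurons as stationary/nonstationary
  and pairs as s-s / s-n / n-n;
- **Conventional comparators** — trial-shifted Pearson correlograms,
  moving-average residual correlations (window 2 reproduces ρ̂ exactly;
  wider windows are biased under drift), and a maximum-likelihood
  scalar-latent-trend Kalman filter whose residual correlation fails
  with few neurons;
- **Synthetic sessions** — every benchmark generator (ARIMA(0,2,1),
  sinusoidal, linear, stepwise drifts; correlated Gaussian noise;
  640-trial sessions of 40 pseudo-random blocks × 16 stimuli with
  circular-Gaussian tuning and 1.0–1.7 s trial durations);
- **Decoding analysis** — 16-class linear-discriminant decoding with
  four train/test schemes (former/former leave-one-out, former/latter,
  former/latter after per-period mean detrending, even/odd), trial
  shuffling, neuron selection, and tuning-curve PCA, to measure the
  impact of short- vs long-term correlations on coding accuracy.

## Worked example

Two neurons share a large second-order random-walk baseline drift
(range ≈ 16 × noise SD over 100 trials) but have **no** noise
correlation; then the same drift with a genuine short-term correlation
of 0.5:

```python
import numpy as np
from stcorr import (TrendSpec, NoiseSpec, simulate_trend, simulate_pair,
                    short_term_correlation, pearson_correlation,
                    build_null_distribution, short_term_test)

trend = simulate_trend(
    TrendSpec("arima021", 100, {"theta": 0.6, "innovation_sd": 0.02}), seed=1
)
x, y = simulate_pair(trend, trend, NoiseSpec(1.0, 1.0, 0.0), seed=3)
print(f"Pearson:    {pearson_correlation(x, y):.3f}")
print(f"short-term: {short_term_correlation(x, y):.3f}")

null = build_null_distribution(n_trials=100, reps=100_000, seed=0)
res = short_term_test(x, y, null, alpha=0.01)
print(f"p = {res.p_value:.3f}")

x2, y2 = simulate_pair(trend, trend, NoiseSpec(1.0, 1.0, 0.5), seed=3)
res2 = short_term_test(x2, y2, null, alpha=0.01)
print(f"planted rho=0.5: estimate {res2.statistic:.3f}, p = {res2.p_value:.5f}")
```

prints

```
Pearson:    0.973
short-term: 0.066
p = 0.648
planted rho=0.5: estimate 0.461, p = 0.00066
```

The ordinary correlation is almost entirely spurious (0.973 from the
shared drift alone); the pairwise estimator reads essentially zero and
its test is calibrated (p = 0.65), while a genuine simultaneous
correlation on the identical drift is recovered (0.461) and detected
(p < 0.001).

## Command line

Each subcommand reads/writes tab-separated text and is fully seeded:

```sh
stcorr simulate --design session --n-neurons 8 --trend arima021 --rho 0.3 \
    --seed 1 --out session.tsv
stcorr estimate session.tsv --out pairs.tsv          # per-stimulus rho + Pearson
stcorr test session.tsv --reps 100000 --out sig.tsv  # Monte-Carlo p values
stcorr nonstationarity session.tsv --out drift.tsv   # serial-correlation test
stcorr correlogram session.tsv --stimulus 0 --neuron-i n000 --neuron-j n001 \
    --max-lag 10 --out cg.tsv
stcorr benchmark --experiment kalman --out bench.tsv
stcorr decode session.tsv --scheme former_latter_detrended --out dec.tsv
```

## Layout

```
src/stcorr/
  session.py      trial-structured data model, TSV I/O, configuration
  estimator.py    pairwise estimator, Pearson, trial-shifted correlograms
  inference.py    Monte-Carlo null + test, serial-correlation test,
                  Bonferroni levels, pair classification
  comparators.py  moving-average and Kalman state-space detrenders
  simulate.py     trend families, correlated noise, full sessions
  decoding.py     LDA schemes, shuffling, selection, tuning-curve PCA
  benchmarks.py   the three estimator-comparison experiments
  cli.py          click command line
docs/methods.md   model, assumptions, numerical choices, limitations
```
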