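# probews

Probabilistic and classical autoregressive early warning signals (EWS) for
regime shifts in univariate time series.

Complex ecological systems — lake plankton, microbial communities,
harvested populations, the climate — can sit near a *tipping point*: a fold
bifurcation where a stable state collides with an unstable one and the
system collapses to an alternative state.  Approaching such a point, the
system recovers ever more slowly from perturbations (*critical slowing
down*), which shows up in data as a rising lag-1 autocorrelation.  This
package detects that rise with three related autoregressive detectors and
provides the simulation machinery to benchmark them:

- **AR(1)** — the field-standard baseline.  Detrend with a Gaussian kernel
  (Scott's-rule bandwidth on the time axis), fit
  `X[t+1] = mu + phi (X[t] - mu) + eps` by OLS in overlapping sliding
  windows (default length 50% of the series, step 1, anchored at the window
  right edge), and quantify the trend of the phi trajectory with Kendall's
  tau.  Significance comes from surrogate data: the best-AIC ARMA(p, q)
  fit (p, q = 1..5) is resimulated, the identical pipeline applied to each
  surrogate, and the observed tau ranked in the resulting null with the
  one-sided add-one p-value.
- **TVAR(1)** — the time-varying AR(1)
  `X[t+1] = mu_t + phi_t (X[t] - mu_t) + eps_t`, fitted in one pass over
  the raw series by Nadaraya–Watson kernel-weighted least squares on time
  rescaled to [0, 1]; the bandwidth is chosen by leave-one-out
  cross-validation.  No detrending and no windows: `mu_t` absorbs the
  trend.  Significance again comes from ARMA surrogates.
- **pTVAR(1)** — the Bayesian TVAR(1).  On the standardized series, both
  `phi_t` and `mu_t` receive Gaussian-process priors with Matérn-3/2
  covariance `alpha^2 (1 + sqrt(3) r / rho) exp(-sqrt(3) r / rho)`
  (defaults: mean 0, amplitude 1, length scale = series length) and
  `sigma ~ half-N(0, 1)`.  The posterior is sampled by Hamiltonian Monte
  Carlo in a whitened parameterization; every posterior draw of the phi
  trajectory yields a Kendall tau, so the warning-signal evidence is read
  directly off the tau posterior — the p-value is the posterior mass at
  `tau <= 0`, no surrogates needed.

A detector declares an EWS when the tau trend is positive and its p-value
is at or below alpha = 0.1.

The benchmark generator simulates the May (1977) harvesting model

    dX = [ r X (1 - X/K) - c X^2 / (X^2 + h^2) ] dt + sigma X dW

with randomly drawn parameters (`T ~ U(50, 200)`, `r ~ N(1, 0.1)`,
`K ~ N(10, 1)`, `h ~ N(1, 0.1)`, `sigma ~ N(0.1, 0.01)`) and a harvest rate
`c(t)` drawn from a squared-exponential GP around a ramp from 1 to 3.5
(regime shifts guaranteed) or around the constant 1 (stationary controls).
For r=1, K=10, h=1 the bistable window of the deterministic skeleton is
c in (1.787, 2.604).  Only the automatically detected pre-shift segment
enters the analysis.

## Worked example

```python
import numpy as np
from probews import TimeSeries, fit_ptvar, posterior_trend_test, PTVARConfig

# a series whose autocorrelation ramps from 0.2 to 0.85
rng = np.random.default_rng(7)
n, phi = 150, np.linspace(0.2, 0.85, 149)
x = np.zeros(n)
for t in range(n - 1):
    x[t + 1] = phi[t] * x[t] + 0.3 * rng.standard_normal()
ts = TimeSeries(np.arange(1.0, n + 1), x)

post = fit_ptvar(ts, PTVARConfig(chains=2, warmup=500, draws=500, seed=1))
test = posterior_trend_test(post, alpha=0.1)
print(f"tau mean {test.tau:.3f}  p {test.p_value:.3f}  EWS: {test.significant}")
print(f"max split-R-hat {post.diagnostics['max_rhat']:.3f}")
```

prints

```
tau mean 0.465  p 0.081  EWS: True
max split-R-hat 1.002
```

i.e. the posterior mean Kendall tau of the phi trajectory is 0.465, 8.1%
of the tau posterior is non-positive (below alpha = 0.1), so the rising
autocorrelation counts as an early warning signal, and the sampler
converged (split-R-hat at 1.002, no divergences).

The same analysis runs from a shell on any two-column `time,value` CSV:

```bash
probews detect series.csv --model ptvar --seed 1          # JSON verdict
probews detect series.csv --model ar1 --n-surrogates 1000
probews simulate --n-reps 250 --seed 1 --out sims/        # benchmark suite
probews benchmark --n-reps 50 --seed 1 --out results.json
probews scan --grid 0.05:1:0.05 --seed 1 --out scan.csv   # bandwidth scan
```

Length-scale presets for the three published case-study series ship in
`examples/*.yaml` (`probews detect data.csv --model ptvar --config ...`).

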