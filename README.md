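# msvdcast

Decomposition-aided multistep forecasting for weekly health-outcome and
accident count series.

Public-safety agencies plan around weekly counts — here, persons injured in
traffic accidents — that are nonstationary: trends shift regime, a strong
seasonal cycle (about 26 weeks) rides on top, and the residual is
autocorrelated. Forecasting such a series several months ahead works much
better when the series is first split into a smooth and an oscillatory part
and both are fed to the predictor. `msvdcast` implements that pipeline:

* **Multilevel SVD of a Hankel matrix (MSVD).** A series `x₁..x_N` is
  embedded into the 2×(N−1) Hankel matrix `H = [[x₁..x_{N−1}], [x₂..x_N]]`.
  Its rank-2 SVD `H = λ₁u₁v₁ᵀ + λ₂u₂v₂ᵀ` (closed form, via the 2×2 Gram
  matrix) splits `x` after anti-diagonal averaging into a smooth part
  (dominant singular value) and an oscillatory part. The smooth part is
  re-embedded and split again, pyramid-style. The singular spectrum rate
  `ΔR_j = R_j / R_{j+1}`, with `R_j = λ₁/(λ₁+λ₂)` at level j, flattens to 1
  when the smooth branch has become effectively rank-1; the recursion stops
  there. Outputs are two additive components with `c_L + c_H = x`: the
  deepest smooth part `c_L` and the accumulated oscillatory parts `c_H`.
* **Stationary wavelet baseline (SWT).** The standard comparison: an
  undecimated (à trous) Daubechies-2 transform at J=3 levels with circular
  boundary; `c_L` is the reconstructed deepest approximation, `c_H` the sum
  of reconstructed details.
* **MIMO forecasting.** All τ horizons are predicted jointly from one
  regressor matrix of P lags of `c_L` and P lags of `c_H` (2P columns):
  linearly, `x̂ = zβᵀ` with the τ×2P coefficient matrix fitted by
  Moore–Penrose least squares, or nonlinearly with a three-layer sigmoid
  perceptron (`Q = round(log₂ N_train)` hidden units) trained full-batch by
  Levenberg–Marquardt over random restarts.
* **Evaluation.** Per-horizon nRMSE, modified Nash–Sutcliffe efficiency
  `mNSE = 1 − SAE/SAD` and modified index of agreement (two-branch `mIA`
  with the 2·SAD balancing term), plus summary rows and method-vs-method
  gain summaries. The lag order P is read off the dominant peak of the
  periodogram, judged against an AR(1) red-noise background.
* **Synthetic data.** A seeded generator of injury-count-like weekly series
  (piecewise-linear trend, seasonal cycle, AR(1) noise) so the whole chain
  is testable end to end.

## Worked example

```python
import msvdcast as mc

x = mc.generate_injury_series(mc.SyntheticSeriesConfig(seed=7))

res = mc.msvd_decompose(x)
print(res.J, res.converged, round(res.delta_R[-1], 6))
# 16 True 0.999901        <- pyramid depth where dR flattened to 1

spec = mc.fourier_power_spectrum(x)
print(spec.dominant_period)
# 26                      <- weeks; becomes the AR order P

cfg = mc.ExperimentConfig(
    synthetic=mc.SyntheticSeriesConfig(seed=7),
    decomposition="msvd", model="mimo_ar", horizons=14,
)
table, art = mc.run_experiment(cfg)
print(table.to_frame(percent=True).round(2).to_string())
```

which prints (metrics ×100; 518 training rows, 223 test rows):

```
           nRMSE   mNSE    mIA
1           0.03  99.34  99.67
2           0.01  99.83  99.91
...
13          1.67  74.32  87.16
14          2.78  58.18  79.09
Min         0.01  58.18  79.09
Max         2.78  99.83  99.91
Mean 1–8    0.15  97.37  98.69
Mean 1–13   0.53  91.47  95.73
Mean 1–14   0.69  89.09  94.54
```

Read it as: one-week-ahead forecasts explain almost all absolute deviation
(mNSE 99.3%), skill decays with horizon, and the 14-week-ahead forecast
still reaches mNSE 58%. `compare_methods` runs MSVD+AR, SWT+AR and SWT+ANN
on the same series and reports the relative gains.

The same chain is available from a shell:

```
msvdcast simulate --n-weeks 780 --seed 7 --out series.csv
msvdcast decompose --input series.csv --method msvd --out components.csv
msvdcast forecast --input series.csv --model mimo_ar --tau 14 --outdir run/
msvdcast compare --input series.csv --tau 13 --outdir cmp/
```

## Layout

```
src/msvdcast/
  msvd.py         Hankel embedding, rank-2 SVD, pyramid, dR stopping
  swt.py          à trous filter bank, SWT/iSWT, component split
  forecasting.py  regressor construction, MIMO-AR, MLP + Levenberg-Marquardt
  evaluation.py   nRMSE/mNSE/mIA, horizon tables, periodogram, lag selection
  synthetic.py    seeded weekly-count generator and fixtures
  pipeline.py     end-to-end runs, method comparison, manifests
  cli.py          the `msvdcast` command
docs/methods.md   model assumptions, parameter choices, limitations
```
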