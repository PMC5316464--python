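# Methods

## The decomposition model

`msvdcast` treats a weekly count series as the sum of two latent parts: a
smooth, slowly varying component `c_L` (level, trend, long-period
seasonality) and an oscillatory component `c_H` (short-period fluctuation
and noise). Nothing is assumed about either part parametrically; the split
is defined operationally by the multilevel Hankel-SVD pyramid.

One level works on the 2×(N−1) Hankel trajectory matrix of the input. With
a window of 2 the SVD has exactly two terms, and each elementary matrix
`λᵢuᵢvᵢᵀ` maps back to a series by anti-diagonal averaging — the standard
SSA/HSVD diagonal-averaging rule, and the unique linear rule under which
the embed→average round trip is the identity. The dominant term is the
level's smooth part, the complement its oscillatory part. The smooth part
is re-embedded and split again; all oscillatory parts are accumulated into
`c_H` (mirroring how an undecimated wavelet cascade accumulates detail
subbands), and `c_L` is the deepest smooth part.

Implementation notes:

* The rank-2 SVD is computed in closed form from the 2×2 Gram matrix
  `HHᵀ`; the smaller eigenvalue uses `det/μ₁` rather than
  `(a+c−disc)/2` to avoid cancellation. Agreement with LAPACK is ~1e−15
  relative on random matrices.
* Per level, the oscillatory part is computed as the exact complement
  `x − c_low`. This is algebraically identical to averaging the second
  elementary matrix (linearity + exact reconstruction) but makes the
  telescoped additivity `c_L + c_H = x` hold to machine precision at any
  depth; the unit suite also checks the elementary-matrix route directly.
* Singular-vector signs are irrelevant (elementary matrices are
  sign-invariant); tied singular values may resolve to any orthonormal
  basis, which leaves every consumed quantity unchanged.
* An all-zero input is defined to have `R = 1` (0/0 guard) and returns zero
  components, converged.

### Stopping rule

The depth diagnostic is the singular spectrum rate `ΔR_j = R_j / R_{j+1}`
with `R_j = λ₁/(λ₁+λ₂)` of level j's own matrix (the recursed component's,
not the original's — consistent with running the loop on the smooth
branch). The recursion stops at the first level with `|ΔR_j − 1| ≤ tol`;
levels are computed eagerly one past the candidate so `ΔR` is always
defined. Hitting `max_levels` (default 32) sets `converged=False` and logs
a warning rather than raising; the full `R`/`ΔR` curves are kept in the
result so the stopping behaviour can be plotted and audited.

`tol` deserves care. For strongly autocorrelated, strictly positive series
(weekly counts), `R₁` is already ≈0.99, so a loose tolerance like 0.01
fires at the very first level, before the pyramid has separated anything.
The default `tol = 1e−4` is calibrated on the synthetic weekly-count
generator: it stops the pyramid at depth ≈15–16, which is where the `ΔR`
curve of such series visibly flattens, and at which point `c_L` is smooth
enough for the forecasting stage to profit. Both `tol` and `max_levels`
are arguments everywhere.

## The wavelet baseline

The comparison split uses the undecimated (à trous) discrete wavelet
transform: per level, circular convolution with a zero-upsampled
Daubechies filter pair; no decimation, so all coefficient sequences keep
length N and the transform is shift-covariant. Analysis filters carry one
1/√2 factor (so `|H|² + |G|² = 1` for the quadrature-mirror pair) and
synthesis is circular correlation with the same filters, which makes
analysis+synthesis exactly inverse on periodic signals — round-trip error
is ~1e−13 in practice. `c_L` is the reconstruction keeping only the
deepest approximation subband, `c_H` the sum of reconstructed details;
both are linear in the input, so `c_L + c_H = x` exactly.

Choices the transform definition leaves open:

* **Boundary**: circular. It is the convention under which perfect
  reconstruction is exact and length is preserved.
* **Lengths not divisible by 2^J**: `swt_components` pads by symmetric
  reflection to the next multiple, transforms, reconstructs and truncates;
  additivity survives because everything is linear. The raw
  `swt_decompose` keeps the divisibility precondition and tells the caller
  to pad.
* **Family**: Daubechies only (order configurable, default 2, J=3 —
  matched to fluctuation periods of 8–16 weeks). Filter taps come from
  PyWavelets; the transform itself is implemented here, and a test pins
  the coefficients to PyWavelets' SWT (equal up to the documented circular
  phase offset of 2(2^j−1) per level for db2).

## Forecasting

Both models use the MIMO strategy: one model, τ outputs, no recursive
feeding of predictions into inputs. Regressor rows run over times
n = P..N−τ and hold the P most recent values of `c_L` then of `c_H`
(2P columns); targets are `x(n+1)..x(n+τ)`. The split is chronological,
train first, `floor(0.70·rows)` rows.

**MIMO-AR** is the minimum-norm least-squares solution of
`targets ≈ zβᵀ` via the Moore–Penrose pseudoinverse: deterministic, exact
on noiseless linear data, well-defined for rank-deficient designs. There
is no intercept in the model form; a bias column is available behind a
flag (off by default).

**MIMO-ANN** is a three-layer perceptron with a logistic-sigmoid hidden
layer of `Q = round(log₂ N_train)` units, linear outputs and no bias
terms. Training is full-batch Levenberg–Marquardt on the sum of squares
over all outputs: analytic Jacobian with respect to all weights, damping
λ multiplied by 10 on rejected steps and divided by 10 on accepted ones
(initial 1e−3, cap 1e10, all configurable), at most `epochs` accepted
steps per run, `runs` random restarts seeded `seed..seed+runs−1`, best
training error wins; per-run error curves are reported so both best-run
and mean-over-runs summaries can be formed.

Standardization: inputs are standardized per column and targets are
centered per horizon and divided by one common scale, all with
training-set statistics, undone automatically at prediction time. The
input side keeps the sigmoid layer out of saturation; the target side
keeps the Gauss–Newton residuals O(1), without which LM on count-scale
targets stalls orders of magnitude above its achievable error. Because
the target scale is a single constant, the optimized objective remains
proportional to the raw sum of squares and accepted-step monotonicity is
unaffected. `standardize=False` gives fully raw behaviour.

## Evaluation and lag selection

Metrics are kept on their natural scale internally; table formatting
multiplies by 100. `mNSE = 1 − SAE/SAD` and the two-branch `mIA` (with
`2·SAD`) are absolute-error analogues of the squared-error skill scores
and are less dominated by extreme weeks; both equal 1 only for a perfect
forecast and the `mIA` branches meet continuously at 0. Tables carry the
per-horizon rows plus Min / Max / Mean 1–8 / Mean 1–13 / Mean 1–τ.

The AR order P is the rounded period of the highest periodogram peak.
The series is linearly detrended first (a "mean" mode is available):
level drift otherwise concentrates in the lowest frequency bin and
hides the seasonal peak on exactly the kind of trending count series the
pipeline targets. Peak significance is assessed against a theoretical
AR(1) spectrum with the lag-1 autocorrelation estimated from the data
(clipped to [0, 1)), normalized to the periodogram's mean power and
scaled by the chi-square quantile (2 dof; 1 dof at the Nyquist bin). The
false-positive rate on white noise at 95% confidence calibrates to ~5%.
Frequency-bin ties resolve toward the longer period and the selection is
logged with its significance flag.

Method gains are reported in two conventions — ratio of summary means,
`100·(mean a − mean b)/mean b`, and mean of per-horizon ratios — because
the two differ for heterogeneous horizons and neither is canonical.

## Synthetic data

The generator emulates what fifteen years of weekly injury counts look
like statistically: `base + piecewise-linear trend + seasonal sinusoid(s)
+ AR(1) noise`, clamped at zero and optionally rounded. Defaults: 780
weeks, base 600, a rise to week 280 / decline to week 348 / mild recovery
(slopes 0.8, −1.5, 0.3 per week), a 26-week cycle of amplitude 60, AR(1)
coefficient 0.6 with marginal sd 25. Magnitudes are chosen so the default
series stays strictly positive and the seasonal peak dominates the
detrended spectrum; a 17-week configuration mimics the minor-cause
analogue. `generate_component_pair` exposes the generator's own
smooth/noise split for forecasting tests that bypass decomposition.

What the generator does **not** emulate: calendar effects (holidays,
leap weeks), heteroscedastic count noise (variance tied to level),
outlier weeks, or regime changes in seasonality. Tests passing on this
data therefore demonstrate correctness of the algorithms and the
protocol, not forecasting skill on real accident data.

## Protocol, leakage and sizes

The default protocol mirrors the standard comparison design: components
extracted from the full series, then a 70/30 chronological split, AR
evaluated to τ=14, the ANN to τ=8 with 500 epochs and 10 restarts. Note
the default ordering leaks test-period information into the components
(the decomposition is global); a `causal` mode recomputes the
decomposition from an expanding window ending at each row's current time
so no regressor sees the future. The paper-style mode logs a leakage
warning once per run. Whether test predictions should be static
multi-output regression or rolling re-fits is ambiguous in the protocol;
the static reading is implemented.

Every run writes a manifest (resolved config, seeds, input checksum,
package version, timings) sufficient to reproduce its CSVs bit-identically
on the same platform.

Problem sizes in the test suite and acceptance script (random series of
length 50–780, 200-replicate spectral calibration, an 80-row LM fixture,
780-week pipeline runs) are the package's default study conditions; they
keep the full check suite in the minutes range on a single CPU.

## Known limitations

* The window length is fixed at 2; general SSA windows and multi-component
  grouping are out of scope.
* The ANN follows the stated bias-free architecture; with `Q ≈ log₂ N_train`
  hidden units it is capacity-limited and is expected to trail the linear
  models, especially beyond ~8 weeks ahead.
* The red-noise test assumes an AR(1) background; strongly periodic noise
  or long-memory residuals violate it.
* `nRMSE` is undefined for zero-mean observations and `mNSE`/`mIA` for
  constant observation windows; these raise informative errors rather than
  returning sentinels.
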