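# Methods

## Model and estimator

The regression model is multilinear: for an input epoch
**x** ∈ ℝ^(I₁×…×I_n) and response **y** ∈ ℝ^(J₁×…×J_m),
ŷ = ⟨x, **B**⟩ contracted over all input modes, with
**B** = Σ_f r_f ∘ q_f built from F rank-one increments. Equivalently, in
matricized form (I = ∏I_k, J = ∏J_k, fixed vectorization convention:
first listed mode varies fastest), Ŷ = X B with B ∈ ℝ^(I×J) of PLS rank F.

### Sufficient statistics

The streaming estimator keeps, per coordinate, the exponentially weighted
count, sum and sum of squares (N_eff, S, SS; forgetting factor λ), and the
*raw* second-moment accumulators

    cxx_raw ← λ·cxx_raw + X_tᵀ X_t ,   cxy_raw ← λ·cxy_raw + X_tᵀ Y_t

on unstandardized matricized epochs. Centered, variance-scaled covariances
are derived exactly at refit time:

    C_XX = (cxx_raw − N_eff·μx μxᵀ) / (σx σxᵀ)
    C_XY = (cxy_raw − N_eff·μx μyᵀ) / (σx σyᵀ)

with μ = S/N_eff and σ² = (SS − S²/N_eff)/(N_eff − 1). This recentring is
an algebraic identity, not an approximation: at λ = 1 the derived
covariances equal those of the pooled standardized data for *any*
partition of the stream into batches, and at λ < 1 they equal the
λ^age-weighted analogues. Standardizing Y as well as X is the default
(`scale_y=True`); with it off, Y is centered only.

### Factor extraction

Given (C_XX, C_XY), the covariance-only kernel recursion produces all
intermediate models: for f = 1…F_max

1. rank-one PARAFAC (ALS) of the deflated C_XY reshaped to its
   (n+m)-mode tensor form → per-mode unit vectors; the vectorized outer
   product of the input-mode vectors is the weight direction w_f;
2. r_f = w_f − Σ_{j<f} (p_jᵀ w_f) r_j;
3. tt_f = r_fᵀ C_XX r_f; if tt_f ≤ 1e−12·trace(C_XX) the direction is
   degenerate and the stack truncates at f−1 (later models alias the last
   valid one);
4. p_f = C_XX r_f / tt_f, q_f = C_XYᵀ r_f / tt_f;
5. C_XY ← C_XY − tt_f · p_f q_fᵀ;
6. B^f = B^{f−1} + r_f q_fᵀ.

For order-1 inputs this is algebraically the classical kernel-PLS2
recursion; the test suite verifies coefficient agreement with an
independent NIPALS PLS2 implementation to ~1e−14 relative.

### ALS initialization: a deliberate choice

The rank-one objective ⟨C, w¹∘…∘q^m⟩ is non-convex; the initialization
selects among its stationary points. Three policies are provided:

- `cold` (**default**): deterministic start from the leading singular
  vector of each single-mode unfolding. The extracted models are then a
  function of the accumulated covariances alone, so any batch partition
  of the same data yields the same models — which is also the cleanest
  reading of the method's "the model is completely identified by the
  covariance tensors" property.
- `warm`: each factor's ALS continues from that factor's projectors of
  the previous update. Fastest and path-dependent; two streams that saw
  the same epochs in different batch groupings can settle on different
  (near-tied) stationary points.
- `best`: run both and keep the higher objective (cold preferred on
  ties).

ALS defaults: relative objective tolerance 1e−9, 100 sweeps maximum. The
reproducibility tests use oracle-grade settings (1e−14…1e−15, thousands of
sweeps) because fixed-point agreement at 1e−8 demands actual convergence.
Sign convention: after convergence the first nonzero entry of every
input-mode vector is made nonnegative, the residual sign is absorbed by
the first output-mode vector, and the scale stays ≥ 0.

### Prediction on non-centered data

The centered model is applied to raw inputs through the denormalized
coefficients B̃ = B·σY/σX (coordinatewise) and intercept
Y₀ = μY − μX·B̃, so Ŷ = X·B̃ + Y₀. This path is algebraically identical to
standardize → contract → destandardize and is verified to 1e−10.

## Recursive validation of the factor number

Before a batch is folded into the covariances, every intermediate model
B¹…B^Fmax (from the *previous* refit) predicts it; squared errors averaged
over epochs and output coordinates (optionally divided by the running
per-coordinate σY² — the `nmse` variant, which makes selection invariant
to the scale of Y) are accumulated with forgetting factor γ, and
F* = argmin with the smallest index on ties. The apply-before-update
ordering is enforced by an update-counter handshake between the model
stack and the validation state; validation starts at the second batch
(there is no model to test before the first), and `select_model` returns
the one-factor model flagged `cold_start` until the first scored batch.

Defaults γ = 1 and λ = 1 (no discounting), matching the stationary
protocol; both are exposed. e⁰ = 0, so at γ = 1 the accumulated error is
a plain cumulative sum.

**A known property of argmin selection on noiseless streams.** When the
stream is exactly noiseless, every additional factor strictly reduces
out-of-sample error (as F grows the PLS solution approaches the ordinary
least-squares solution, which is exact on noiseless data), so F* climbs
to F_max rather than settling at the generating rank; exact error ties —
the only case the parsimony tie-break can resolve — do not occur at
finite samples because the sample input covariance is not the identity.
Rank identification by argmin therefore needs observation noise, under
which extra factors genuinely overfit: at SNR 10–20 the selector settles
near (slightly above) the generating rank and tracks a mid-stream rank
switch within a few batches. The test suite asserts the noisy behaviour
and documents the noiseless one.

## Feature extraction

1 s epochs stepped every 100 ms; each channel is transformed with a
complex Morlet CWT at the configured analysis frequencies (ECoG band:
10…150 Hz in 10 Hz steps; MEG band: 5…100 Hz in 5 Hz steps); coefficient
moduli are averaged within ten contiguous, non-overlapping 100 ms bins
(this is the only reading under which 1 s of 100 ms windows yields
exactly 10 temporal points); epochs stack into an
N × frequency × time × channel tensor. The Morlet envelope width is 7
cycles of the analysis frequency by default (σ_t = width/(2πf), the
common neurophysiology parameterization), exposed in `EpochConfig` and
mapped onto the PyWavelets `cmorB-C` family via B = width²/(2π²), C = 1.
Edge effects from wavelet support at the recording boundaries are not
trimmed; callers decoding near edges should discard the first/last epochs
themselves. For supervised use the response is aligned to the epoch's
*end* time (causal decoding). No artifact rejection, re-referencing or
line-noise filtering is performed.

## Modality influence

The influence of mode k on a fitted model is
w_k[i] ∝ Σ_{all other indices} |B[…, i, …]|, normalized to unit sum
(making profiles comparable across refits); output modes are included in
the summation. For a rank-one model the profile over mode k is exactly
the normalized |w^k|. An all-zero model yields a uniform profile, flagged
degenerate. Averaging across recordings or output coordinates is left to
the report layer.

## Synthetic stream generator

`StreamSpec`/`make_truth`/`gen_batches` generate ground-truth streaming
regression data: B_true = Σ_r α_r · w_r¹∘…∘wⁿ_r∘q_r¹∘…∘q_r^m with
unit-norm factor vectors drawn reproducibly from the seed and strengths
α_r = 0.7^(r−1). The geometric decay keeps the planted model
identifiable — with tied strengths the leading rank-one component of
C_XY is not unique and factor sequences are not reproducible — and
mirrors the decaying component spectra of real decoders. X entries are
i.i.d. standard normal; Y = X·B_true + ε with ε calibrated per output
coordinate so Var(signal)/Var(noise) equals the requested SNR (`snr=None`
for noiseless). Drift options: a coefficient *switch* at a given batch
(optionally with a new rank) and a continuous *rotation* toward an
independent target. Default geometry mirrors the full-scale protocol
(15×10×64 inputs, 3×3 responses, 100-epoch batches, 70 batches).

What the generator does *not* emulate: wavelet-textured inputs
(coordinates of real feature tensors are strongly correlated and
heavy-tailed), autocorrelated epochs from overlapping windows, artifacts
and nonstationary noise. Passing the synthetic benchmarks therefore
demonstrates correctness of the estimator's algebra, bookkeeping,
selection and adaptation dynamics — not decoding performance on real
recordings. An integration path exists for realistic texture: feed
sinusoid-mixture signals through the CWT module and regress on the
resulting tensors.

## Problem sizes and defaults

The bundled tests and the acceptance script run scaled-down geometries
(feature dimensions 24–480, 2 000–7 000 epochs, F_max ≤ 20), chosen so
the whole suite completes in a few minutes on one core while exercising
every code path at realistic conditioning. At the full ECoG geometry
(I = 9600) the covariance accumulator is 9600², ≈ 740 MB in float64 —
supported, but refits are minutes rather than milliseconds, and a
practical F_max there is in the hundreds (the CLI default is 20, sized
for the small geometries; raise it with `--f-max` for large runs).

## Known limitations

- Only C_XY is deflated (sufficient in the kernel-PLS family); C_XX is
  kept intact.
- Exponentially weighted recentring is exact for the statistics stored
  here; per-batch standardization drift is therefore not an issue, but a
  λ so small that N_eff ≤ 1 leaves the variance undefined (the first
  update must contain at least two epochs).
- Missing data, sparse tensors and rank-R (R > 1 per factor)
  decompositions are out of scope.
- The streaming loop is single-process; no real-time scheduling
  guarantees.
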