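# rewnpls — streaming N-way PLS tensor regression

`rewnpls` implements **Recursive Exponentially Weighted N-way Partial
Least Squares (REW-NPLS)**: a tensor-input/tensor-output regression
estimator for data that arrive as a stream of batches, together with
**recursive validation** — an online procedure that selects the
number-of-factors hyper-parameter while the stream runs, instead of
offline cross-validation.

It is written for adaptive neural decoding (brain–computer interfaces),
where epochs of a frequency × time × channel feature tensor
**x**(t) ∈ ℝ^(I₁×…×I_n) must be mapped to a movement or state tensor
**y**(t) ∈ ℝ^(J₁×…×J_m) by a decoder that is recalibrated every few
seconds as new data arrive — but nothing in the estimator is specific to
neural data: any streaming multilinear regression problem fits.

## The model

The decoder is multilinear: Ŷ = X **B**, with a coefficient tensor
**B** ∈ ℝ^((I₁×…×I_n)×(J₁×…×J_m)) built from F rank-one factors, each an
outer product of per-mode projection vectors w¹∘…∘wⁿ. The estimator never
stores observations. Its sufficient statistics are the exponentially
weighted covariance tensors

    C_XX ← λ·C_XX + X_tᵀ X_t ,   C_XY ← λ·C_XY + X_tᵀ Y_t ,

(λ ∈ [0, 1] is the forgetting factor; λ = 1 keeps all past data, λ < 1
discounts it exponentially), plus running per-coordinate means and
variances for continuously updated standardization. Each incoming batch
triggers a refit: a covariance-only kernel-PLS recursion extracts the
factors, with each factor's projection direction obtained by a rank-one
PARAFAC (alternating least squares) of the deflated cross-covariance
tensor. The recursion produces **all intermediate models B¹…B^Fmax** at no
extra cost.

That stack of intermediate models is what makes online hyper-parameter
selection possible: before each batch is used for fitting, every B^f is
tested on it, per-factor errors are accumulated with their own forgetting
factor γ,

    e^f ← γ·e^f + ERROR(Ŷ^f, Y) ,       F* = argmin_f e^f ,

and the deployed decoder is B^{F*}.

The package also provides the surrounding pipeline: complex-Morlet CWT
feature extraction (1 s epochs stepped every 100 ms, power decimated to
ten 100 ms bins — 15×10×64 slabs for a 64-channel, 10–150 Hz ECoG
configuration), modality-influence analysis of a fitted coefficient
tensor, a ground-truth synthetic stream generator, and HDF5 persistence.

## Worked example

Simulate a rank-2 tensor-regression stream with the geometry
8×6×10 → 3 at SNR 20 (30 training batches of 100 epochs plus a held-out
test set), fit it recursively with online selection of F, and inspect the
result:

```sh
$ rewnpls simulate --out demo.h5 --x-shape 8,6,10 --y-shape 3 --rank 2 \
      --snr 20 --batch-size 100 --n-batches 30 --test-batches 5 --seed 1
wrote 30 train batches (+5 test) to demo.h5

$ rewnpls stream --batches demo.h5 --model demo_model.h5 --f-max 10 \
      --trace demo_trace.tsv
streamed 30 batches; F*=7; model → demo_model.h5

$ rewnpls predict --model demo_model.h5 --batches demo.h5
coordinate 0    r=0.9750
coordinate 1    r=0.9751
coordinate 2    r=0.9768
mean r = 0.9756 (F=7)
```

Reading the output: recursive validation settled on F\* = 7 factors after
30 batches, and the selected model predicts the three held-out response
coordinates with a Pearson correlation of ≈ 0.98 (the noise ceiling at
SNR 20 is r = √(20/21) ≈ 0.976). `demo_trace.tsv` logs the accumulated
per-factor errors e¹…e^Fmax and F\* after every batch.

The same from Python:

```python
import rewnpls as rw

spec = rw.StreamSpec(x_shape=(8, 6, 10), y_shape=(3,), rank=2,
                     snr=20.0, batch_size=100, n_batches=30, seed=1)
truth = rw.make_truth(spec)
state, stack = rw.init_state(spec.x_shape, spec.y_shape, lam=1.0, f_max=10)
rv = rw.RVState(f_max=10)
for batch in rw.gen_batches(spec, truth):
    if not stack.is_empty:                      # test before fitting
        rv = rw.rv_update(rv, stack, batch.x, batch.y)
    state, stack = rw.update(state, stack, batch.x, batch.y)
model = rw.select_model(rv, stack)              # B^{F*}
```

Which frequencies / time lags / channels drive the decoder:

```sh
$ rewnpls influence --model demo_model.h5 --mode-labels frequency,time,channel
modality        index   weight
frequency       0       0.06541305
frequency       1       0.099317298
...
```

Each profile is the sum of absolute coefficients along one mode,
normalized to unit total weight.

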