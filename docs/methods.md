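# Methods

## The discrete smoothed Wigner–Ville distribution

For a length-`N` real signal the instantaneous autocorrelation is taken at
symmetric integer lags, `R(n, m) = x(n+m)·x(n−m)` for
`m = −(N−1) … N−1`, with indices outside `0 … N−1` contributing zero
(feature vectors are not periodic, so no wrap-around). The transform over
lag uses the kernel `exp(−j2πkm/N)`, `k = 0 … N−1`; since the kernel has
period `N` in `m`, lags are folded modulo `N` and a single length-`N` FFT
per time row evaluates the sum exactly. This is the standard
integer-lag discrete pseudo-WVD construction: it avoids half-sample
interpolation at the cost of a **doubled-frequency convention** — output
bin `k` corresponds to normalized frequency `k/(2N)` cycles/sample, so a
sinusoid at bin `k0` (frequency `k0/N`) appears at output bin `2k0 mod N`,
with a mirror at `N − 2k0` for real input (`bin_to_frequency` documents
the mapping).

Because `R(n, −m) = R(n, m)` for real input, the lag DFT is exactly real;
the implementation verifies the imaginary residue is below `1e−9` relative
to the matrix maximum and raises otherwise (a violated symmetry would be a
bug, not noise).

Useful identity kept as a test anchor: summing the plain WVD over all `N`
frequency bins retains only lag `m = 0`, giving `Σ_k W(n, k) = N·x(n)²`
exactly — the time marginal is proportional to instantaneous energy with
constant `N`.

### Smoothing

The smoothed variant applies, before the lag DFT,

1. time smoothing: each lag column convolved with a **unit-sum** Kaiser
   window `g` (normalizing `g` makes the degenerate size-1 window the
   identity, and keeps amplitudes comparable across window sizes);
2. frequency smoothing: the lag axis multiplied by a Kaiser window `H`
   centered at lag 0 (peak value 1, not normalized).

The returned matrix is the point-wise absolute value, hence non-negative.
A size-1 `g` plus a rectangular `H` covering all `2N−1` lags reduces the
SWVD to `|WVD|` exactly; for that reason the time window is limited to
`N` taps but the lag window may have up to `2N−1`.

### Cross terms and the analytic-signal flag

A real sinusoid pair at `±f0` interferes at DC; a two-tone signal also
interferes at the midpoint frequency. Both interference terms oscillate
along time, so the time smoothing `g` averages them toward zero — this is
the property that makes the smoothed encoding well-behaved, and it is
asserted directly (two-tone midpoint-band peak strictly smaller after
smoothing, across seeds). A consequence worth stating plainly: the
**plain** WVD of a raw real sinusoid does *not* have its per-time argmax
at the sinusoid's bin — the DC interference line and its sinc leakage win
at roughly half of the interior times (verified by direct evaluation).
Localization of the plain WVD is therefore a property of the analytic
signal, and the optional `analytic=True` flag (Hilbert transform
preprocessing) exists for exactly that use. It is **off by default**: the
encoded feature vectors are not bandpass signals, and the smoothed
transform — the one the encoder actually uses — localizes cleanly on raw
real input at every sampled window size.

### Parameters

| parameter | default | meaning |
|---|---|---|
| Kaiser `β` | 0.5 | main-lobe/side-lobe trade-off of all smoothing windows; 0 = rectangular. A mild taper; configurable everywhere. |
| window sizes `M1,M2,M3` | drawn `U(0.3N,0.5N)`, `U(0.5N,0.7N)`, `U(0.7N,0.9N)` | per-channel smoothing strength; rounded to the nearest odd integer (a center tap is needed for symmetric smoothing) and sorted, since odd-rounding can nudge adjacent draws across a range boundary. |
| `quadrant_threshold` | off | vectors longer than this are zero-padded to a multiple of 4, split into 4 equal segments, encoded independently (independent window triples by default; a flag shares one triple) and tiled in reading order TL, TR, BL, BR. |

## Baseline encoders

- **Reshape** — zero-pad to the next perfect square, fill row-major,
  replicate to 3 identical channels. Destroys locality on purpose; the
  weakest sensible baseline.
- **CWT** — complex-Morlet magnitude scalogram over `L` log-spaced scales
  spanning pseudo-frequencies from Nyquist down to two cycles per record;
  the three channels use center frequencies `ω0 ∈ {5, 6, 8}` (three
  distinct time/frequency trade-offs). Implemented in-package
  (`_wavelets.py`) because the environment provides no CWT.
- **DWT** — multilevel orthogonal DWT with circular (periodized) boundary
  handling after zero-padding to a power of two; channels use the Haar,
  Daubechies-2 and Daubechies-4 filters; the concatenated
  `[cA_L, cD_L, …, cD_1]` vector is tiled row-major into a square grid.
  Correctness is anchored by exact perfect-reconstruction tests of the
  filter bank. Both wavelet encoders are deterministic.

Neither the CWT nor the DWT variant claims to replicate any particular
published configuration; they are documented, parameterized baselines.

## Ensemble protocol

Per member: one feature permutation (recorded, identical on train and
test), optional per-feature 0–255 scaling with train-only parameters (no
clipping of test values; constant columns map to 0), one encoder draw, one
backbone training run. The 0–255 step precedes the permutation-sensitive
encoding but is itself per-feature, so its order relative to the
permutation provably does not matter. Member scores are post-softmax
probabilities; the ensemble output is their unweighted mean (the mean
rule — averaging probabilities rather than logits is the common choice and
keeps members on one scale).

Epoch selection follows the *training-set* performance: the member keeps
the weights of the epoch whose training metric (accuracy by default,
training AUC optionally for 2-class) was highest, ties resolved to the
earliest epoch. Members whose loss becomes non-finite are dropped with a
warning rather than retried, and the surviving count is reported.

The in-tree backbone is a small fully-connected net (sklearn MLP) over an
average-pooled (factor 4), flattened, per-pixel-standardized image, trained
with adam or sgd+momentum at learning rate 0.001 and batch size 30. The
reference-scale protocol (15 members, 30 epochs, ImageNet-pretrained
convolutional backbones at 224×224) is expressible through the same
backbone contract — `fit(images, y)` with an epoch loop, `trace_`,
best-epoch restoration, `predict_proba` — but is not exercised by the test
suite, which must run on one CPU; desk-scale defaults are 3 members and
10 epochs.

## SVM reference and fusion

`OptimizedSVC`: [0, 1] min–max scaling fit on training data only, then an
RBF SVM grid-searched over `C ∈ {2⁻⁵ … 2¹⁵}`, `γ ∈ {2⁻¹⁵ … 2³}` (log-2
grids, step 4 in the quick defaults used by tests) with stratified 5-fold
cross-validation internal to the training partition; the inner selection
metric mirrors the outer one (AUC for 2-class, accuracy otherwise); exact
score ties prefer the smallest `C`, then the smallest `γ` (simpler
models). Scores entering fusion are Platt probability estimates;
`score_kind='decision'` switches to raw decision values.

Fusion combines named score matrices as `Σ wᵢ·Sᵢ`. Cross-family fusions
(e.g. `2*svm+cnne`) z-normalize each component first — moments over **all
entries** of the matrix being fused (per-class optional), which makes the
result invariant to any positive affine rescaling of a component. The
plain mean rule over same-scale softmax ensembles skips normalization.
Computing the moments on the fused (test-time) matrix mirrors the usual
practice but is leakage-sensitive if scores from different partitions are
mixed; callers combining partitions should normalize per partition.

AUC is computed by the Mann–Whitney rank formulation (average ranks, so
tied pairs count 1/2) — exactly the pair-counting definition, which the
tests assert against a brute-force pair counter and sklearn.

## Synthetic data: what a green test establishes

`spectral` mode: class `c` is a unit sinusoid at bin `class_freqs[c]` with
uniform random phase plus i.i.d. Gaussian noise (`noise_sd = 0.5` by
default); classes differ *only* in spectral content, so time–frequency
encodings are discriminative by construction, and a periodogram-peak
classifier is a closed-form oracle (its accuracy degrades monotonically
with noise, which is asserted). `mean_shift` mode: standard-normal
vectors with `effect_size = 1.0` added on a random 20% of features for
class 1 — a moderate separation a practitioner would call realistic for an
RBF SVM. Defaults (2 classes, 200/class, L = 64) keep every stage
CPU-fast while matching the shorter of the real feature-vector regimes
(hundreds of features).

What the generator does **not** emulate: correlated features, learned
embeddings' manifold structure, compositional constraints of barcode
k-mer statistics, class imbalance, label noise. A green end-to-end test
establishes that the pipeline discriminates spectral structure under
moderate noise and that ensembling/fusion do not hurt — not that the
method wins on any real benchmark.

## Numerical choices and degenerate inputs

- Imaginary-residue tolerance of the lag DFT: `1e−9` relative (raises).
- SWVD/oracle agreement: `1e−8` relative, tested for `N ≤ 64`.
- Even window sizes are promoted to the next odd integer.
- Constant feature columns normalize to 0 under both the 0–255 and [0, 1]
  maps; out-of-range test values are never clipped.
- z-normalizing a constant score matrix raises (undefined scale).
- Epoch-trace ties select the earliest epoch; grid-search ties the
  smallest `(C, γ)`.
- All randomness flows from integer seeds through numpy `SeedSequence`
  spawning; fitted estimators are pure functions of (data, seed), and the
  run manifest records every member seed, permutation and window triple.

## Known limitations

- The SWVD path is `O(N² log N)` per channel but the `N × N` output is
  quadratic in the segment length; very long vectors should use quadrant
  composition (or larger pooling) rather than direct encoding.
- The small-net backbone is a stand-in for pretrained convolutional
  backbones; absolute scores on real data will differ accordingly.
- Platt-calibrated SVM probabilities can have poorly placed 0.5
  thresholds on small training sets (ranking, i.e. AUC, is unaffected).
- DeepInsight- and IGTD-style learned layouts are not implemented; any
  transformer with the encoder interface (`fit`/`transform` to
  `(n, H, W, 3)`) can be plugged into the ensemble in their place.
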