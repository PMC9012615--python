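# Methods

This note documents the models, numerical conventions and design
choices behind `raecg`, and what the synthetic-data experiments do and
do not demonstrate.

## Beat segmentation

A beat is defined by three consecutive annotated R peaks
`R_prev < R_cur < R_last`.  The extracted window is the central three
quarters of `[R_prev, R_last]`:

- length `round(3 (R_last − R_prev) / 4)`,
- start `R_prev + round((R_last − R_prev) / 8)`,

with rounding to nearest (ties up).  The symmetric-trim placement was
chosen over centring the window on `R_cur`; both are defensible
readings of "the middle 3/4 of the neighbouring span", so the
alternative is exposed as `window_mode="r_centered"`.  First and last
beats of a record are never segmented (no neighbour), windows that
would overrun the signal are dropped rather than padded (only possible
in r-centred mode), and Q-class beats are skipped because the
classifier's output covers N/S/V/F only.  No filtering, resampling or
denoising is applied anywhere.

## Scalogram encoding

The transform is the literal discretised wavelet correlation
`C(a,b) = a^{-1/2} Σ_t x(t) ψ((t−b)/a)` with one translation per
sample and full-support kernels evaluated by FFT convolution, so it
matches a brute-force double sum to floating-point precision (the test
suite checks 1e-6 relative agreement).  Defaults:

- **ψ**: real Morlet `exp(−t²/2) cos(5t)`; Mexican hat available.
  Morlet is the usual choice for ECG time-frequency analysis.
- **scales**: 64 log-spaced values whose pseudo-frequencies span
  0.5–45 Hz at 360 Hz — baseline wander up to QRS content.  Rows are
  ordered by increasing scale.
- **rendering**: magnitude → min-max to [0,1] (a constant matrix maps
  to zeros, the only degenerate case) → bilinear resize
  (half-pixel-centre convention) to a square image, 224 px by default →
  3 channels by replication.  A viridis colormap mode exists for
  visual parity with plotted scalograms; it has no claimed numeric
  consequence.

## Class balancing

Balancing replicates each training image of class c into `factor(c)`
copies: the original plus shifts taken in a fixed inventory order
(identity first, then ±2, ±4, ±6, ±8, ±10 px alternating along x and
y).  The default factors 1/20/10/20 for N/S/V/F are the values forced
by the pre/post population arithmetic of the interpatient training
set this pipeline follows (e.g. 943 S beats × 20 = 18 860).  Shifts
act on images, not on the 1-D trace, so the beat's time-domain
content is preserved.  `balance_dataset` refuses test-partition (DS2)
or already-balanced input — the evaluation protocol depends on it.

## Network

All shapes below are for the canonical 224×224×3 input; `input_size`
scales the whole network (the tests and acceptance run use 32 px,
purely a problem-size choice for CPU runs).

- **R-block** `(in, mid, out, strides)`: pre-activation bottleneck —
  BN→ReLU→Conv1×1 (in→mid), BN→ReLU→Conv3×3 (mid→mid, stride s),
  BN→ReLU→Conv1×1 (mid→out) — plus identity shortcut when `in == out`
  and stride 1, otherwise a single stride-s 1×1 projection.
- **A-block** `(C, n groups)`: channels split into n groups, each group
  into halves of `C/2n`.  Channel half: global average per channel →
  per-channel affine (W₁, b₁) → softmax **across the C/2n channels** →
  broadcast multiply → residual add.  Spatial half: group
  normalisation (1 group per half, layer-norm-like; configurable) →
  per-channel affine (W₂, b₂) → softmax **across the H·W positions of
  each channel** → elementwise multiply → residual add.  Halves and
  groups are concatenated back; no channel shuffle is applied.  The
  softmax axes are the only axes along which each branch's statistics
  vary, and the attention product is broadcast elementwise
  multiplication — the only reading the shapes admit.  Default n = 2,
  W init 1, b init 0.
- **RA-UNET** (bottom layer): encoder = 3 × [max-pool 3×3/2 → A-block
  → R-block(16,4,16)], the innermost 7×7 level without an R-block;
  decoder = 3 × [bilinear upsample → additive same-size skip →
  A-block] → final R-block.  Skip sources are the post-R-block encoder
  maps at 28 and 14 px and the module input at 56 px; the addition
  happens after upsampling and before the decoder A-block, following
  the encoder→decoder prose order of the design.
- **Assembly**: stem conv 7×7/2 (16 ch) → max-pool 3×3/2 → R-block1 →
  initial map F₀ (56×56×16); middle = R-block5(F₀); bottom =
  RA-UNET(F₀); fusion = F₀ ⊕ middle ⊕ bottom (elementwise sum — the
  head expects 16 channels, which rules out concatenation); head =
  R-block2 (→28×28×32) → R-block3 (→14×14×64) → R-block4 (→7×7×64) →
  global average pool → FC → 4 scores.  The sum-fusion also counters
  the magnitude decay caused by repeated ReLU stages.
- **Ablations**: `use_rblock=False` replaces strided/channel-changing
  R-blocks with their plain 3×3 conv and removes pure
  feature-processing ones; `use_ablock`, `channel_att`, `spatial_att`,
  `top_skip`, `middle_layer` switch the corresponding structures off.

### Initialisation

Convolution and linear weights are uniform in
`[−1/√fan_in, +1/√fan_in]`, biases zero, attention scales one.  A
higher-gain He initialisation was tried first and rejected: the
A-block's residual attention (output up to `(1 + w)·x`) and the
unnormalised projection shortcuts compound multiplicatively across the
encoder-decoder, and with √6-gain weights the logits reach O(10³) at
initialisation, which stalls short training runs.  With the
conservative bound the 5-epoch overfit sanity check converges
(training loss 0.77 → 0.02).

### Numerics

The network runs on a numpy reverse-mode autodiff engine written for
this package (`raecg.nn`): broadcast arithmetic, matmul, im2col/col2im
convolution, max-pool with argmax routing, bilinear resampling with
half-pixel centres, batch/group normalisation (ε = 1e-5, BN momentum
0.1) and numerically-stabilised softmax.  Gradients of every
structured operation are validated against central finite differences.
Training is deterministic given the seed; evaluation mode is
bitwise-deterministic.

## Training and evaluation protocol

Adam (β = 0.9/0.999, ε = 1e-8), cross-entropy on raw scores, batch
size 16, initial rate 1e-3, ×0.1 every 20 epochs; 60 epochs by default
(three decay steps), configurable.  No early stopping or model
selection — the last-epoch weights are evaluated.  Class order is
N, S, V, F everywhere.  Metrics are one-vs-rest from the 4×4 confusion
matrix; zero-denominator rates report 0 with a warning.  Multiclass
accuracy is `100·trace/total`.  Interpatient discipline: records are
assigned whole to DS1 (train) or DS2 (test), only DS1 is ever
balanced, and scoring is one prediction per beat.

For real MIT-BIH-layout data the split is the standard de Chazal
interpatient protocol: records 102, 104, 107, 217 (paced) excluded,
22 records per partition, verified disjoint.  Records 201 and 202 come
from the same patient yet sit in different partitions in this
protocol; we follow it unchanged and note the leakage caveat.

## Synthetic data

Beats are sums of Gaussian bumps (P, QRS, T) at jittered R-R intervals
(mean 0.8 s, 5% fractional jitter, 360 Hz, additive Gaussian noise
0.02 mV by default): N has a full narrow complex; V a wide
high-amplitude QRS with inverted T and no P; F the average of N and V;
S near-normal morphology whose preceding R-R is shortened by 25–40% —
prematurity carried in timing, mirroring the real N/S confusability.
Defaults for multi-record simulations: class mix 70/10/15/5% N/S/V/F
(normal-dominated, as in clinical recordings, but with enough minority
beats that per-class metrics are estimable at a few hundred beats),
records alternately assigned to DS1/DS2.

What passing on synthetic data shows: the mechanics are correct —
segmentation arithmetic, encoding, count-exact balancing, gradient
flow, protocol guards, and that the architecture can learn
class-conditional time-frequency structure.  What it does not show:
benchmark-level performance on real ECG.  Synthetic class evidence is
cleaner and lower-dimensional than physiological variability (no
inter-patient morphology shifts, electrode artefacts, or rhythm
context), so absolute metric values on fixtures overstate real-data
performance, particularly for S.

## Problem sizes

The test suite and the acceptance script run the pipeline at 32-pixel
images, 12–24 scales, 4–8 training epochs and a few hundred beats;
these are the package's chosen desk-scale study conditions.  The
canonical 224-pixel configuration is exercised in forward passes
(full shape-trace assertions) and is what `RunConfig` defaults to for
users with real data and longer budgets.
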