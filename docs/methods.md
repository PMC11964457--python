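# Methods

`pdgait` grades Parkinson's disease severity (Hoehn–Yahr classes Healthy, 2,
2.5, 3) from 18-channel plantar vertical ground reaction force (VGRF)
recordings: 8 in-sole sensors per foot sampled at 100 Hz plus one total-force
channel per foot, collected during ~2-minute self-paced walks. This note
records the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Pipeline

1. **Load or simulate** walks (19-column whitespace text: time + 18 forces)
   with a demographics table carrying group and Hoehn–Yahr stage per subject.
2. **Augment** the *training* walks (optional) with label-preserving
   transforms, appending one augmented copy per original.
3. **LPR transform** (optional): replace each channel by its
   linear-prediction residual at decimation rate 4, 2 or 1.
4. **Window** every walk into 100-step segments with 50% overlap; each
   segment inherits its subject's class.
5. **Train** a classifier on the training-fold segments; grade each held-out
   walk by majority vote over its segment predictions.
6. **Evaluate** with subject-independent k-fold cross-validation: all
   records of a subject fall entirely on one side of every fold, with
   controls and patients chunked into 1/k validation shares separately.

## Augmentation operators

All operators map a T×18 walk to a same-shape walk and are applied before
windowing (permutation's minimum block length equals the window length, so it
cannot act on windows). Defaults:

| operator        | mechanism                                              | defaults |
|-----------------|--------------------------------------------------------|----------|
| jitter          | + i.i.d. N(0, σ²) noise                                | σ = 2 |
| scale           | one N(1, σ²) factor per channel                        | σ = 0.1 |
| rotate          | Rodrigues rotation of consecutive channel triples around their unit-normalised time-mean axis, angle ~ U(−π, π] | group size 3 |
| magnitude_warp  | multiply by a cubic-spline curve through knot+2 control values ~ N(1, σ²) | σ = 0.2, knot = 4 |
| permute         | shuffle contiguous blocks                              | n_perm = 4, min length 100 |
| time_warp       | re-interpolate along a warped time axis (cumulative sum of a positive spline rate curve, floor 10⁻³) | σ = 0.2, knot = 4 |
| random_sample   | keep n random time points per channel (endpoints forced), linear re-interpolation | n = 1000 |

Interpretation choices, config-switchable: *scale* draws one factor per
**channel** (a per-row factor would equal magnitude warping with white
noise); *rotate* groups the 18 channels into consecutive triples;
*magnitude_warp*'s strength is unstated upstream and mirrors time_warp
(0.2). Validation data is never augmented, and augmented copies are appended
to (never substituted for) the originals.

## Linear-prediction residuals

Per channel: centred mean filter (window 3) → min–max normalisation to
[0, 1] (constant → zeros) → keep every r-th sample, r ∈ {4, 2, 1} (tags
`lp_25` / `lp_50` / `lp_100` for the effective 25/50/100 Hz rates) → fit
a_1..a_p by least squares minimising Σₙ (x(n) − Σₖ aₖ x(n−k))² → emit the
residual e(n) = x(n) − Σₖ aₖ x(n−k), with the p warm-up samples set to zero
to preserve alignment for windowing. The predictor order p defaults to 10
(unstated upstream); coefficients are estimated per channel per walk.
Rank-deficient designs (all-zero channels) fall back to a lightly
ridge-regularised solve with a warning. Heavier decimation leaves more
unpredictable variation, so the residual range grows with the decimation
factor — asserted as a rank statistic on synthetic walks.

## Classifiers

Both are implemented on a compact NumPy engine (`pdgait.nn`) with manual
forward/backward passes, verified against numerical gradients; everything is
float32, single-threaded and deterministic under a seed.

**1D ConvNet.** Each channel's (100, 1) window passes through its own branch:
conv(8 filters, k=3) → conv(16, 3) → maxpool(2) → conv(16, 3) → conv(1, 3) →
maxpool(2) → flatten → dense(50), all SELU
(λ ≈ 1.05070, α ≈ 1.67326). The 18 × 50 branch features are concatenated and
fused by dense(100) → dense(20), each followed by dropout (rate 0.1), into a
4-class softmax. Branch weights are separate per channel by default
(`shared_branches` folds channels into the batch through one branch instead);
the separate branches are evaluated as grouped convolutions — one stacked
matmul per kernel tap across all 18 branches — purely for speed, numerically
identical to 18 independent stacks. 135 674 parameters at the default
configuration.

**Time–spatial transformer.** Each channel's scalar window runs through a
pre-norm encoder block: layer norm → 2-head self-attention (key dim 100) →
dropout (0.3) → residual, then layer norm → feed-forward (width 2×key dim,
SELU) → residual. The block's output is flattened and fused by a fully
connected layer into a 16-dim embedding per channel. The stack of 18 channel
embeddings plus a fixed sinusoidal positional encoding on the *sensor index*
passes through an identical spatial encoder block, is mean-pooled over
sensors, and classified by dense(50, SELU) → dropout → softmax(4).

Two open points were settled as follows. Pooling the d=1 time-encoder output
over time would collapse each channel to a single scalar before fusion, so
the flatten-then-dense fusion above is used instead — this is the "fused via
a fully connected layer" step. After the spatial encoder the tokens are
mean-pooled rather than flattened: with the positional encoding off the model
is then exactly invariant to sensor ordering (a property the test suite
asserts), while with it on the sensor layout matters. Time-encoder weights
are shared across channels by default.

**Training.** Categorical cross-entropy, Nadam (β₁ = 0.9, β₂ = 0.999),
default learning rate 2·10⁻⁴; early stopping monitors validation loss
(min_delta 10⁻⁴, patience 10) and restores the best-epoch weights. Inputs
are standardised per channel with training-fold statistics stored on the
model. A non-finite loss aborts with a diagnostic. Class weighting is off by
default.

## Evaluation

Metrics follow the one-vs-rest confusion-matrix decomposition: precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean, accuracy
trace/total; weighted averages are support-weighted. Zero denominators
define the metric as 0 with a warning. The evaluation unit for headline
numbers is the majority-voted **walk** (ties break toward the lower class —
deterministic, under-calls severity); segment-level confusion matrices are
reported alongside. Augmentation recipes are compared on bit-identical fold
manifests (hash-asserted). The augmentation effect is tested with a Welch
two-sample t-test on per-walk 0/1 correctness indicators pooled over folds;
no multiple-testing correction is applied across recipes. Sensor ablation
removes one symmetric pair — (L1,R1)…(L8,R8), (TotalL,TotalR) — rebuilds the
classifier with 16 inputs, reruns the cross-validation, and ranks pairs by
ascending accuracy.

## Synthetic cohorts

The simulator generates what the classifiers exploit, not biomechanics:
quasi-periodic alternating-foot stance bursts at ~1 stride/s, each stance an
"M"-shaped profile of two raised-cosine lobes (heel strike at 27% of stance,
toe-off at 73%, width 70%, mid-stance valley ≈ half peak) weighted per sensor
from heel-dominant (L1) to toe-dominant (L8); per-sensor Gaussian noise
(σ = 2 N) added *before* summation so totals remain exact sensor sums.
Severity acts on exactly three knobs:

* stance fraction 0.56 / 0.63 / 0.70 / 0.77 (Healthy → stage 3),
* right/left amplitude ratio 1.00 / 0.92 / 0.84 / 0.76,
* cycle-timing jitter SD 10 / 18 / 27 / 38 ms.

Subject-level amplitude (±6%), cadence (±5%) and stance offset (±0.008) are
drawn once per subject, so walks of one subject correlate — which is what
makes the subject-independence machinery testable. The inter-class
separation is deliberately large: synthetic class recovery validates the
pipeline, it does not emulate the difficulty of real patient data, and
passing it says nothing about real-data accuracy.

A planted-signal mode confines class information to chosen sensors (default
use: L2/R2) by scaling only their amplitude (factors 1.0 / 0.85 / 0.70 /
0.55 plus the asymmetry gradient) while keeping stance timing
class-independent. Timing is kept neutral on purpose: the total channels are
exact sensor sums, and a stance-duration signal on one sensor would surface
in TotalL/TotalR at full strength, defeating ablation experiments that
expect the information to sit in the planted pair.

## Problem sizes and numerical choices

The shipped experiments run on scaled-down cohorts chosen as the package's
own calibration: class recovery uses 10 subjects/class with 20 s walks and
3-fold subject-independent CV; the augmentation comparison subsamples
training walks to 20% (stratified, ≥1 walk per class) over 5 seeds at
2 folds; the ablation uses 8 subjects/class, 15 s walks, 2 folds, three
candidate pairs. Class recovery and the augmentation comparison train for up
to 30 epochs at the 2·10⁻⁴ reference rate; the ablation passes learning rate
10⁻³ with batch 100 and up to 40 epochs — its far smaller training sets need
the larger step. Tie-breaks, the time-warp rate floor (10⁻³),
the totals tolerance (1 N), and the standardisation floor (10⁻⁶) are fixed
constants documented at their definition sites.

## Limitations

* The simulator's class separation is optimistic; real H&Y grading is far
  noisier, and the dual-task/medication structure of real cohorts is not
  modelled (the loader tags walk type; inclusion is a config choice).
* The NumPy engine targets CPU determinism, not throughput; it is adequate
  for the shipped problem sizes, not for full-scale (2-minute, hundreds of
  subjects) training.
* LPR order p, the mean-filter window, and the normalisation flavour are
  unstated upstream; the defaults here (10, 3, min–max) are flagged
  explicitly and config-exposed.
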