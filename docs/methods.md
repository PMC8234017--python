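# Methods

## Scope and modelling stance

The package emulates, at bit level, a single-cycle hardware unit that
performs a 4×4 fixed-point matrix multiply-accumulate with pluggable
multipliers, and models the cost of running a convolutional detection
backbone on copies of that unit. One `gemm_update` call is one clock
cycle's work: 16 length-4 dot products, 64 multiplier activations, exact
accumulation. There is no pipeline, register-file or memory-system
simulation; latency is modelled as `invocations × delay / n_units`, an
arithmetic-only lower bound. Delay/power/area/PDP figures are synthesis
measurements consumed as configuration constants (`agemm/data/
unit_timings.yaml`) and are never recomputed.

## Number system

Operands are Q(16,12): 16-bit two's-complement payloads worth
`payload / 2^12`. Quantization is `⌊v·2^f⌋` with saturation — floor
(toward −∞) everywhere, including requantization, so quantization error of
non-saturating inputs lies in `[0, 2^-f)` and round-trips are exact.
Products carry 2f fraction bits and are accumulated in unbounded integers
(software image of "exact adders"); a saturating view at a configurable
width exists for hardware-faithful studies. Activations are requantized to
16 bits once per layer, after accumulation and before the activation
function. The convention that inter-layer traffic is requantized to 16
bits is a declared design choice; alternatives (wider inter-layer formats)
would change approximate-path outputs but not invocation counts.

## Multipliers

The exact reference is the true signed integer product. The approximate
family is Mitchell logarithmic multiplication in sign-magnitude form:
XOR the signs, write each magnitude as `2^k(1+m)`, approximate the product
magnitude as `2^(k1+k2)(1+m1+m2)` when `m1+m2 < 1` and `2^(k1+k2+1)(m1+m2)`
otherwise. Implemented exactly in integer arithmetic: with mantissa
integers `m1, m2` the sum at common denominator `2^(k1+k2)` is
`s = m1·2^k2 + m2·2^k1`, and the result is `2^(k1+k2) + s` or `2s`. Two
truncating variants model cheaper circuits:

- **dynamic truncation** (`trunc_width w`, default 5): each operand keeps
  its leading one plus `w−1` following bits;
- **two-stage trim** (`trim_bits (o, t)`, default (8, 4)): operands keep
  their top `o` significant bits, then mantissas keep `t` bits.

Truncation discards bits with no rounding compensation, and the most
negative payload −32768 saturates to magnitude 32767 before the log path.
The published circuits these presets echo add design-specific compensation
logic; the presets are therefore named "-like" and are not gate-level
replicas. Error characterization (NMED, normalizer `(2^15−1)^2` at 16 bits
and `(2^(b−1)−1)^2` at width b; MRED over nonzero exact products) uses
seeded uniform sampling (default 10^6 pairs) or exhaustive enumeration up
to 10-bit operands; larger exhaustive requests are refused.

## Convolution lowering

Convolutions use "same" zero padding with `O = ⌈I/S⌉` — the only
convention that reproduces every row of the bundled backbone table, whose
parameters are taken verbatim rather than re-derived from the network
graph (the table's channel counts encode cross-stage routing not modelled
here). Patches are anchored so that output position `(oy, ox)` covers
input rows `[oy·S − ⌊(F−1)/2⌋, …]`; flattening is channel-major
(`c·F² + fy·F + fx`) in both filter rows and patch columns. Both lowered
matrices are zero-padded to multiples of 4; padded entries contribute
exactly zero because adders are exact and every multiplier maps a zero
operand to zero. A layer therefore costs exactly
`⌈K/4⌉·⌈O²/4⌉·⌈C·F²/4⌉` unit invocations, which the emulator's multiplier
counter reproduces as 64× that number. Pooling (2×2 stride-2 max) and 2×
nearest-neighbour upsampling are multiplication-free.

Leaky-ReLU uses slope 0.1 (the family default for this detector class),
quantized to Q(16,12) (payload 409) and applied as an integer
scale-and-shift outside the multiplier counter — the software image of a
lookup-table activation. The identity activation is available for oracle
comparisons.

## Detection metrics

Boxes are axis-aligned with continuous corner coordinates (converters
accept COCO `[x,y,w,h]` and YOLO center layouts). Matching is greedy in
descending confidence: each retained detection takes the unmatched
same-class, same-image ground truth of highest IoU ≥ t; ground truths
match at most once. The confidence filter is strictly greater-than
(default 0.5) where applied; the AP path sweeps the confidence axis and
applies no filter. AP is the 101-point interpolated average
(`P_interp(R) = max_{R'≥R} P(R')` over the grid {0.00, …, 1.00}); mAP
averages AP over classes and an IoU-threshold set — {0.5} and
{0.50, 0.55, …, 0.95}. Greedy matching is the convention of the standard
evaluation tooling; it can differ from optimal assignment on heavily
overlapping layouts, which the synthetic scenes avoid by construction.

## Synthetic fixtures

All generators are pure functions of (seed, size parameters). Tile and
layer generators draw values uniformly from [−1, 1), where real
activations and weights of quantization-aware networks concentrate; small
test layers (I ≤ 10, C ≤ 3, F ≤ 3) keep loop oracles affordable while
exercising every padding/tiling branch — the counts for full-size layers
come from the closed-form model, which the emulator is shown to agree with
on those small layers. The scene generator emulates a top-down
hive-entrance monitoring benchmark (order of 16 insects per image; the
real benchmark holds 1040 boxes over 65 images) by placing
non-overlapping ground-truth boxes and deriving detections with controlled
jitter (localization), drop-out (recall) and well-separated spurious boxes
(precision). It does not render imagery or model appearance, occlusion,
crowding or class confusion — passing tests certify the metric machinery
and the emulator, not detector quality on real images; published mAP
figures for the real dataset require the external images and trained
weights and are out of scope.

## Numerical choices and limitations

- Floor rounding everywhere; no stochastic or nearest rounding modes.
- The characteristic `k` is obtained with `frexp`, exact for integers
  below 2^53; all multiplier arithmetic is integer, so emulation is
  bit-reproducible across platforms.
- Summation order inside dot products is fixed but immaterial (exact
  adds).
- Reported latencies round half-up (1 decimal in ms, integer rates),
  matching the presentation convention of the timing constants' source.
- The cost model ignores memory traffic, scheduling and the non-conv
  layers' (multiplication-free) runtime; it is a lower bound, not a
  performance prediction.
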