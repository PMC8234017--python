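# agemm

Bit-accurate software emulation of an **approximate general matrix multiply
(AGEMM) unit**: a hardware block that computes `C ← C + A×B` over 4×4 tiles of
signed 16-bit fixed-point operands using approximate multipliers and exact
adders. Around the unit, the package provides everything needed to reason
about deploying it in a convolutional object detector:

- the Q(16,12) fixed-point number system (quantization `⌊v·2^f⌋/2^f`,
  requantization of wide accumulators),
- a parameterized family of **Mitchell logarithmic multipliers** (plain,
  dynamically truncated, two-stage trimmed) plus the exact reference
  multiplier, with NMED/MRED error characterization,
- the MAC → MAC4 → 4×4 GEMM-unit hierarchy (64 multiplier activations per
  invocation, counted),
- **im2col lowering** of convolutional layers to tiled 4×4 matrix products,
  plus multiplication-free max-pooling and upsampling,
- an **invocation-count cost model**: a conv layer needs
  `⌈K/4⌉·⌈O²/4⌉·⌈C·F²/4⌉` unit invocations; with per-invocation delay *d*
  (a synthesis constant) and *n* concurrent units, the arithmetic-only
  latency bound is `invocations · d / n`,
- object-detection scoring: IoU, greedy COCO-style matching, 101-point
  interpolated AP, mAP[0.5] and mAP[0.5:0.95],
- seeded fixture generators, including a synthetic stand-in for a top-down
  honeybee-monitoring detection benchmark.

It is aimed at approximate-computing researchers who want to evaluate
multiplier designs at the application level (a detection CNN backbone)
without synthesizing hardware or training networks.

## The model in brief

A Mitchell multiplier writes each magnitude as `2^k(1+m)`, `m ∈ [0,1)`,
approximates `log2` by `k+m`, adds, and takes the approximate antilog:

```
|a|·|b| ≈ 2^(k1+k2)·(1+m1+m2)   if m1+m2 < 1
          2^(k1+k2+1)·(m1+m2)    otherwise
```

realized purely with shifts and adds. It never overestimates, and is exact
when an operand is a power of two. The truncating variants (`w=5` dynamic
truncation, `(8,4)` two-stage trim) mirror the headline parameters of
published designs and trade accuracy for circuit cost.

For a 25-layer detection backbone (21 conv layers, input 416×416), the cost
model gives 58,845,696 unit invocations per inference pass; at the measured
4.70 ns delay of the exact unit that is 277 ms on one unit, or 34.6 ms and
29 inferences/s on eight — and 26.3 ms / 38 inferences/s with the fastest
approximate variant (speedup 1.31).

## Worked example

```
$ agemm demo --mult dr-alm5-like --seed 0
layer I=8 C=2 F=3 K=4 mult=dr-alm5-like multiplier_calls=5120 output_nmed=0.00724803
```

A seeded random 8×8×2 input is convolved with four 3×3×2 filters twice —
once with the exact multiplier, once with the truncated-Mitchell one. The
layer needs 80 GEMM-unit invocations (`⌈4/4⌉·⌈64/4⌉·⌈18/4⌉ = 1·16·5`), hence
`80 × 64 = 5120` multiplier activations; the approximate output deviates
from the exact one by about 0.7% of the representable range on average.

```
$ agemm cost --mult dr-alm5-like --units 8 | tail -2
total,58845696
# unit=dr-alm5-like n_units=8 time_ms=26.3 images_per_s=38 speedup=1.31
```

Per-layer and total invocation counts for the bundled backbone table, and
the latency/throughput/speedup of eight concurrent approximate units
against the exact reference.

```
$ agemm characterize --mult mitchell --exhaustive-bits 8
multiplier,nmed,mred,mean_error,n_samples,seed
mitchell,9.383259e-03,3.699411e-02,0.000000e+00,65536,None
```

Exhaustive error characterization of the plain Mitchell multiplier over all
signed 8-bit operand pairs: mean absolute error ≈ 0.94% of the maximum
product (NMED), mean relative error ≈ 3.7%; signed errors cancel by
symmetry. Other subcommands: `agemm gemm` (random tile updates, deviation
from the exact path) and `agemm eval --gt gt.json --pred pred.json`
(mAP scoring of COCO-style files).

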