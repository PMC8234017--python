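# Synthesis measurements of the 16-bit fixed-point GEMM/AGEMM units
# (45 nm standard-cell flow). These are configuration constants consumed
# by the cost model; they are never recomputed by this package.
# delay: ns per unit invocation, power: mW, area: 1e3 um^2, pdp: pJ
units:
  exact:
    delay: 4.70
    power: 5.32
    area: 107.3
    pdp: 25.0
  dr-alm5-like:
    delay: 3.58
    power: 1.58
    area: 43.2
    pdp: 5.6
  tl16-8-4-like:
    delay: 4.16
    power: 1.48
    area: 39.0
    pdp: 6.2
  rad1024-like:
    delay: 3.78
    power: 2.83
    area: 61.9
    pdp: 10.7
  hralm3-like:
    delay: 4.46
    power: 1.80
    area: 45.7
    pdp: 8.0
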