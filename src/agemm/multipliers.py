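"""Exact and approximate 16-bit fixed-point multipliers.

The approximation family is logarithmic (Mitchell) multiplication: write
each magnitude as ``2**k * (1 + m)`` with mantissa ``m in [0, 1)``,
approximate ``log2`` by ``k + m``, add the logarithms, and take the
approximate antilogarithm

    2**(k1+k2) * (1 + m1 + m2)       if m1 + m2 < 1
    2**(k1+k2+1) * (m1 + m2)         otherwise,

which a circuit realizes purely with leading-one detection, shifts and
adds.  Mitchell multiplication never overestimates the exact product of
two positive operands and is exact whenever a mantissa is zero (a
power-of-two operand).

Two cheaper variants truncate operands before the logarithmic path:

* ``mitchell_dynamic_trunc`` keeps only the leading one plus ``w - 1``
  following bits of each operand (dynamic truncation anchored at the
  leading one); the preset ``w=5`` mirrors the headline parameter of
  DR-ALM5-class designs.
* ``mitchell_two_stage_trim`` first trims each operand to its top
  ``o`` significant bits, then trims the Mitchell mantissa to ``t``
  bits; the preset ``(o, t) = (8, 4)`` mirrors TL16-8/4-class designs.

These are clean parameterized stand-ins named "*-like": the cited
hardware designs add design-specific compensation logic that is out of
scope here.  Truncation discards low bits with no rounding compensation.
Signs are handled in sign-magnitude form (XOR of the operand signs,
applied last); the most negative payload -32768 saturates to magnitude
32767 before the logarithmic path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .fixed_point import DEFAULT_SPEC, FixedPointScalar, WideAccumulator

__all__ = [
    "MultiplierSpec",
    "Multiplier",
    "ErrorStats",
    "exact_mul",
    "mitchell_mul",
    "trimmed_mul",
    "characterize",
    "MULTIPLIER_PRESETS",
    "make_multiplier",
]

KINDS = ("exact", "mitchell", "mitchell_dynamic_trunc", "mitchell_two_stage_trim")

# exhaustive characterization is refused above this many operand bits
MAX_EXHAUSTIVE_BITS = 10


@dataclass(frozen=True)
class MultiplierSpec:
    """Selects and parameterizes one multiplier behavior.

    ``trunc_width`` is the number of significant bits kept per operand for
    the dynamic-truncation variant; ``trim_bits`` is the (operand width,
    mantissa width) pair for the two-stage variant.  ``exact`` ignores both.
    """

    kind: str = "exact"
    trunc_width: int = 5
    trim_bits: Tuple[int, int] = (8, 4)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown multiplier kind {self.kind!r}; expected one of {KINDS}")
        if not 1 <= self.trunc_width <= 15:
            raise ValueError("trunc_width must be in [1, 15]")
        if not all(1 <= b <= 15 for b in self.trim_bits):
            raise ValueError("trim widths must be in [1, 15]")


MULTIPLIER_PRESETS = {
    "exact": MultiplierSpec("exact"),
    "mitchell": MultiplierSpec("mitchell"),
    "dr-alm5-like": MultiplierSpec("mitchell_dynamic_trunc", trunc_width=5),
    "tl16-8-4-like": MultiplierSpec("mitchell_two_stage_trim", trim_bits=(8, 4)),
}


@dataclass(frozen=True)
class ErrorStats:
    """Error characterization of one multiplier against the exact product.

    ``nmed`` is the mean absolute error normalized by the maximum exact
    product magnitude D_max = (2**15 - 1)**2 for 16-bit signed operands
    (generally ``(2**(b-1) - 1)**2`` at operand width ``b``); ``mred`` is
    the mean relative error over pairs with a nonzero exact product.
    """

    nmed: float
    mred: float
    mean_error: float
    n_samples: int
    seed: Optional[int]


def _truncate_to_top_bits(mag: np.ndarray, k: np.ndarray, width: int) -> np.ndarray:
    """Zero all bits of ``mag`` below its top ``width`` significant bits."""
    shift = np.maximum(k + 1 - width, 0)
    return (mag >> shift) << shift


def _mantissa_trim(mant: np.ndarray, k: np.ndarray, width: int) -> np.ndarray:
    """Keep the top ``width`` bits of a mantissa that has ``k`` fraction bits."""
    shift = np.maximum(k - width, 0)
    return (mant >> shift) << shift


def _characteristic(mag: np.ndarray) -> np.ndarray:
    """Floor of log2 of a positive integer array (position of the leading one)."""
    # frexp is exact on integers < 2**53: mag = frac * 2**exp, frac in [0.5, 1)
    _, exp = np.frexp(mag.astype(np.float64))
    return (exp - 1).astype(np.int64)


def _mitchell_payloads(a: np.ndarray, b: np.ndarray, spec: MultiplierSpec) -> np.ndarray:
    """Vectorized Mitchell-family product of int64 payload arrays."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    sign = np.where((a < 0) != (b < 0), -1, 1)
    # |INT16_MIN| is unrepresentable in 15 bits: saturate before the log path
    mag_a = np.minimum(np.abs(a), 32767)
    mag_b = np.minimum(np.abs(b), 32767)
    nonzero = (mag_a > 0) & (mag_b > 0)
    # avoid log of zero lanes; they are masked out at the end
    ma = np.where(nonzero, mag_a, 1)
    mb = np.where(nonzero, mag_b, 1)

    if spec.kind == "mitchell_dynamic_trunc":
        ka, kb = _characteristic(ma), _characteristic(mb)
        ma = _truncate_to_top_bits(ma, ka, spec.trunc_width)
        mb = _truncate_to_top_bits(mb, kb, spec.trunc_width)
    elif spec.kind == "mitchell_two_stage_trim":
        ka, kb = _characteristic(ma), _characteristic(mb)
        ma = _truncate_to_top_bits(ma, ka, spec.trim_bits[0])
        mb = _truncate_to_top_bits(mb, kb, spec.trim_bits[0])

    ka, kb = _characteristic(ma), _characteristic(mb)
    mant_a = ma - (np.int64(1) << ka)
    mant_b = mb - (np.int64(1) << kb)
    if spec.kind == "mitchell_two_stage_trim":
        mant_a = _mantissa_trim(mant_a, ka, spec.trim_bits[1])
        mant_b = _mantissa_trim(mant_b, kb, spec.trim_bits[1])

    # mantissa sum at the common denominator 2**(ka+kb)
    s = (mant_a << kb) + (mant_b << ka)
    one = np.int64(1) << (ka + kb)
    result = np.where(s < one, one + s, s << 1)
    return np.where(nonzero, sign * result, 0)


def _exact_payloads(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.asarray(a, dtype=np.int64) * np.asarray(b, dtype=np.int64)


def multiply_payloads(a: np.ndarray, b: np.ndarray, spec: MultiplierSpec) -> np.ndarray:
    """Elementwise product of payload arrays under the selected multiplier."""
    if spec.kind == "exact":
        return _exact_payloads(a, b)
    return _mitchell_payloads(a, b, spec)


def exact_mul(a: FixedPointScalar, b: FixedPointScalar) -> WideAccumulator:
    """Exact signed product; fraction bits add."""
    return WideAccumulator(a.payload * b.payload, a.spec.fraction_bits + b.spec.fraction_bits)


def mitchell_mul(
    a: FixedPointScalar, b: FixedPointScalar, spec: MultiplierSpec = MultiplierSpec("mitchell")
) -> WideAccumulator:
    """Plain Mitchell logarithmic product (no truncation)."""
    p = int(_mitchell_payloads(np.array([a.payload]), np.array([b.payload]), spec)[0])
    return WideAccumulator(p, a.spec.fraction_bits + b.spec.fraction_bits)


def trimmed_mul(a: FixedPointScalar, b: FixedPointScalar, spec: MultiplierSpec) -> WideAccumulator:
    """Truncating Mitchell variants (dynamic truncation or two-stage trim)."""
    if spec.kind not in ("mitchell_dynamic_trunc", "mitchell_two_stage_trim"):
        raise ValueError(f"trimmed_mul requires a truncating kind, got {spec.kind!r}")
    p = int(_mitchell_payloads(np.array([a.payload]), np.array([b.payload]), spec)[0])
    return WideAccumulator(p, a.spec.fraction_bits + b.spec.fraction_bits)


class Multiplier:
    """A multiplier instance with an invocation counter.

    The counter tallies scalar multiplier activations, the quantity the
    cost model is built on: one :meth:`__call__` is one activation, and a
    vectorized :meth:`on_payloads` call counts one per element.
    """

    def __init__(self, spec: MultiplierSpec):
        self.spec = spec
        self.calls = 0

    def reset(self) -> None:
        self.calls = 0

    def __call__(self, a: FixedPointScalar, b: FixedPointScalar) -> WideAccumulator:
        self.calls += 1
        p = int(multiply_payloads(np.array([a.payload]), np.array([b.payload]), self.spec)[0])
        return WideAccumulator(p, a.spec.fraction_bits + b.spec.fraction_bits)

    def on_payloads(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = np.asarray(a)
        self.calls += a.size
        return multiply_payloads(a, b, self.spec)


def make_multiplier(name_or_spec) -> Multiplier:
    """Build a counting multiplier from a preset name or a MultiplierSpec."""
    if isinstance(name_or_spec, MultiplierSpec):
        return Multiplier(name_or_spec)
    try:
        return Multiplier(MULTIPLIER_PRESETS[name_or_spec])
    except KeyError:
        raise ValueError(
            f"unknown multiplier {name_or_spec!r}; presets: {sorted(MULTIPLIER_PRESETS)}"
        ) from None


def characterize(
    spec: MultiplierSpec,
    n_samples: int = 1_000_000,
    seed: int = 0,
    exhaustive_bits: Optional[int] = None,
) -> ErrorStats:
    """Measure NMED / MRED / mean error of a multiplier against the exact product.

    Either draws ``n_samples`` uniform signed 16-bit operand pairs (seeded,
    reproducible) or, with ``exhaustive_bits = b <= 10``, enumerates every
    signed b-bit operand pair.  NMED is normalized by the largest exact
    product magnitude at the operand width.
    """
    if exhaustive_bits is not None:
        if exhaustive_bits > MAX_EXHAUSTIVE_BITS:
            raise ValueError(
                f"exhaustive characterization above {MAX_EXHAUSTIVE_BITS}-bit operands "
                f"(2**20 pairs) is refused; use sampling instead"
            )
        lo, hi = -(1 << (exhaustive_bits - 1)), (1 << (exhaustive_bits - 1)) - 1
        ops = np.arange(lo, hi + 1, dtype=np.int64)
        a, b = np.meshgrid(ops, ops, indexing="ij")
        a, b = a.ravel(), b.ravel()
        d_max = float(hi) ** 2
        used_seed = None
    else:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        a = rng.integers(-32768, 32768, size=n_samples, dtype=np.int64)
        b = rng.integers(-32768, 32768, size=n_samples, dtype=np.int64)
        d_max = float((1 << 15) - 1) ** 2
        used_seed = seed

    approx = multiply_payloads(a, b, spec)
    exact = _exact_payloads(a, b)
    err = (approx - exact).astype(np.float64)
    abs_err = np.abs(err)
    nz = exact != 0
    mred = float(np.mean(abs_err[nz] / np.abs(exact[nz]).astype(np.float64))) if nz.any() else 0.0
    return ErrorStats(
        nmed=float(np.mean(abs_err)) / d_max,
        mred=mred,
        mean_error=float(np.mean(err)),
        n_samples=int(a.size),
        seed=used_seed,
    )
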