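"""Signed 16-bit fixed-point number system Q(16, f).

Every operand that enters the GEMM unit is a 16-bit two's-complement
integer payload interpreted as ``payload / 2**f``.  The default format is
Q(16, 12): 3 integer bits, 12 fraction bits, one sign bit, covering
[-8, 8) with a resolution of 2**-12.

Quantization floors (rounds toward minus infinity) and saturates, so an
out-of-range real value clips to the nearest representable extreme rather
than wrapping.  Products of two Q(16, f) numbers are held in a wide
accumulator at 2f fraction bits; accumulation is exact (unbounded Python
integers), and :func:`requantize` brings an accumulator back to 16 bits
with the same floor-and-saturate convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantizationSpec",
    "FixedPointScalar",
    "WideAccumulator",
    "DEFAULT_SPEC",
    "quantize",
    "dequantize",
    "requantize",
    "quantize_array",
    "dequantize_array",
    "requantize_array",
]

INT16_MIN = -(1 << 15)
INT16_MAX = (1 << 15) - 1


@dataclass(frozen=True)
class QuantizationSpec:
    """Fixed-point format: ``total_bits`` wide with ``fraction_bits`` below the binary point."""

    total_bits: int = 16
    fraction_bits: int = 12

    def __post_init__(self) -> None:
        if self.total_bits != 16:
            raise ValueError("only 16-bit operands are supported")
        if not 0 <= self.fraction_bits < self.total_bits:
            raise ValueError("fraction_bits must lie in [0, total_bits)")

    @property
    def scale(self) -> int:
        return 1 << self.fraction_bits

    @property
    def min_real(self) -> float:
        return INT16_MIN / self.scale

    @property
    def max_real(self) -> float:
        return INT16_MAX / self.scale


DEFAULT_SPEC = QuantizationSpec()


@dataclass(frozen=True)
class FixedPointScalar:
    """One 16-bit operand: integer ``payload`` with value ``payload / 2**f``."""

    payload: int
    spec: QuantizationSpec = DEFAULT_SPEC

    def __post_init__(self) -> None:
        if not INT16_MIN <= self.payload <= INT16_MAX:
            raise ValueError(f"payload {self.payload} outside 16-bit signed range")

    @property
    def value(self) -> float:
        return self.payload / self.spec.scale


@dataclass(frozen=True)
class WideAccumulator:
    """Wide product/accumulator: exact integer payload at ``fraction_bits`` (2f for a raw product).

    The payload is an unbounded Python integer, emulating exact adders; an
    optional saturating view at a chosen bit width is available through
    :meth:`saturated`.
    """

    payload: int
    fraction_bits: int

    @property
    def value(self) -> float:
        return self.payload / (1 << self.fraction_bits)

    def saturated(self, bits: int) -> "WideAccumulator":
        """Clamp the payload to a signed ``bits``-wide range (hardware-faithful mode)."""
        lo, hi = -(1 << (bits - 1)), (1 << (bits - 1)) - 1
        return WideAccumulator(min(max(self.payload, lo), hi), self.fraction_bits)


def quantize(v: float, spec: QuantizationSpec = DEFAULT_SPEC) -> FixedPointScalar:
    """Quantize a real value: ``floor(v * 2**f)`` saturated to the 16-bit signed range."""
    if not math.isfinite(v):
        raise ValueError(f"cannot quantize non-finite value {v!r}")
    payload = math.floor(v * spec.scale)
    payload = min(max(payload, INT16_MIN), INT16_MAX)
    return FixedPointScalar(payload, spec)


def dequantize(x: FixedPointScalar) -> float:
    """Exact real value ``payload / 2**f``."""
    return x.payload / x.spec.scale


def requantize(p: WideAccumulator, spec: QuantizationSpec = DEFAULT_SPEC) -> FixedPointScalar:
    """Bring a wide accumulator back to Q(16, f).

    Arithmetic right shift by the excess fraction bits (floor rounding,
    matching the quantizer), then saturate to the 16-bit signed range.
    """
    shift = p.fraction_bits - spec.fraction_bits
    if shift < 0:
        raise ValueError("accumulator has fewer fraction bits than the target format")
    payload = p.payload >> shift  # arithmetic shift: floors for negatives too
    payload = min(max(payload, INT16_MIN), INT16_MAX)
    return FixedPointScalar(payload, spec)


# -- vectorized counterparts (payload arrays, int64) -------------------------

def quantize_array(v: np.ndarray, spec: QuantizationSpec = DEFAULT_SPEC) -> np.ndarray:
    """Vectorized :func:`quantize`; returns an int64 payload array."""
    v = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot quantize non-finite values")
    payload = np.floor(v * spec.scale)
    return np.clip(payload, INT16_MIN, INT16_MAX).astype(np.int64)


def dequantize_array(payload: np.ndarray, spec: QuantizationSpec = DEFAULT_SPEC) -> np.ndarray:
    return np.asarray(payload, dtype=np.float64) / spec.scale


def requantize_array(
    payload: np.ndarray, fraction_bits: int, spec: QuantizationSpec = DEFAULT_SPEC
) -> np.ndarray:
    """Vectorized :func:`requantize` on an int64 accumulator array."""
    shift = fraction_bits - spec.fraction_bits
    if shift < 0:
        raise ValueError("accumulator has fewer fraction bits than the target format")
    out = np.asarray(payload, dtype=np.int64) >> shift
    return np.clip(out, INT16_MIN, INT16_MAX)
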