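"""Emulation of the 4x4 GEMM unit: MAC, MAC4, and the tile update C <- C + A x B.

The hardware unit wires 16 MAC4 blocks (64 multipliers and adders in
total) so that one invocation performs a full 4x4 multiply-accumulate in
one clock cycle.  This module emulates it functionally: one
:func:`gemm_update` call is one clock cycle's work and activates the
multiplier exactly 64 times, which the :class:`~agemm.multipliers.Multiplier`
counter records for the cost model.  Products may be approximate;
accumulation is always exact integer addition (approximation is confined
to the multipliers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fixed_point import DEFAULT_SPEC, FixedPointScalar, QuantizationSpec, WideAccumulator
from .multipliers import Multiplier

__all__ = ["TILE", "TileMatrix", "AccumTile", "mac", "mac4", "gemm_update"]

TILE = 4


@dataclass(frozen=True)
class TileMatrix:
    """A 4x4 operand tile (matrix A or B) of int64 payloads in a shared format."""

    payloads: np.ndarray
    spec: QuantizationSpec = DEFAULT_SPEC

    def __post_init__(self) -> None:
        arr = np.asarray(self.payloads, dtype=np.int64)
        if arr.shape != (TILE, TILE):
            raise ValueError(f"tile must be {TILE}x{TILE}, got {arr.shape}")
        object.__setattr__(self, "payloads", arr)

    def scalar(self, i: int, j: int) -> FixedPointScalar:
        return FixedPointScalar(int(self.payloads[i, j]), self.spec)


@dataclass(frozen=True)
class AccumTile:
    """A 4x4 accumulator tile (matrix C) at a shared fraction-bit count (2f for products)."""

    payloads: np.ndarray
    fraction_bits: int = 2 * DEFAULT_SPEC.fraction_bits

    def __post_init__(self) -> None:
        arr = np.asarray(self.payloads, dtype=np.int64)
        if arr.shape != (TILE, TILE):
            raise ValueError(f"accumulator tile must be {TILE}x{TILE}, got {arr.shape}")
        object.__setattr__(self, "payloads", arr)

    @classmethod
    def zeros(cls, fraction_bits: int = 2 * DEFAULT_SPEC.fraction_bits) -> "AccumTile":
        return cls(np.zeros((TILE, TILE), dtype=np.int64), fraction_bits)


def mac(c: WideAccumulator, a: FixedPointScalar, b: FixedPointScalar, mul: Multiplier) -> WideAccumulator:
    """One multiply-accumulate: c' = c + mul(a, b), with an exact add."""
    p = mul(a, b)
    if p.fraction_bits != c.fraction_bits:
        raise ValueError("accumulator and product fraction bits disagree")
    return WideAccumulator(c.payload + p.payload, c.fraction_bits)


def mac4(
    c: WideAccumulator,
    a: Sequence[FixedPointScalar],
    b: Sequence[FixedPointScalar],
    mul: Multiplier,
) -> WideAccumulator:
    """Dot-product update: c' = c + sum_i mul(a_i, b_i) over vectors of length four."""
    if len(a) != TILE or len(b) != TILE:
        raise ValueError(f"mac4 requires vectors of length {TILE}")
    ap = np.array([x.payload for x in a], dtype=np.int64)
    bp = np.array([x.payload for x in b], dtype=np.int64)
    prods = mul.on_payloads(ap, bp)
    return WideAccumulator(c.payload + int(prods.sum()), c.fraction_bits)


def gemm_update(C: AccumTile, A: TileMatrix, B: TileMatrix, mul: Multiplier) -> AccumTile:
    """One GEMM-unit invocation: C'[i,j] = C[i,j] + sum_k mul(A[i,k], B[k,j]).

    Exactly 64 multiplier activations per call (16 dot-products of length
    four), matching the hardware's single-cycle datapath.
    """
    if A.spec != B.spec:
        raise ValueError("operand tiles must share a quantization spec")
    if C.fraction_bits != 2 * A.spec.fraction_bits:
        raise ValueError("accumulator fraction bits must equal 2f of the operands")
    # all 64 operand pairs of the 16 MAC4 dot-products, in one counted batch:
    # pair [i, j, k] holds (A[i, k], B[k, j])
    a_ops = np.broadcast_to(A.payloads[:, None, :], (TILE, TILE, TILE))
    b_ops = np.broadcast_to(B.payloads.T[None, :, :], (TILE, TILE, TILE))
    prods = mul.on_payloads(np.ascontiguousarray(a_ops), np.ascontiguousarray(b_ops))
    return AccumTile(C.payloads + prods.sum(axis=2), C.fraction_bits)
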