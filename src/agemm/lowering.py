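"""Lowering of convolutional layers to tiled 4x4 GEMM.

A convolution of a C-channel I-by-I input with K filters of C x F x F
elements at stride S is rewritten as a matrix product: each filter
becomes one row of the K-by-CF^2 filter matrix, each input patch becomes
one column of the CF^2-by-O^2 input matrix, and the K-by-O^2 product is
reshaped back to the output tensor.  Both matrices are zero-padded to
multiples of the 4x4 tile size and the product is computed tile by tile
with the GEMM unit: the output holds ceil(K/4) * ceil(O^2/4) tiles and
each tile takes ceil(CF^2/4) unit invocations.

Convolutions use "same" zero padding, so O = ceil(I / S) — the only
convention consistent with the backbone layer table.  Pooling (2x2 max,
stride 2) and nearest-neighbour 2x upsampling involve no multiplications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .fixed_point import DEFAULT_SPEC, QuantizationSpec, quantize, requantize_array
from .gemm import TILE, AccumTile, TileMatrix, gemm_update
from .multipliers import Multiplier

__all__ = [
    "LayerConfig",
    "Tensor",
    "LoweredMatrices",
    "output_size",
    "im2col",
    "filters_to_matrix",
    "tiled_matmul",
    "conv_layer",
    "maxpool",
    "upsample",
    "load_layer_table",
]

LAYER_TYPES = ("conv", "pool", "upsample")
_TYPE_CODES = {"c": "conv", "p": "pool", "u": "upsample"}


@dataclass(frozen=True)
class LayerConfig:
    """One backbone layer row: type, input size I, channels C, filter size F,
    stride S (0.5 encodes 2x upsampling), filter count K, output size O."""

    layer_type: str
    I: int
    C: int
    F: int
    S: Union[int, float, Fraction]
    K: int
    O: int
    layer_id: int = 0

    def __post_init__(self) -> None:
        if self.layer_type not in LAYER_TYPES:
            raise ValueError(f"layer_type must be one of {LAYER_TYPES}")
        if min(self.I, self.C, self.F, self.K, self.O) <= 0 or self.S <= 0:
            raise ValueError("all layer parameters must be positive")
        expected = output_size(self.I, self.F, self.S, self.layer_type)
        if expected != self.O:
            raise ValueError(
                f"layer {self.layer_id}: output size {self.O} inconsistent with "
                f"I={self.I}, S={self.S} (expected {expected})"
            )


@dataclass(frozen=True)
class Tensor:
    """A dense C x H x W activation tensor of fixed-point payloads."""

    payloads: np.ndarray  # int64, shape (C, H, W)
    spec: QuantizationSpec = DEFAULT_SPEC

    def __post_init__(self) -> None:
        arr = np.asarray(self.payloads, dtype=np.int64)
        if arr.ndim != 3:
            raise ValueError(f"tensor must be C x H x W, got shape {arr.shape}")
        object.__setattr__(self, "payloads", arr)

    @property
    def shape(self) -> tuple:
        return self.payloads.shape


@dataclass(frozen=True)
class LoweredMatrices:
    """Filter matrix (K x CF^2) and input matrix (CF^2 x O^2), zero-padded to tiles."""

    filter_matrix: np.ndarray
    input_matrix: np.ndarray
    K: int
    O: int
    CF2: int
    spec: QuantizationSpec = DEFAULT_SPEC


def output_size(I: int, F: int, S, layer_type: str = "conv") -> int:
    """Output channel size O for a layer.

    conv: O = ceil(I/S) (same padding); pool: O = I/S exactly; upsample: O = 2I.
    """
    if layer_type == "conv":
        return math.ceil(I / S)
    if layer_type == "pool":
        o = Fraction(I) / Fraction(S)
        if o.denominator != 1:
            raise ValueError(f"pooling size {I} not divisible by stride {S}")
        return int(o)
    if layer_type == "upsample":
        return 2 * I
    raise ValueError(f"unknown layer type {layer_type!r}")


def _pad_to_tile(n: int) -> int:
    return TILE * math.ceil(n / TILE)


def im2col(x: Tensor, F: int, S: int) -> np.ndarray:
    """Rearrange input patches into the CF^2 x O^2 matrix (unpadded).

    Column j holds the zero-padded F x F x C patch at output position j
    (row-major over output positions; channel-major within the column:
    index c*F*F + fy*F + fx).  Patch anchoring for output position (oy, ox)
    covers input rows [oy*S - (F-1)//2, oy*S - (F-1)//2 + F).
    """
    C, H, W = x.payloads.shape
    O_h = math.ceil(H / S)
    O_w = math.ceil(W / S)
    off = (F - 1) // 2
    # pad generously and slice; zero padding is exact in fixed point
    padded = np.zeros((C, H + 2 * F, W + 2 * F), dtype=np.int64)
    padded[:, F : F + H, F : F + W] = x.payloads
    cols = np.empty((C * F * F, O_h * O_w), dtype=np.int64)
    for fy in range(F):
        for fx in range(F):
            rows = np.arange(O_h) * S - off + fy + F
            cols_idx = np.arange(O_w) * S - off + fx + F
            patch = padded[:, rows][:, :, cols_idx]  # (C, O_h, O_w)
            idx = fy * F + fx
            cols[idx :: F * F, :] = patch.reshape(C, O_h * O_w)
    return cols


def filters_to_matrix(filters: np.ndarray) -> np.ndarray:
    """Flatten K filters of shape (C, F, F) into the K x CF^2 filter matrix.

    Row k uses the same channel-major order as :func:`im2col` columns, so
    unflattening a row reproduces the filter.
    """
    filters = np.asarray(filters, dtype=np.int64)
    if filters.ndim != 4:
        raise ValueError(f"filters must have shape (K, C, F, F), got {filters.shape}")
    K = filters.shape[0]
    return filters.reshape(K, -1)


def lower(x: Tensor, filters: np.ndarray, S: int) -> LoweredMatrices:
    """Lower one convolution to padded filter/input matrices."""
    filters = np.asarray(filters, dtype=np.int64)
    K, C, F, _ = filters.shape
    if C != x.payloads.shape[0]:
        raise ValueError("filter channel count does not match the input tensor")
    fm = filters_to_matrix(filters)
    im = im2col(x, F, S)
    CF2, O2 = im.shape
    O = int(math.isqrt(O2))
    fpad = np.zeros((_pad_to_tile(K), _pad_to_tile(CF2)), dtype=np.int64)
    fpad[:K, :CF2] = fm
    ipad = np.zeros((_pad_to_tile(CF2), _pad_to_tile(O2)), dtype=np.int64)
    ipad[:CF2, :O2] = im
    return LoweredMatrices(fpad, ipad, K=K, O=O, CF2=CF2, spec=x.spec)


def tiled_matmul(lm: LoweredMatrices, mul: Multiplier) -> np.ndarray:
    """Multiply the lowered matrices tile by tile with the GEMM unit.

    Each 4x4 output tile accumulates ceil(CF^2/4) successive gemm_update
    calls; padding rows/columns are stripped from the returned K x O^2
    accumulator matrix (fraction bits 2f).
    """
    fm, im = lm.filter_matrix, lm.input_matrix
    n_i, n_k = fm.shape[0] // TILE, fm.shape[1] // TILE
    n_j = im.shape[1] // TILE
    out = np.zeros((fm.shape[0], im.shape[1]), dtype=np.int64)
    frac = 2 * lm.spec.fraction_bits
    for ti in range(n_i):
        for tj in range(n_j):
            acc = AccumTile.zeros(frac)
            for tk in range(n_k):
                A = TileMatrix(fm[ti * TILE : (ti + 1) * TILE, tk * TILE : (tk + 1) * TILE], lm.spec)
                B = TileMatrix(im[tk * TILE : (tk + 1) * TILE, tj * TILE : (tj + 1) * TILE], lm.spec)
                acc = gemm_update(acc, A, B, mul)
            out[ti * TILE : (ti + 1) * TILE, tj * TILE : (tj + 1) * TILE] = acc.payloads
    return out[: lm.K, : lm.O * lm.O]


def _leaky_relu_payloads(p: np.ndarray, spec: QuantizationSpec) -> np.ndarray:
    """Leaky ReLU with the 0.1 slope quantized to the operand format.

    Emulates a lookup-table activation: the scaling happens outside the
    GEMM datapath and is never counted as a multiplier invocation.
    """
    slope = quantize(0.1, spec).payload
    return np.where(p >= 0, p, (p * slope) >> spec.fraction_bits)


_ACTIVATIONS = ("identity", "leaky_relu")


def conv_layer(
    x: Tensor,
    filters: np.ndarray,
    cfg: LayerConfig,
    mul: Multiplier,
    activation: str = "leaky_relu",
) -> Tensor:
    """Run one convolutional layer through the tiled GEMM pipeline.

    Lower, multiply tile-wise, requantize the wide accumulators back to
    Q(16, f) once per layer, then apply the activation elementwise.
    """
    if cfg.layer_type != "conv":
        raise ValueError("conv_layer requires a conv LayerConfig")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"activation must be one of {_ACTIVATIONS}")
    filters = np.asarray(filters, dtype=np.int64)
    K, C, F, _ = filters.shape
    if (K, C, F) != (cfg.K, cfg.C, cfg.F):
        raise ValueError("filter shapes inconsistent with the layer config")
    if x.payloads.shape != (cfg.C, cfg.I, cfg.I):
        raise ValueError("input tensor shape inconsistent with the layer config")
    lm = lower(x, filters, int(cfg.S))
    acc = tiled_matmul(lm, mul)  # K x O^2 at 2f
    out = requantize_array(acc, 2 * x.spec.fraction_bits, x.spec)
    if activation == "leaky_relu":
        out = _leaky_relu_payloads(out, x.spec)
    return Tensor(out.reshape(cfg.K, cfg.O, cfg.O), x.spec)


def maxpool(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling (multiplication-free)."""
    C, H, W = x.payloads.shape
    if H % 2 or W % 2:
        raise ValueError(f"pooling requires even spatial dimensions, got {H}x{W}")
    p = x.payloads.reshape(C, H // 2, 2, W // 2, 2)
    return Tensor(p.max(axis=(2, 4)), x.spec)


def upsample(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling (multiplication-free)."""
    p = np.repeat(np.repeat(x.payloads, 2, axis=1), 2, axis=2)
    return Tensor(p, x.spec)


def load_layer_table(path: Union[str, Path]) -> List[LayerConfig]:
    """Parse a backbone layer table (TSV with columns layer, type, I, C, F, S, K, O).

    Type codes are c/p/u for conv/pool/upsample; each row's output size is
    validated against :func:`output_size` when the config is constructed.
    """
    df = pd.read_csv(path, sep="\t")
    cfgs = []
    for row in df.itertuples(index=False):
        s = Fraction(str(row.S))
        cfgs.append(
            LayerConfig(
                layer_type=_TYPE_CODES[str(row.type)],
                I=int(row.I),
                C=int(row.C),
                F=int(row.F),
                S=int(s) if s.denominator == 1 else s,
                K=int(row.K),
                O=int(row.O),
                layer_id=int(row.layer),
            )
        )
    return cfgs
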