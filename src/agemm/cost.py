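"""Invocation-count and latency model of the GEMM/AGEMM unit.

A convolutional layer lowered to tiled matrix multiplication needs

    ceil(K/4) * ceil(O^2/4) * ceil(C*F^2/4)

invocations of the 4x4 GEMM unit; pooling and upsampling layers need
none.  With a per-invocation propagation delay d (a synthesis constant,
supplied as configuration) and n identical units working concurrently,
the theoretical arithmetic-only lower bound on one inference pass is

    time = total_invocations * d / n,

the throughput is its reciprocal, and the speedup of one unit over a
reference is simply the delay ratio (the invocation counts cancel).
Memory-transfer time is deliberately ignored: this is a lower bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .lowering import LayerConfig

__all__ = [
    "UnitTiming",
    "CostReport",
    "layer_invocations",
    "backbone_invocations",
    "execution_time",
    "images_per_second",
    "speedup",
    "cost_report",
    "load_unit_timings",
    "round_ms",
    "round_rate",
]


@dataclass(frozen=True)
class UnitTiming:
    """Synthesis measurements of one unit: delay in ns per invocation,
    optional power (mW), area (1e3 um^2) and power-delay product (pJ).
    These are configuration constants, never computed here."""

    name: str
    delay: float
    power: Optional[float] = None
    area: Optional[float] = None
    pdp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delay <= 0:
            raise ValueError("delay must be positive")


@dataclass(frozen=True)
class CostReport:
    per_layer: Tuple[Tuple[int, int], ...]  # (layer id, invocations)
    total_invocations: int
    execution_time: float  # seconds
    images_per_second: float
    n_units: int
    timing: UnitTiming
    speedup_vs_reference: Optional[float] = None


def layer_invocations(cfg: LayerConfig) -> int:
    """GEMM-unit invocations for one layer (0 for pool/upsample)."""
    if cfg.layer_type != "conv":
        return 0
    tiles_out = math.ceil(cfg.K / 4) * math.ceil(cfg.O**2 / 4)
    passes = math.ceil(cfg.C * cfg.F**2 / 4)
    return tiles_out * passes


def backbone_invocations(cfgs: Sequence[LayerConfig]) -> int:
    """Total invocations for one inference pass over a layer list."""
    if not cfgs:
        raise ValueError("layer list must be non-empty")
    return sum(layer_invocations(c) for c in cfgs)


def execution_time(total: int, timing: UnitTiming, n_units: int = 1) -> float:
    """Arithmetic-only execution time in seconds for n concurrent units."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    return total * timing.delay * 1e-9 / n_units


def images_per_second(total: int, timing: UnitTiming, n_units: int = 1) -> float:
    return 1.0 / execution_time(total, timing, n_units)


def speedup(reference: UnitTiming, candidate: UnitTiming) -> float:
    """Execution-time ratio reference/candidate; invocation counts cancel."""
    return reference.delay / candidate.delay


def round_ms(seconds: float, decimals: int = 1) -> float:
    """Milliseconds rounded half-up, the convention of reported latencies."""
    ms = seconds * 1e3
    q = 10**decimals
    return math.floor(ms * q + 0.5) / q


def round_rate(rate: float) -> int:
    """Throughput rounded to whole inferences per second."""
    return math.floor(rate + 0.5)


def cost_report(
    cfgs: Sequence[LayerConfig],
    timing: UnitTiming,
    n_units: int = 1,
    reference: Optional[UnitTiming] = None,
) -> CostReport:
    per_layer = tuple((c.layer_id, layer_invocations(c)) for c in cfgs)
    total = sum(n for _, n in per_layer)
    t = execution_time(total, timing, n_units)
    return CostReport(
        per_layer=per_layer,
        total_invocations=total,
        execution_time=t,
        images_per_second=1.0 / t,
        n_units=n_units,
        timing=timing,
        speedup_vs_reference=speedup(reference, timing) if reference else None,
    )


def load_unit_timings(path=None) -> Dict[str, UnitTiming]:
    """Load unit timing constants from YAML (the bundled file by default)."""
    if path is None:
        src = resources.files("agemm.data").joinpath("unit_timings.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {
        name: UnitTiming(name=name, **vals) for name, vals in raw["units"].items()
    }
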