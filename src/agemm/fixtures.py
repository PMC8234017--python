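"""Seeded generators for tiles, layers, the backbone table, and synthetic detection scenes.

Every generator is a pure function of its spec: the same seed and size
parameters produce bit-identical output.  The synthetic scene generator
emulates the study setting this package is aimed at — top-down hive-
entrance images with on the order of sixteen honeybees each (the real
benchmark holds 1040 ground-truth boxes over 65 images) — by placing
non-overlapping ground-truth boxes and deriving detections from them
with controlled jitter (localization quality), drop-out (recall) and
spurious boxes (precision).  It stands in for the real dataset, which is
not distributed with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Tuple

import numpy as np

from .detection import BoundingBox, Detection, GroundTruthBox
from .fixed_point import DEFAULT_SPEC, QuantizationSpec, quantize_array
from .gemm import TILE, TileMatrix
from .lowering import LayerConfig, Tensor, load_layer_table, output_size

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "gen_tiles",
    "gen_layer",
    "gen_backbone_table",
    "gen_scene",
]

# real activations/weights live well inside the Q(16,12) range; keep fixture
# values small enough that modest accumulations stay faithful after requantization
_VALUE_RANGE = (-1.0, 1.0)


def gen_tiles(
    seed: int, count: int = 1, spec: QuantizationSpec = DEFAULT_SPEC
) -> List[Tuple[TileMatrix, TileMatrix]]:
    """Seeded random (A, B) operand tile pairs with values in [-1, 1)."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(count):
        a = quantize_array(rng.uniform(*_VALUE_RANGE, (TILE, TILE)), spec)
        b = quantize_array(rng.uniform(*_VALUE_RANGE, (TILE, TILE)), spec)
        pairs.append((TileMatrix(a, spec), TileMatrix(b, spec)))
    return pairs


def gen_layer(
    seed: int,
    I: int = 8,
    C: int = 2,
    F: int = 3,
    S: int = 1,
    K: int = 4,
    spec: QuantizationSpec = DEFAULT_SPEC,
) -> Tuple[Tensor, np.ndarray, LayerConfig]:
    """Seeded random (input tensor, filters, config) for one conv layer."""
    if min(I, C, F, S, K) < 1:
        raise ValueError("layer sizes must be positive")
    rng = np.random.default_rng(seed)
    x = Tensor(quantize_array(rng.uniform(*_VALUE_RANGE, (C, I, I)), spec), spec)
    filters = quantize_array(rng.uniform(*_VALUE_RANGE, (K, C, F, F)), spec)
    cfg = LayerConfig("conv", I=I, C=C, F=F, S=S, K=K, O=output_size(I, F, S, "conv"))
    return x, filters, cfg


def gen_backbone_table() -> List[LayerConfig]:
    """The bundled 25-row backbone layer table (verbatim from the data file)."""
    src = resources.files("agemm.data").joinpath("backbone_layers.tsv")
    with resources.as_file(src) as path:
        return load_layer_table(path)


@dataclass(frozen=True)
class SceneSpec:
    """Knobs of the synthetic detection benchmark.

    ``jitter`` shifts and rescales true boxes (as a fraction of box size)
    before they become detections, controlling the IoU distribution;
    ``tp_rate`` is the chance a ground truth produces a detection at all;
    ``fp_rate`` is the expected number of spurious detections per true box.
    """

    seed: int = 0
    n_images: int = 5
    image_size: int = 416
    boxes_per_image: int = 16
    box_size: float = 28.0
    jitter: float = 0.0
    tp_rate: float = 1.0
    fp_rate: float = 0.0
    label: int = 0


@dataclass(frozen=True)
class SyntheticScene:
    spec: SceneSpec
    ground_truth: Tuple[GroundTruthBox, ...]
    detections: Tuple[Detection, ...]

    @property
    def image_sizes(self):
        return {i: (self.spec.image_size, self.spec.image_size) for i in range(self.spec.n_images)}


def _place_boxes(rng, spec: SceneSpec, image_id: int) -> List[GroundTruthBox]:
    """Rejection-sample non-overlapping boxes on one image."""
    boxes: List[GroundTruthBox] = []
    half = spec.box_size / 2
    attempts = 0
    while len(boxes) < spec.boxes_per_image:
        attempts += 1
        if attempts > 200 * spec.boxes_per_image:
            raise ValueError("box density too high to place without overlap")
        cx = rng.uniform(half, spec.image_size - half)
        cy = rng.uniform(half, spec.image_size - half)
        cand = BoundingBox.from_center(cx, cy, spec.box_size, spec.box_size)
        if all(
            max(abs(cx - (g.box.xmin + g.box.xmax) / 2), abs(cy - (g.box.ymin + g.box.ymax) / 2))
            >= 1.5 * spec.box_size
            for g in boxes
        ):
            boxes.append(GroundTruthBox(cand, spec.label, image_id))
    return boxes


def gen_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate ground truths and detections with controlled quality.

    True-positive detections are jittered copies of ground-truth boxes
    with confidences in (0.5, 1.0]; spurious detections land away from the
    layout with confidences in (0.5, 0.9).  All randomness is seeded.
    """
    if 1.5 * spec.box_size * np.sqrt(spec.boxes_per_image) > spec.image_size:
        raise ValueError("infeasible scene density")
    rng = np.random.default_rng(spec.seed)
    gts: List[GroundTruthBox] = []
    dets: List[Detection] = []
    for img in range(spec.n_images):
        img_gts = _place_boxes(rng, spec, img)
        gts.extend(img_gts)
        for g in img_gts:
            if rng.uniform() >= spec.tp_rate:
                continue
            dx = rng.uniform(-spec.jitter, spec.jitter) * spec.box_size
            dy = rng.uniform(-spec.jitter, spec.jitter) * spec.box_size
            scale = 1.0 + rng.uniform(-spec.jitter, spec.jitter)
            w = (g.box.xmax - g.box.xmin) * scale
            h = (g.box.ymax - g.box.ymin) * scale
            cx = (g.box.xmin + g.box.xmax) / 2 + dx
            cy = (g.box.ymin + g.box.ymax) / 2 + dy
            conf = float(rng.uniform(0.55, 1.0))
            dets.append(Detection(BoundingBox.from_center(cx, cy, w, h), conf, spec.label, img))
        n_fp = rng.poisson(spec.fp_rate * spec.boxes_per_image)
        for _ in range(n_fp):
            # spurious boxes are kept clear of every true box so they can
            # never be rescued as matches
            while True:
                cx = rng.uniform(spec.box_size, spec.image_size - spec.box_size)
                cy = rng.uniform(spec.box_size, spec.image_size - spec.box_size)
                if all(
                    max(
                        abs(cx - (g.box.xmin + g.box.xmax) / 2),
                        abs(cy - (g.box.ymin + g.box.ymax) / 2),
                    )
                    >= 1.5 * spec.box_size
                    for g in img_gts
                ):
                    break
            conf = float(rng.uniform(0.51, 0.9))
            dets.append(
                Detection(
                    BoundingBox.from_center(cx, cy, spec.box_size, spec.box_size),
                    conf,
                    spec.label,
                    img,
                )
            )
    return SyntheticScene(spec, tuple(gts), tuple(dets))
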