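"""Independent brute-force oracles the emulator is checked against.

These deliberately avoid the package's shift/add integer paths: the
multiplier oracle works in exact rational arithmetic on binary strings,
the linear-algebra oracles are naive Python loops, and the matching
oracle enumerates assignments exhaustively.
"""

from fractions import Fraction
from itertools import permutations
import math


def oracle_mitchell(a: int, b: int, kind: str = "mitchell", w: int = 5, trim=(8, 4)) -> int:
    """Scalar Mitchell-family product of two signed 16-bit payloads, via Fractions."""
    if a == 0 or b == 0:
        return 0
    sign = -1 if (a < 0) != (b < 0) else 1
    mags = []
    for x in (a, b):
        m = min(abs(x), 32767)
        if kind == "mitchell_dynamic_trunc":
            m = _keep_top_bits(m, w)
        elif kind == "mitchell_two_stage_trim":
            m = _keep_top_bits(m, trim[0])
        mags.append(m)
    ks = [m.bit_length() - 1 for m in mags]
    mants = [Fraction(m - 2**k, 2**k) for m, k in zip(mags, ks)]
    if kind == "mitchell_two_stage_trim":
        t = trim[1]
        mants = [Fraction(math.floor(m * 2**t), 2**t) for m in mants]
    s = mants[0] + mants[1]
    k = ks[0] + ks[1]
    res = 2**k * (1 + s) if s < 1 else 2 ** (k + 1) * s
    assert res.denominator == 1 if isinstance(res, Fraction) else True
    return sign * int(res)


def _keep_top_bits(m: int, width: int) -> int:
    bits = bin(m)[2:]
    if len(bits) <= width:
        return m
    return int(bits[:width] + "0" * (len(bits) - width), 2)


def matmul_loop(A, B):
    """Triple-loop integer matrix product on lists of lists."""
    n, k = len(A), len(A[0])
    m = len(B[0])
    out = [[0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            s = 0
            for kk in range(k):
                s += A[i][kk] * B[kk][j]
            out[i][j] = s
    return out


def conv_loop(x, filters, S):
    """Naive same-padded convolution on integer payload arrays (C,H,W) x (K,C,F,F)."""
    C = len(x)
    H, W = len(x[0]), len(x[0][0])
    K = len(filters)
    F = len(filters[0][0])
    O = math.ceil(H / S)
    off = (F - 1) // 2
    out = [[[0] * O for _ in range(O)] for _ in range(K)]
    for k in range(K):
        for oy in range(O):
            for ox in range(O):
                s = 0
                for c in range(C):
                    for fy in range(F):
                        for fx in range(F):
                            y, xx = oy * S - off + fy, ox * S - off + fx
                            if 0 <= y < H and 0 <= xx < W:
                                s += x[c][y][xx] * filters[k][c][fy][fx]
                out[k][oy][ox] = s
    return out


def optimal_tp_count(det_boxes, gt_boxes, iou_fn, t: float) -> int:
    """Maximum achievable TP count over all one-to-one det-to-GT assignments."""
    n_d, n_g = len(det_boxes), len(gt_boxes)
    feasible = [
        [iou_fn(d, g) >= t for g in gt_boxes] for d in det_boxes
    ]
    best = 0
    slots = list(range(n_g)) + [None] * n_d  # None = unmatched
    for assign in set(permutations(slots, n_d)):
        used = [a for a in assign if a is not None]
        if len(used) != len(set(used)):
            continue
        tp = sum(1 for d, g in enumerate(assign) if g is not None and feasible[d][g])
        best = max(best, tp)
    return best


def ap_101_by_hand(flags, n_gt: int) -> float:
    """101-point interpolated AP from (confidence-sorted) TP flags, by direct enumeration."""
    points = []
    tp = fp = 0
    for is_tp in flags:
        tp += int(is_tp)
        fp += int(not is_tp)
        points.append((tp / n_gt, tp / (tp + fp)))
    total = 0.0
    for i in range(101):
        r = i / 100
        ps = [p for rec, p in points if rec >= r - 1e-12]
        total += max(ps) if ps else 0.0
    return total / 101
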