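"""Enhancement metrics: banded MSE and tolerance-matched loop F1.

Loop matching is set-membership with a closed +/- ``tolerance``-bin square
around each pixel: a predicted loop is a TP if any truth loop lies in its
window (one truth loop may validate several predictions), and a truth loop
is an FN if no prediction lies in its window.  F1 = TP / (TP + (FP + FN)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import BAND_BINS, ContactMap
from .loops import LoopSet

__all__ = ["MatchResult", "matrix_mse", "loop_f1"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tolerance: int

    @property
    def f1(self) -> float:
        denom = self.tp + 0.5 * (self.fp + self.fn)
        return self.tp / denom if denom > 0 else 0.0


def matrix_mse(
    pred: ContactMap | np.ndarray,
    truth: ContactMap | np.ndarray,
    band_bins: int = BAND_BINS,
) -> float:
    """Mean squared difference over the banded pixels |i - j| <= band_bins."""
    p = pred.counts if isinstance(pred, ContactMap) else np.asarray(pred, dtype=float)
    t = truth.counts if isinstance(truth, ContactMap) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if isinstance(pred, ContactMap) and isinstance(truth, ContactMap):
        if pred.normalized != truth.normalized:
            raise ValueError("pred and truth must be on the same normalization")
    n = p.shape[0]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    mask = d <= band_bins
    return float(np.mean((p[mask] - t[mask]) ** 2))


def _as_pixels(loops) -> list[tuple[int, int]]:
    if isinstance(loops, LoopSet):
        return sorted(loops.pixels())
    return sorted(set((int(i), int(j)) for i, j in loops))


def loop_f1(pred, truth, tolerance: int = 5, one_to_one: bool = False) -> MatchResult:
    """Match predicted against truth loops within a +/- tolerance square.

    ``one_to_one`` switches to greedy bipartite matching (each truth loop
    validates at most one prediction), ordered by Chebyshev distance.
    """
    ps = _as_pixels(pred)
    ts = _as_pixels(truth)
    if not ps and not ts:
        return MatchResult(0, 0, 0, tolerance)
    pa = np.array(ps).reshape(-1, 2)
    ta = np.array(ts).reshape(-1, 2)
    if len(ps) and len(ts):
        cheb = np.maximum(
            np.abs(pa[:, None, 0] - ta[None, :, 0]),
            np.abs(pa[:, None, 1] - ta[None, :, 1]),
        )
        hit = cheb <= tolerance
    else:
        hit = np.zeros((len(ps), len(ts)), dtype=bool)
    if one_to_one:
        pairs = sorted(
            ((cheb[i, j], i, j) for i, j in np.argwhere(hit)), key=lambda x: (x[0], x[1], x[2])
        )
        used_p: set[int] = set()
        used_t: set[int] = set()
        tp = 0
        for _, i, j in pairs:
            if i not in used_p and j not in used_t:
                used_p.add(i)
                used_t.add(j)
                tp += 1
        fp = len(ps) - tp
        fn = len(ts) - tp
    else:
        tp = int(hit.any(axis=1).sum())
        fp = len(ps) - tp
        fn = int((~hit.any(axis=0)).sum())
    return MatchResult(tp=tp, fp=fp, fn=fn, tolerance=tolerance)
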