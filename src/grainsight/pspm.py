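"""Position-sensitive prediction: score-map RoI pooling, voting, regression.

The classification pathway produces ``k^2 * (C + 1)`` score maps (``k x k``
spatial bins, ``C`` foreground classes plus background). An RoI of size
``w x h`` is partitioned into ``k x k`` bins of roughly ``w/k x h/k`` cells;
bin ``(i, j)`` for class ``c`` average-pools *only its own* channel
``(i, j, c)`` over the bin's cells. The per-class bin scores are then voted
(averaged over the k^2 bins) and passed through a softmax. A parallel ``4k^2``
pathway pools class-agnostic box-regression deltas the same way. There are no
trainable parameters after the RoI stage.

Channel layout: classification channel ``(j * k + i) * (C + 1) + c`` holds bin
row ``j`` (y), bin column ``i`` (x), class ``c``; regression channel
``(j * k + i) * 4 + q`` holds delta component ``q`` of bin ``(i, j)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RoI",
    "ps_roi_pool",
    "ps_roi_pool_grad",
    "vote_scores",
    "pool_regression",
    "pool_regression_grad",
]


@dataclass(frozen=True)
class RoI:
    """Rectangle in feature-map coordinates (continuous; quantized at pool time)."""

    x0: float
    y0: float
    w: float
    h: float

    def quantize(self) -> tuple[int, int, int, int]:
        """Integer (x0, y0, w, h) with w, h >= 1 after rounding."""
        x0 = int(math.floor(self.x0))
        y0 = int(math.floor(self.y0))
        w = max(1, int(round(self.w)))
        h = max(1, int(round(self.h)))
        return x0, y0, w, h


def _bin_edges(size: int, k: int) -> list[tuple[int, int]]:
    """Cell-quantized bin boundaries: bin i spans floor(i*size/k) .. ceil((i+1)*size/k)."""
    edges = []
    for i in range(k):
        lo = int(math.floor(i * size / k))
        hi = int(math.ceil((i + 1) * size / k))
        edges.append((lo, hi))
    return edges


def _check_roi(roi: RoI, map_h: int, map_w: int) -> tuple[int, int, int, int]:
    x0, y0, w, h = roi.quantize()
    if x0 < 0 or y0 < 0 or x0 + w > map_w or y0 + h > map_h:
        raise ValueError(
            f"RoI ({x0},{y0},{w},{h}) outside feature map {map_w}x{map_h}"
        )
    return x0, y0, w, h


def ps_roi_pool(maps: np.ndarray, roi: RoI, k: int, C: int) -> np.ndarray:
    """Position-sensitive average pooling of classification score maps.

    ``maps`` has shape ``(k*k*(C+1), H, W)``. Returns a ``(k, k, C+1)`` bin
    table indexed ``[j, i, c]`` (bin row, bin column, class). Bins that receive
    zero cells (RoIs smaller than the bin grid) yield 0.
    """
    maps = np.asarray(maps)
    if maps.ndim != 3 or maps.shape[0] != k * k * (C + 1):
        raise ValueError(f"expected ({k * k * (C + 1)}, H, W) maps, got {maps.shape}")
    x0, y0, w, h = _check_roi(roi, maps.shape[1], maps.shape[2])
    out = np.zeros((k, k, C + 1), dtype=np.float64)
    xedges = _bin_edges(w, k)
    yedges = _bin_edges(h, k)
    for j in range(k):
        ylo, yhi = yedges[j]
        for i in range(k):
            xlo, xhi = xedges[i]
            if yhi <= ylo or xhi <= xlo:
                continue  # empty bin
            base = (j * k + i) * (C + 1)
            cells = maps[base : base + C + 1, y0 + ylo : y0 + yhi, x0 + xlo : x0 + xhi]
            out[j, i] = cells.mean(axis=(1, 2))
    return out


def ps_roi_pool_grad(
    grad_bins: np.ndarray, roi: RoI, k: int, C: int, map_shape: tuple[int, int, int]
) -> np.ndarray:
    """Adjoint of :func:`ps_roi_pool` for backpropagation.

    Scatters ``grad_bins`` (``(k, k, C+1)``) back onto score-map gradients of
    ``map_shape``; each bin's gradient is spread uniformly over its cells.
    """
    grad = np.zeros(map_shape, dtype=np.float64)
    x0, y0, w, h = _check_roi(roi, map_shape[1], map_shape[2])
    xedges = _bin_edges(w, k)
    yedges = _bin_edges(h, k)
    for j in range(k):
        ylo, yhi = yedges[j]
        for i in range(k):
            xlo, xhi = xedges[i]
            if yhi <= ylo or xhi <= xlo:
                continue
            n = (yhi - ylo) * (xhi - xlo)
            base = (j * k + i) * (C + 1)
            grad[base : base + C + 1, y0 + ylo : y0 + yhi, x0 + xlo : x0 + xhi] += (
                grad_bins[j, i][:, None, None] / n
            )
    return grad


def vote_scores(bin_table: np.ndarray) -> np.ndarray:
    """Average the k^2 per-class bin scores and softmax across classes.

    Input ``(k, k, C+1)``; output ``(C+1,)`` probabilities summing to 1.
    The vote is parameter-free.
    """
    r = np.asarray(bin_table, dtype=np.float64).mean(axis=(0, 1))
    z = r - r.max()
    e = np.exp(z)
    return e / e.sum()


def pool_regression(maps: np.ndarray, roi: RoI, k: int) -> np.ndarray:
    """Position-sensitive pooling of the ``4k^2`` regression maps.

    Per-bin pooling yields a ``(k, k, 4)`` table whose bin mean is the single
    class-agnostic delta ``(tx, ty, tw, th)`` for the RoI.
    """
    table = ps_roi_pool(maps, roi, k, 3)  # 4 channels per bin == C+1 with C=3
    return table.mean(axis=(0, 1))


def pool_regression_grad(
    grad_delta: np.ndarray, roi: RoI, k: int, map_shape: tuple[int, int, int]
) -> np.ndarray:
    """Adjoint of :func:`pool_regression`."""
    grad_bins = np.broadcast_to(
        np.asarray(grad_delta, dtype=np.float64) / (k * k), (k, k, 4)
    )
    return ps_roi_pool_grad(grad_bins, roi, k, 3, map_shape)
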