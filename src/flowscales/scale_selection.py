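"""Robust-scale selection from a Markov-stability scan.

A scale is *robust* when its optimised partition is (i) persistent across
neighbouring scales — a block of low values in the cross-scale NVI matrix —
and (ii) reproducible under the non-convex optimisation — a dip in the
within-scale ensemble NVI.  The Block NVI curve pools the cross-scale matrix
over a local window and is smoothed; its basins (delimited by the watershed
maxima between local minima) each contribute one selected scale: the argmin
of the within-scale NVI inside the basin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .markov_stability import ScaleScan

__all__ = ["ScaleSelection", "block_nvi", "select_robust_scales", "default_kernel"]


def default_kernel(m: int) -> int:
    """Default pooling half-width: max(1, ceil(m / 20))."""
    return max(1, int(np.ceil(m / 20)))


def block_nvi(scan: ScaleScan, kernel: int) -> np.ndarray:
    """Average-pooled, smoothed diagonal of the cross-scale NVI matrix.

    The pooled value at grid index i is the mean of ``NVI(u, v)`` over all
    u, v within ``kernel`` of i (window truncated at the grid edges); the
    pooled curve is then smoothed by a centred moving average of width
    ``2 * kernel + 1``, also truncated at the edges.
    """
    m = scan.n_scales
    if not 1 <= kernel < m:
        raise InvalidParameterError(f"kernel must be in [1, {m - 1}]")
    C = scan.nvi_cross
    pooled = np.empty(m)
    for i in range(m):
        lo, hi = max(0, i - kernel), min(m, i + kernel + 1)
        pooled[i] = C[lo:hi, lo:hi].mean()
    smooth = np.empty(m)
    for i in range(m):
        lo, hi = max(0, i - kernel), min(m, i + kernel + 1)
        smooth[i] = pooled[lo:hi].mean()
    return smooth


def _local_minima(curve: np.ndarray) -> list[int]:
    """Indices of local minima; plateaus collapse to their central index."""
    m = len(curve)
    # runs of equal value
    minima = []
    i = 0
    while i < m:
        j = i
        while j + 1 < m and curve[j + 1] == curve[i]:
            j += 1
        left_ok = i == 0 or curve[i - 1] > curve[i]
        right_ok = j == m - 1 or curve[j + 1] > curve[j]
        if left_ok and right_ok:
            minima.append((i + j) // 2)
        i = j + 1
    return minima


@dataclass
class ScaleSelection:
    """Outcome of robust-scale selection.

    ``basins`` are inclusive index intervals of the scale grid, one per
    Block-NVI local minimum; ``selected`` holds one scale index per basin
    (the within-scale NVI argmin there).
    """

    block_nvi: np.ndarray
    basins: list
    selected: list
    kernel_size: int

    def selected_scales(self, scan: ScaleScan) -> np.ndarray:
        return scan.scales[self.selected]

    def to_json(self, scan: ScaleScan, path) -> None:
        payload = {
            "kernel": self.kernel_size,
            "basins": [
                {
                    "index_range": [int(a), int(b)],
                    "scale_range": [float(scan.scales[a]), float(scan.scales[b])],
                }
                for a, b in self.basins
            ],
            "selected": [
                {
                    "index": int(i),
                    "scale": float(scan.scales[i]),
                    "n_communities": int(scan.partitions[i].n_communities),
                }
                for i in self.selected
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def select_robust_scales(
    scan: ScaleScan, kernel: int | None = None, max_basins: int | None = None
) -> ScaleSelection:
    """Select one robust scale per basin of the Block NVI curve.

    Basins are delimited by the (watershed) local maxima of the smoothed
    Block NVI between adjacent local minima, and by the grid ends; boundary
    maxima belong to neither basin.  Within each basin the selected scale
    minimises the within-scale ensemble NVI, ties broken toward the basin's
    Block-NVI minimum (then toward the lower index).  A constant Block NVI
    curve yields a single basin spanning the grid.  ``max_basins`` keeps
    only the deepest basins (lowest Block-NVI minimum), preserving scale
    order.
    """
    m = scan.n_scales
    if kernel is None:
        kernel = default_kernel(m)
    curve = block_nvi(scan, kernel)

    if np.ptp(curve) == 0:
        minima = [int(np.argmin(scan.nvi_within))]
        basins = [(0, m - 1)]
    else:
        minima = _local_minima(curve)
        if not minima:  # monotone curve: single basin
            minima = [int(np.argmin(curve))]
        bounds = []
        for a, b in zip(minima[:-1], minima[1:]):
            seg = curve[a + 1 : b]
            bounds.append(a + 1 + int(np.argmax(seg)))
        basins = []
        for idx, mn in enumerate(minima):
            lo = 0 if idx == 0 else bounds[idx - 1] + 1
            hi = m - 1 if idx == len(minima) - 1 else bounds[idx] - 1
            if lo > hi:  # degenerate sliver between adjacent boundaries
                lo = hi = mn
            basins.append((lo, hi))

    selected = []
    for (lo, hi), mn in zip(basins, minima):
        seg = scan.nvi_within[lo : hi + 1]
        best = seg.min()
        tied = np.flatnonzero(seg == best) + lo
        # ties: closest to the basin's Block-NVI minimum, then lowest index
        anchor = lo + int(np.argmin(curve[lo : hi + 1]))
        selected.append(int(tied[np.argmin(np.abs(tied - anchor))]))

    if max_basins is not None and len(basins) > max_basins:
        depth = [curve[lo : hi + 1].min() for lo, hi in basins]
        keep = sorted(np.argsort(depth)[:max_basins])
        basins = [basins[i] for i in keep]
        selected = [selected[i] for i in keep]

    return ScaleSelection(
        block_nvi=curve, basins=basins, selected=selected, kernel_size=kernel
    )
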