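"""Marker-controlled watershed by Meyer's flooding algorithm.

One watershed implementation serves both label synthesis (expert dots as
markers) and the classical baseline (h-dome regional maxima as markers).
Flooding is fully deterministic: pixels are resolved in ascending order of
(relief value, insertion order), with marker pixels seeded in raster order.

A pixel is resolved against the labels of its already-resolved neighbors:

* exactly one distinct basin label -> the pixel joins that basin;
* two or more distinct basin labels -> the pixel becomes a watershed-line
  pixel (recorded in the line mask; its stored label is the smallest
  adjacent basin so that the label raster still partitions the frame);
* none (all resolved neighbors are line pixels) -> the pixel takes the
  smallest stored label among those line neighbors.

Hence distinct basins are never adjacent: the one-pixel-wide line always
separates them, and the basin count equals the marker count.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["watershed"]


def watershed(relief: np.ndarray, markers: np.ndarray, connectivity: int = 8):
    """Flood ``relief`` from ``markers``.

    Parameters
    ----------
    relief : 2-D float array; low values are flooded first.
    markers : 2-D integer array, 0 = unmarked, >0 = basin seed label.
    connectivity : 4 or 8, the neighborhood used for flooding.

    Returns
    -------
    labels : 2-D int32 array, a full partition of the frame (every pixel
        carries a basin label > 0 whenever at least one marker exists).
    line : 2-D bool array, True on watershed-line pixels.
    """
    relief = np.asarray(relief, dtype=np.float64)
    markers = np.asarray(markers)
    if relief.shape != markers.shape:
        raise ValueError("relief and markers must share dimensions")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    h, w = relief.shape
    labels = markers.astype(np.int32).ravel().copy()
    line = np.zeros(h * w, dtype=bool)
    # 0 = far, 1 = queued, 2 = resolved
    status = np.where(labels > 0, 2, 0).astype(np.int8)
    rel = relief.ravel()

    if connectivity == 4:
        offs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    else:
        offs = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

    def neighbors(p):
        r, c = divmod(p, w)
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr * w + cc

    heap: list = []
    counter = 0
    for p in np.flatnonzero(status == 2):
        for q in neighbors(p):
            if status[q] == 0:
                heapq.heappush(heap, (rel[q], counter, q))
                counter += 1
                status[q] = 1

    while heap:
        _, _, p = heapq.heappop(heap)
        basin_labels = set()
        line_labels = set()
        for q in neighbors(p):
            if status[q] == 2:
                if line[q]:
                    line_labels.add(int(labels[q]))
                else:
                    basin_labels.add(int(labels[q]))
        if len(basin_labels) == 1:
            labels[p] = basin_labels.pop()
        elif not basin_labels:
            labels[p] = min(line_labels)
        else:
            line[p] = True
            labels[p] = min(basin_labels)
        status[p] = 2
        for q in neighbors(p):
            if status[q] == 0:
                heapq.heappush(heap, (rel[q], counter, q))
                counter += 1
                status[q] = 1

    return labels.reshape(h, w), line.reshape(h, w)
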