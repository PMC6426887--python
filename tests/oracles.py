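"""Independent brute-force oracles for morphology, watershed, and matching.

Everything here is written from the mathematical definitions (explicit
loops over structuring-element offsets, iterative geodesic dilation,
exhaustive assignment enumeration) so the implementations under test are
checked against code that shares none of their machinery.
"""

from __future__ import annotations

import numpy as np


def _pad_reflect(img: np.ndarray, r: int) -> np.ndarray:
    # matches scipy.ndimage mode="reflect" (edge value repeated)
    return np.pad(img, r, mode="symmetric")


def bf_erosion(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    r = footprint.shape[0] // 2
    p = _pad_reflect(img, r)
    out = np.empty_like(img, dtype=float)
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if footprint[dy + r, dx + r]]
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            out[y, x] = min(p[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def bf_dilation(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    # grayscale dilation with a symmetric footprint
    r = footprint.shape[0] // 2
    p = _pad_reflect(img, r)
    out = np.empty_like(img, dtype=float)
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if footprint[dy + r, dx + r]]
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            out[y, x] = max(p[y + r + dy, x + r + dx] for dy, dx in offs)
    return out


def bf_opening(img, footprint):
    return bf_dilation(bf_erosion(img, footprint), footprint)


def bf_closing(img, footprint):
    return bf_erosion(bf_dilation(img, footprint), footprint)


def bf_white_tophat(img, footprint):
    return img - bf_opening(img, footprint)


def bf_asf(img, max_radius, footprint_of):
    out = img.astype(float)
    for r in range(1, max_radius + 1):
        fp = footprint_of(r)
        out = bf_closing(bf_opening(out, fp), fp)
    return out


def bf_reconstruction_by_dilation(marker: np.ndarray, mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Iterative geodesic dilation until stability."""
    rec = np.minimum(marker.astype(float), mask)
    while True:
        grown = np.minimum(bf_dilation_nopad(rec, footprint), mask)
        if np.array_equal(grown, rec):
            return rec
        rec = grown


def bf_dilation_nopad(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Dilation ignoring out-of-frame positions (for geodesic reconstruction)."""
    r = footprint.shape[0] // 2
    h, w = img.shape
    out = np.full_like(img, -np.inf, dtype=float)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if not footprint[dy + r, dx + r]:
                continue
            ys = slice(max(0, dy), min(h, h + dy))
            xs = slice(max(0, dx), min(w, w + dx))
            ys_src = slice(max(0, -dy), min(h, h - dy))
            xs_src = slice(max(0, -dx), min(w, w - dx))
            out[ys_src, xs_src] = np.maximum(out[ys_src, xs_src], img[ys, xs])
    return out


def bf_hdome(img: np.ndarray, h: float, footprint: np.ndarray) -> np.ndarray:
    rec = bf_reconstruction_by_dilation(np.clip(img - h, 0.0, None), img, footprint)
    return img - rec


def bf_regional_maxima(img: np.ndarray) -> np.ndarray:
    """8-connected plateaus strictly greater than every outside neighbor.

    The whole-image plateau (no outside neighbors) is not a maximum.
    """
    h, w = img.shape
    visited = np.zeros((h, w), dtype=bool)
    out = np.zeros((h, w), dtype=bool)
    for sy in range(h):
        for sx in range(w):
            if visited[sy, sx]:
                continue
            v = img[sy, sx]
            stack = [(sy, sx)]
            comp = []
            visited[sy, sx] = True
            is_max = True
            has_outside = False
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dy == 0 and dx == 0:
                            continue
                        yy, xx = y + dy, x + dx
                        if not (0 <= yy < h and 0 <= xx < w):
                            continue
                        if img[yy, xx] == v:
                            if not visited[yy, xx]:
                                visited[yy, xx] = True
                                stack.append((yy, xx))
                        else:
                            has_outside = True
                            if img[yy, xx] > v:
                                is_max = False
            if is_max and has_outside:
                for y, x in comp:
                    out[y, x] = True
    return out


def bf_watershed(relief: np.ndarray, markers: np.ndarray, connectivity: int = 8):
    """Naive Meyer flooding: the frontier is rescanned for its minimum
    (value, insertion order) at every step instead of using a heap."""
    h, w = relief.shape
    labels = markers.astype(int).copy()
    line = np.zeros((h, w), dtype=bool)
    resolved = labels > 0
    offs = (
        [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if connectivity == 4
        else [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    )

    def neighbors(y, x):
        for dy, dx in offs:
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                yield yy, xx

    frontier = []  # (value, insertion_counter, y, x)
    queued = np.zeros((h, w), dtype=bool)
    counter = 0
    for y in range(h):
        for x in range(w):
            if resolved[y, x]:
                for yy, xx in neighbors(y, x):
                    if not resolved[yy, xx] and not queued[yy, xx]:
                        frontier.append((relief[yy, xx], counter, yy, xx))
                        counter += 1
                        queued[yy, xx] = True
    while frontier:
        i_best = min(range(len(frontier)), key=lambda i: frontier[i][:2])
        _, _, y, x = frontier.pop(i_best)
        basin = set()
        shadow = set()
        for yy, xx in neighbors(y, x):
            if resolved[yy, xx]:
                (shadow if line[yy, xx] else basin).add(labels[yy, xx])
        if len(basin) == 1:
            labels[y, x] = basin.pop()
        elif not basin:
            labels[y, x] = min(shadow)
        else:
            line[y, x] = True
            labels[y, x] = min(basin)
        resolved[y, x] = True
        for yy, xx in neighbors(y, x):
            if not resolved[yy, xx] and not queued[yy, xx]:
                frontier.append((relief[yy, xx], counter, yy, xx))
                counter += 1
                queued[yy, xx] = True
    return labels, line


def bf_max_matching(pred: np.ndarray, truth: np.ndarray, tol: float) -> int:
    """Exhaustive maximum-cardinality one-to-one matching within tolerance."""
    adj = []
    for p in pred:
        d = np.sqrt(((truth - p) ** 2).sum(axis=1)) if len(truth) else np.empty(0)
        adj.append(set(np.flatnonzero(d <= tol).tolist()))
    best = 0

    def rec(i, used):
        nonlocal best
        if i == len(adj):
            best = max(best, len(used))
            return
        if len(used) + (len(adj) - i) <= best:
            return
        for t in adj[i] - used:
            rec(i + 1, used | {t})
        rec(i + 1, used)

    rec(0, set())
    return best
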