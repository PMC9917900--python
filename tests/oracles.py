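"""Independent reference implementations used only by the tests.

These deliberately avoid the package's algorithms: candidate peaks are
found by a direct scan of the definition, and distance pruning is done by
exhaustive enumeration of all candidate subsets, selecting the subset
that is lexicographically greatest in tallest-first priority order —
no greedy shortcut.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_candidates(v) -> list[int]:
    """Interior strict local maxima; a plateau counts once, at its first
    index; runs touching either end are excluded."""
    v = list(v)
    n = len(v)
    out = []
    for i in range(1, n - 1):
        if i > 0 and v[i] == v[i - 1]:
            continue  # not the first index of its run
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j == n - 1:
            continue  # run touches the right end
        if v[i - 1] < v[i] and v[j + 1] < v[i]:
            out.append(i)
    return out


def oracle_prominence(v, idx: int) -> float:
    """Height above the higher of the two minima flanking the peak up to
    its nearest strictly higher neighbors (or the trace ends)."""
    v = list(v)
    h = v[idx]
    left = [x for x in _walk(v, idx, -1, h)]
    right = [x for x in _walk(v, idx, +1, h)]
    left_min = min(left) if left else h
    right_min = min(right) if right else h
    return h - max(left_min, right_min)


def _walk(v, idx, step, h):
    i = idx + step
    while 0 <= i < len(v) and v[i] <= h:
        yield v[i]
        i += step


def oracle_find_peaks(
    v,
    min_height: float = 0.0,
    d_frames: float = 1.0,
    min_prominence: float | None = None,
) -> list[int]:
    """Exhaustive-search peak selection (distance given in frames)."""
    v = list(v)
    cands = [
        c
        for c in oracle_candidates(v)
        if v[c] >= min_height
        and (min_prominence is None or oracle_prominence(v, c) >= min_prominence)
    ]
    priority = sorted(cands, key=lambda c: (-v[c], c))
    best_bits, best_subset = -1, ()
    for r in range(len(cands) + 1):
        for subset in itertools.combinations(cands, r):
            if any(
                abs(a - b) < d_frames - 1e-9
                for a, b in itertools.combinations(subset, 2)
            ):
                continue
            bits = sum(1 << (len(priority) - 1 - p)
                       for p, c in enumerate(priority) if c in subset)
            if bits > best_bits:
                best_bits, best_subset = bits, subset
    return sorted(best_subset)


def oracle_pixel_quantile(frames: np.ndarray, q: float) -> np.ndarray:
    """Per-pixel temporal quantile via an explicit per-pixel loop."""
    t, h, w = frames.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = np.quantile(frames[:, r, c], q)
    return out
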