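"""Independent brute-force oracles used to validate the segmentation chain.

These deliberately avoid the library routines the implementation uses:
hysteresis is a breadth-first flood fill seeded at pixels above the high
threshold, and the size filter is a hand-rolled component labelling pass.
"""

from collections import deque

import numpy as np

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def bfs_hysteresis(image: np.ndarray, low: float, high: float) -> np.ndarray:
    """Flood fill from pixels > high through 8-neighbours with value > low."""
    h, w = image.shape
    out = np.zeros((h, w), dtype=bool)
    queue = deque((y, x) for y in range(h) for x in range(w) if image[y, x] > high)
    for y, x in queue:
        out[y, x] = True
    while queue:
        y, x = queue.popleft()
        for dy, dx in _NEIGHBOURS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not out[ny, nx] and image[ny, nx] > low:
                out[ny, nx] = True
                queue.append((ny, nx))
    return out


def label_components_8(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components of a boolean mask, as pixel lists."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                comp = []
                queue = deque([(y, x)])
                seen[y, x] = True
                while queue:
                    cy, cx = queue.popleft()
                    comp.append((cy, cx))
                    for dy, dx in _NEIGHBOURS:
                        ny, nx = cy + dy, cx + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and mask[ny, nx] and not seen[ny, nx]
                        ):
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                comps.append(comp)
    return comps


def filter_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop components with fewer than min_area pixels."""
    out = np.zeros_like(mask, dtype=bool)
    for comp in label_components_8(mask):
        if len(comp) >= min_area:
            for y, x in comp:
                out[y, x] = True
    return out
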