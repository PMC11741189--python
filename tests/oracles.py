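"""Independent brute-force oracles used to validate the image primitives.

These deliberately avoid scipy/scikit-image morphology and labeling so they
stay independent of the implementation paths they check.
"""

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[int]:
    """Connected-component areas by explicit BFS flood fill.

    Returns the sorted list of component areas (pixel counts).
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    areas = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            area = 0
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                area += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        queue.append((rr, cc))
            areas.append(area)
    return sorted(areas)


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def brute_force_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with an exact disk: min filter then max filter.

    Border handling matches nearest-edge replication implicitly by clipping
    the footprint to the image (same as scipy's 'nearest' would not be --
    here we simply restrict the footprint to in-bounds pixels, which is the
    natural definition on a finite grid).
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    offsets = _disk_offsets(radius)
    eroded = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = [
                img[r + dr, c + dc]
                for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            eroded[r, c] = min(vals)
    opened = np.empty_like(img)
    for r in range(h):
        for c in range(w):
            vals = [
                eroded[r + dr, c + dc]
                for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w
            ]
            opened[r, c] = max(vals)
    return opened
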