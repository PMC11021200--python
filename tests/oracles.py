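"""Independent brute-force oracles used to check the package's fast paths.

These deliberately share no code with the implementation: flood fill is
breadth-first over an explicit queue, nearest neighbors are an O(n*m)
double loop.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighborhood_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order != 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labeling; labels follow raster discovery order."""
    mask = np.asarray(mask).astype(bool)
    offs = neighborhood_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    nz, ny, nx = mask.shape
    next_label = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or labels[z, y, x]:
                    continue
                next_label += 1
                queue = deque([(z, y, x)])
                labels[z, y, x] = next_label
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in offs:
                        wz, wy, wx = cz + dz, cy + dy, cx + dx
                        if 0 <= wz < nz and 0 <= wy < ny and 0 <= wx < nx:
                            if mask[wz, wy, wx] and not labels[wz, wy, wx]:
                                labels[wz, wy, wx] = next_label
                                queue.append((wz, wy, wx))
    return labels


def brute_force_nn(src_pts, src_ids, tgt_pts, tgt_ids, exclude_same_id=False):
    """All-pairs nearest neighbor with lowest-id tie-break.

    Returns (nearest_ids, distances); a source with no eligible target
    gets id -1 and distance NaN.
    """
    src_pts = np.asarray(src_pts, float)
    tgt_pts = np.asarray(tgt_pts, float)
    out_ids = []
    out_d = []
    for i in range(len(src_pts)):
        best_d, best_id = None, -1
        for j in range(len(tgt_pts)):
            if exclude_same_id and tgt_ids[j] == src_ids[i]:
                continue
            d = 0.0
            for k in range(3):
                d += (src_pts[i, k] - tgt_pts[j, k]) ** 2
            d = d**0.5
            if best_d is None or d < best_d or (d == best_d and tgt_ids[j] < best_id):
                best_d, best_id = d, int(tgt_ids[j])
        out_ids.append(best_id)
        out_d.append(np.nan if best_d is None else best_d)
    return np.array(out_ids), np.array(out_d)
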