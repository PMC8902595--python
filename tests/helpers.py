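"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: connected
components by breadth-first flood fill over explicit neighbour offsets,
sphere offsets by direct enumeration.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan == 1:
                    offs.append((dx, dy, dz))
                elif connectivity == 18 and manhattan <= 2:
                    offs.append((dx, dy, dz))
                elif connectivity == 26:
                    offs.append((dx, dy, dz))
    return offs


def flood_fill_clusters(binary: np.ndarray, connectivity: int,
                        extent: int) -> set[frozenset[int]]:
    """Connected components >= extent as frozensets of linear indices."""
    binary = np.asarray(binary, dtype=bool)
    shape = binary.shape
    offs = neighbour_offsets(connectivity)
    visited = np.zeros(shape, dtype=bool)
    out: set[frozenset[int]] = set()
    for start in map(tuple, np.argwhere(binary)):
        if visited[start]:
            continue
        visited[start] = True
        component = [start]
        queue = deque([start])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offs:
                nx, ny, nz = x + dx, y + dy, z + dz
                if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                        and 0 <= nz < shape[2] and binary[nx, ny, nz]
                        and not visited[nx, ny, nz]):
                    visited[nx, ny, nz] = True
                    component.append((nx, ny, nz))
                    queue.append((nx, ny, nz))
        if len(component) >= extent:
            out.add(frozenset(np.ravel_multi_index(np.array(component).T, shape).tolist()))
    return out


def clusterset_as_sets(clusters, shape) -> set[frozenset[int]]:
    return {frozenset(np.ravel_multi_index(c.voxels.T, shape).tolist())
            for c in clusters.clusters}


def brute_force_sphere_offsets(radius: float) -> set[tuple[int, int, int]]:
    r = int(np.ceil(radius))
    return {(dx, dy, dz)
            for dx in range(-r, r + 1)
            for dy in range(-r, r + 1)
            for dz in range(-r, r + 1)
            if dx * dx + dy * dy + dz * dz <= radius * radius + 1e-9}


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form pooled-variance two-sample t (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
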