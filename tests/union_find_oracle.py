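"""Brute-force union-find labelling of 26-connected components (test oracle)."""

import numpy as np

_NEIGHBORS = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) < (0, 0, 0)]  # backward half of the 26-neighborhood


def label_26_connected(binary: np.ndarray) -> np.ndarray:
    """Scan in C order, union each foreground voxel with its backward neighbors,
    then assign labels by first-voxel discovery order."""
    shape = binary.shape
    parent = {}

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    fg = np.argwhere(binary)
    for x, y, z in fg:
        idx = (int(x), int(y), int(z))
        parent[idx] = idx
        for dx, dy, dz in _NEIGHBORS:
            nb = (idx[0] + dx, idx[1] + dy, idx[2] + dz)
            if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2] and nb in parent):
                union(idx, nb)

    labels = np.zeros(shape, dtype=np.int32)
    next_label = 1
    root_to_label = {}
    for x, y, z in fg:  # argwhere returns C order: discovery order is lexicographic
        root = find((int(x), int(y), int(z)))
        if root not in root_to_label:
            root_to_label[root] = next_label
            next_label += 1
        labels[x, y, z] = root_to_label[root]
    return labels
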