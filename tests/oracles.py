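"""Slow, obviously-correct reference implementations used only in tests.

These deliberately share no code with the package: connected components are
found with an explicit flood fill over a Python set, adjacency by scanning
every neighbour offset of every voxel.
"""

from itertools import product

import numpy as np

NEIGHBOURS = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, o)) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def flood_components(mask: np.ndarray, connectivity: int = 26):
    """List of voxel-index sets, one per connected component of a 3D mask."""
    offsets = NEIGHBOURS[connectivity]
    remaining = set(map(tuple, np.argwhere(mask)))
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for o in offsets:
                nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def touches(component: set, other_mask: np.ndarray, connectivity: int = 26) -> bool:
    """Does any voxel of the component neighbour a voxel of other_mask?"""
    shape = other_mask.shape
    for v in component:
        for o in NEIGHBOURS[connectivity]:
            nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if all(0 <= nb[i] < shape[i] for i in range(3)) and other_mask[nb]:
                return True
    return False


def surviving_cysts(pred: np.ndarray, min_voxels: int, connectivity: int = 26):
    """Cyst components that pass contact-with-pancreas and minimum size."""
    pancreas = pred == 1
    keep = []
    for comp in flood_components(pred == 2, connectivity):
        if len(comp) >= min_voxels and touches(comp, pancreas, connectivity):
            keep.append(comp)
    return keep
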