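"""Independent oracles used by the test suite.

Everything here is deliberately computed by a different route than the
package code: topology via Euler characteristic of the cubical complex,
Yen's criterion by direct per-cut evaluation, Mann–Whitney by full
enumeration with pair counting.
"""

from itertools import combinations, product
from math import log

import numpy as np
from scipy import ndimage

_CUBE27 = np.ones((3, 3, 3), dtype=bool)
_OFFS26 = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


def euler_characteristic(mask: np.ndarray) -> int:
    """χ of the closed cubical complex of the foreground voxels.

    Cells of each dimension are counted as present when any incident voxel
    is foreground; χ = V − E + F − C.
    """
    P = np.pad(mask.astype(bool), 1)
    n_cubes = int(mask.sum())
    n_faces = 0
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(0, -1)
        sl1[ax] = slice(1, None)
        n_faces += int((P[tuple(sl0)] | P[tuple(sl1)]).sum())
    n_edges = 0
    for ax in range(3):
        other = [a for a in range(3) if a != ax]
        acc = None
        for s0, s1 in product((slice(0, -1), slice(1, None)), repeat=2):
            sl = [slice(None)] * 3
            sl[other[0]] = s0
            sl[other[1]] = s1
            piece = P[tuple(sl)]
            acc = piece if acc is None else (acc | piece)
        n_edges += int(acc.sum())
    acc = None
    for s0, s1, s2 in product((slice(0, -1), slice(1, None)), repeat=3):
        piece = P[s0, s1, s2]
        acc = piece if acc is None else (acc | piece)
    n_vertices = int(acc.sum())
    return n_vertices - n_edges + n_faces - n_cubes


def betti_numbers(mask: np.ndarray) -> tuple[int, int, int]:
    """(b0, b1, b2): components (26-conn), independent loops, cavities (6-conn)."""
    m = mask.astype(bool)
    b0 = int(ndimage.label(m, structure=_CUBE27)[1])
    bg_labels, n_bg = ndimage.label(~m, structure=ndimage.generate_binary_structure(3, 1))
    border = set()
    for ax in range(3):
        for idx in (0, -1):
            sl = [slice(None)] * 3
            sl[ax] = idx
            border.update(np.unique(bg_labels[tuple(sl)]))
    border.discard(0)
    b2 = n_bg - len(border)
    b1 = b0 + b2 - euler_characteristic(m)
    return b0, int(b1), b2


def graph_cycle_rank(mask: np.ndarray) -> int:
    """Cycle rank (edges − vertices + components) of the 26-adjacency graph."""
    coords = [tuple(c) for c in np.argwhere(mask)]
    present = set(coords)
    n_edges = 0
    for z, y, x in coords:
        for dz, dy, dx in _OFFS26:
            if (z + dz, y + dy, x + dx) in present:
                n_edges += 1
    n_edges //= 2
    n_comp = int(ndimage.label(mask, structure=_CUBE27)[1]) if coords else 0
    return n_edges - len(coords) + n_comp


def yen_best_cut_bruteforce(hist) -> int:
    """Index t of the cut (foreground = bins > t) maximizing Yen's criterion,
    evaluated cut by cut from the definition; ties broken toward lowest t."""
    hist = np.asarray(hist, dtype=float)
    p = hist / hist.sum()
    best_t, best_val = None, -np.inf
    for t in range(len(p) - 1):
        p1 = float(p[: t + 1].sum())
        p2 = 1.0 - p1
        s1 = float((p[: t + 1] ** 2).sum())
        s2 = float((p[t + 1 :] ** 2).sum())
        if p1 <= 0 or p2 <= 0 or s1 <= 0 or s2 <= 0:
            continue
        val = -log(s1 * s2) + 2.0 * log(p1 * p2)
        if val > best_val:
            best_t, best_val = t, val
    return best_t


def _u_stat(values_a, values_b) -> float:
    """U of group a by direct pair counting (ties count one half)."""
    u = 0.0
    for a in values_a:
        for b in values_b:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mann_whitney_p_bruteforce(samples_a, samples_b) -> float:
    """Two-sided exact p by enumerating every group-A labeling of the pool."""
    pooled = list(samples_a) + list(samples_b)
    n_a = len(samples_a)
    u_obs = _u_stat(samples_a, samples_b)
    n_le = n_ge = n_total = 0
    indices = range(len(pooled))
    for combo in combinations(indices, n_a):
        in_a = set(combo)
        group_a = [pooled[i] for i in combo]
        group_b = [pooled[i] for i in indices if i not in in_a]
        u = _u_stat(group_a, group_b)
        n_total += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / n_total)
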