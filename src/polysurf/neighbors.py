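"""Periodic geometry primitives: slab-style boundary conditions.

All systems in this package are periodic in x and y (the mineral surface
plane) and open in z.  Distances therefore use the minimum-image convention
in-plane only.  Two search paths are provided: a vectorised brute-force
O(N*M) scan used for small systems and as the reference everywhere, and a
KD-tree path that tiles one point set over the 3x3 in-plane images for
larger systems.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

# below this many pairs the brute-force path is used directly
_BRUTE_FORCE_LIMIT = 300


def minimum_image_displacement(
    ri: np.ndarray, rj: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Displacement ``rj - ri`` wrapped in x and y only.

    Broadcasts: ``ri`` may be (3,) or (N, 3), ``rj`` (3,) or (M, 3) as long
    as numpy broadcasting applies.
    """
    d = np.asarray(rj, dtype=float) - np.asarray(ri, dtype=float)
    box = np.asarray(box, dtype=float)
    d = d.copy()
    for ax in (0, 1):
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def distance_matrix(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs distances between point sets ``a`` (N,3) and ``b`` (M,3)."""
    d = minimum_image_displacement(a[:, None, :], b[None, :, :], box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap x and y into [0, L); z is left open."""
    out = np.array(positions, dtype=float, copy=True)
    for ax in (0, 1):
        out[..., ax] = np.mod(out[..., ax], box[ax])
    return out


def _tiled_tree(points: np.ndarray, box: np.ndarray) -> tuple[cKDTree, np.ndarray]:
    """KD-tree over the 3x3 in-plane periodic images of ``points``.

    Returns the tree and the index map from tiled rows back to the
    original point indices.
    """
    n = len(points)
    shifts = [
        np.array([ix * box[0], iy * box[1], 0.0])
        for ix in (-1, 0, 1)
        for iy in (-1, 0, 1)
    ]
    tiled = np.concatenate([points + s for s in shifts])
    index = np.tile(np.arange(n), len(shifts))
    return cKDTree(tiled), index


def pairs_within(
    a: np.ndarray,
    b: np.ndarray,
    cutoff: float,
    box: np.ndarray,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices (ia, ib) and distances of cross pairs closer than ``cutoff``.

    ``strict`` selects ``<`` (the package-wide boundary convention) versus
    ``<=``.  Pairs are unique per (ia, ib); self-pairs are not excluded, so
    callers comparing a set against itself must filter ``ia == ib`` if
    needed.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        empty = np.empty(0, dtype=int)
        return empty, empty.copy(), np.empty(0, dtype=float)
    if len(a) * len(b) <= _BRUTE_FORCE_LIMIT**2:
        dm = distance_matrix(a, b, box)
        mask = dm < cutoff if strict else dm <= cutoff
        ia, ib = np.nonzero(mask)
        return ia, ib, dm[ia, ib]
    tree, index = _tiled_tree(b, box)
    qa = wrap_positions(a, box)
    ia_list, ib_list, d_list = [], [], []
    hits = tree.query_ball_point(qa, cutoff)
    for i, hit in enumerate(hits):
        if not hit:
            continue
        hit = np.asarray(hit)
        dj = tree.data[hit] - qa[i]
        dist = np.sqrt(np.einsum("ij,ij->i", dj, dj))
        keep = dist < cutoff if strict else dist <= cutoff
        bj = index[hit[keep]]
        # a tiled query can hit the same source atom through two images;
        # keep the closest occurrence of each
        order = np.argsort(dist[keep])
        seen: dict[int, float] = {}
        for o in order:
            j = int(bj[o])
            if j not in seen:
                seen[j] = float(dist[keep][o])
        for j, dd in seen.items():
            ia_list.append(i)
            ib_list.append(j)
            d_list.append(dd)
    return (
        np.asarray(ia_list, dtype=int),
        np.asarray(ib_list, dtype=int),
        np.asarray(d_list, dtype=float),
    )


def min_cross_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum distance between two point sets under in-plane images."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("min_cross_distance: empty point set")
    if len(a) * len(b) <= _BRUTE_FORCE_LIMIT**2:
        return float(distance_matrix(a, b, box).min())
    tree, _ = _tiled_tree(b, box)
    d, _ = tree.query(wrap_positions(a, box), k=1)
    return float(np.min(d))
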