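"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own closed-form or heuristic
code paths: rotation space is searched on a refined Euler-angle grid,
and global alignment scores are enumerated recursively.
"""

import numpy as np


def _euler_rotations(az, ay, az2):
    """Batch of z-y-z Euler rotations for all angle combinations."""
    a, b, c = np.meshgrid(az, ay, az2, indexing="ij")
    a, b, c = a.ravel(), b.ravel(), c.ravel()
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rot = np.empty((len(a), 3, 3))
    rot[:, 0, 0] = ca * cb * cc - sa * sc
    rot[:, 0, 1] = -ca * cb * sc - sa * cc
    rot[:, 0, 2] = ca * sb
    rot[:, 1, 0] = sa * cb * cc + ca * sc
    rot[:, 1, 1] = -sa * cb * sc + ca * cc
    rot[:, 1, 2] = sa * sb
    rot[:, 2, 0] = -sb * cc
    rot[:, 2, 1] = sb * sc
    rot[:, 2, 2] = cb
    return rot


def grid_search_rmsd(coords_a, coords_b, final_step_deg=0.05):
    """Minimum superposition RMSD by hierarchically refined grid search
    over rotation space (optimal translation is centroid matching and is
    applied in closed form for every rotation)."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def batch_rmsd(rots):
        moved = np.einsum("kij,nj->kni", rots, bc)
        diff = moved - ac[None]
        return np.sqrt((diff ** 2).sum(axis=(1, 2)) / len(a))

    coarse = np.deg2rad(9.0)
    spans = (2 * np.pi, np.pi, 2 * np.pi)
    grids = [np.arange(0, spans[i] + coarse / 2, coarse) for i in range(3)]
    rots = _euler_rotations(*grids)
    r = batch_rmsd(rots)
    nb, nc = len(grids[1]), len(grids[2])

    def decompose(k):
        ia, rem = divmod(k, nb * nc)
        ib, ic = divmod(rem, nc)
        return np.array([grids[0][ia], grids[1][ib], grids[2][ic]])

    # refine the best few coarse basins independently (RMSD over rotation
    # space is multimodal for small point sets)
    order = np.argsort(r)[:12]
    best_rmsd = float(r[order[0]])
    for k in order:
        center = decompose(int(k))
        step = coarse
        while step > np.deg2rad(final_step_deg):
            step /= 3.0
            local = [center[i] + np.arange(-4, 5) * step for i in range(3)]
            rr = batch_rmsd(_euler_rotations(*local))
            kk = int(np.argmin(rr))
            ia, rem = divmod(kk, 81)
            ib, ic = divmod(rem, 9)
            center = np.array([local[0][ia], local[1][ib], local[2][ic]])
            best_rmsd = min(best_rmsd, float(rr[kk]))
    return best_rmsd


def brute_force_global_score(seq_a, seq_b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Optimal global alignment score by exhaustive recursion (tiny inputs)."""

    def rec(i, j):
        if i == len(seq_a):
            return gap * (len(seq_b) - j)
        if j == len(seq_b):
            return gap * (len(seq_a) - i)
        sub = match if seq_a[i] == seq_b[j] else mismatch
        return max(rec(i + 1, j + 1) + sub, rec(i + 1, j) + gap, rec(i, j + 1) + gap)

    return rec(0, 0)


def bipartition_sets(tree):
    """Brute-force unrooted split set via leaf-set enumeration per edge."""
    labels = set(tree.leaf_labels())
    ref = min(labels)
    out = set()

    def leafset(node):
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(leafset(c) for c in node.children))

    def walk(node):
        for c in node.children:
            below = leafset(c)
            if 2 <= len(below) <= len(labels) - 2:
                out.add(below if ref not in below else frozenset(labels - below))
            walk(c)

    walk(tree.root)
    return out
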