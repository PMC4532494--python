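"""Pairwise Calpha superposition and topological-equivalence detection.

Two domains are compared by an iterative superposition aligner:

1. *Seeding.*  Every pair of gapless 8-residue fragments (start
   positions on a stride-4 grid in both domains) is superposed by the
   Kabsch algorithm; the fragment transform that brings the largest
   number of residues within the distance cutoff is kept.
2. *Iteration.*  Under the current transform a score matrix
   ``S(i, j) = max(0, cutoff - d(i, j))`` is built over all residue
   pairs and a global, sequence-order-preserving dynamic program (linear
   gap penalty per gap position) selects an equivalence set: the aligned
   pairs whose Calpha distance is at most the cutoff.  The rigid
   transform is then re-fit on that set by Kabsch superposition.
3. *Convergence.*  Iteration stops when the equivalence set repeats
   itself; if it oscillates instead of converging, the iteration with
   the most equivalences (ties: lower RMSD) is returned.

The final report satisfies the topological-equivalence contract: every
reported residue pair is within the cutoff (default 3.0 A) under the
final transform, and the RMSD is computed over exactly those pairs.
Externally computed equivalences (e.g. from DALI-style tools) can be
imported from a two-column TSV instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from sdm_phylo.errors import DegenerateInputError, FormatError
from sdm_phylo.structure_io import DomainStructure

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3.0  # A, topological-equivalence distance
FRAGMENT_LENGTH = 8
FRAGMENT_STRIDE = 4
GAP_PENALTY = 0.5
MIN_SEED_PAIRS = 8


@dataclass
class StructuralAlignment:
    """Residue equivalences and optimal rigid transform for one domain pair."""

    id_a: str
    id_b: str
    pairs: list[tuple[int, int]]  # 0-based indices, strictly increasing in both
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector, A
    rmsd: float  # A, over `pairs`
    converged: bool
    n_iterations: int
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n_equivalent(self) -> int:
        return len(self.pairs)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the rigid transform (maps structure-b coordinates onto a)."""
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray):
    """Optimal proper rigid superposition of b onto a (paired point sets).

    Returns ``(rotation, translation, rmsd)`` minimizing the RMSD of
    ``coords_b @ rotation.T + translation`` against ``coords_a`` over
    all proper rotations; reflections are suppressed (det = +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DegenerateInputError("coordinate sets must be matching N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 paired points, got {n}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2:
        logger.warning("collinear point set: rotation about the line is arbitrary")
    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    e = np.diag([1.0, 1.0, d])
    rot = vt.T @ e @ u.T
    trans = ca - rot @ cb
    diff = ac - bc @ rot.T
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    if rmsd < 1e-10:  # numerically exact superposition (identical inputs)
        rmsd = 0.0
    return rot, trans, rmsd


def _batched_kabsch(frags_a: np.ndarray, frags_b: np.ndarray):
    """Kabsch for K fragment pairs at once: (K,L,3),(K,L,3) -> (K,3,3),(K,3)."""
    ca = frags_a.mean(axis=1)
    cb = frags_b.mean(axis=1)
    ac = frags_a - ca[:, None, :]
    bc = frags_b - cb[:, None, :]
    h = np.einsum("kli,klj->kij", bc, ac)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("kij,klj->kil", vt.transpose(0, 2, 1), u))
    e = np.zeros((len(h), 3, 3))
    e[:, 0, 0] = e[:, 1, 1] = 1.0
    e[:, 2, 2] = np.sign(det)
    rot = np.einsum("kij,kjl,kml->kim", vt.transpose(0, 2, 1), e, u)
    trans = ca - np.einsum("kij,kj->ki", rot, cb)
    return rot, trans


@njit(cache=True)
def _dp_traceback(score: np.ndarray, gap: float) -> np.ndarray:
    """Global order-preserving DP on a match-score matrix.

    Maximizes sum of matched scores minus `gap` per unmatched residue
    position.  Ties prefer the diagonal (match) move, then the gap that
    consumes a residue of the first structure.  Returns matched (i, j)
    pairs as an M x 2 array, strictly increasing in both columns.
    """
    n, m = score.shape
    best = np.empty((n + 1, m + 1), dtype=np.float64)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    best[0, 0] = 0.0
    for i in range(1, n + 1):
        best[i, 0] = -gap * i
        move[i, 0] = 1
    for j in range(1, m + 1):
        best[0, j] = -gap * j
        move[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = best[i - 1, j - 1] + score[i - 1, j - 1]
            up = best[i - 1, j] - gap
            left = best[i, j - 1] - gap
            if diag >= up and diag >= left:
                best[i, j] = diag
                move[i, j] = 0
            elif up >= left:
                best[i, j] = up
                move[i, j] = 1
            else:
                best[i, j] = left
                move[i, j] = 2
    out = np.empty((min(n, m), 2), dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            out[k, 0] = i - 1
            out[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return out[:k][::-1].copy()


@njit(cache=True)
def _score_seeds(rots: np.ndarray, transs: np.ndarray, buckets: np.ndarray,
                 n_buckets: int, a: np.ndarray, b: np.ndarray,
                 cutoff2: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-register best seed: the transform with the most a-residues
    having a transformed b-residue within the cutoff.

    Candidates are grouped by their sequence-offset bucket (alignment
    register) because a pseudo-symmetric fold admits misregistered
    superpositions that score well geometrically but collapse under the
    order-preserving DP.  Within each bucket candidates are visited in
    order, so equal counts keep the lexicographically lowest seed; a
    count upper bound prunes candidates that cannot beat their bucket's
    leader.
    """
    n, m = a.shape[0], b.shape[0]
    # two slots per bucket: distinct nearby seeds can flow to different
    # fixed points of the iteration, so a runner-up is kept as well
    best_counts = np.full((n_buckets, 2), -1, dtype=np.int64)
    best_idx = np.full((n_buckets, 2), -1, dtype=np.int64)
    bt = np.empty((m, 3))
    for k in range(rots.shape[0]):
        bk = buckets[k]
        bound = best_counts[bk, 1]  # must beat the bucket's runner-up
        rot = rots[k]
        tr = transs[k]
        for j in range(m):
            for r in range(3):
                bt[j, r] = (rot[r, 0] * b[j, 0] + rot[r, 1] * b[j, 1]
                            + rot[r, 2] * b[j, 2] + tr[r])
        count = 0
        pruned = False
        for i in range(n):
            if count + (n - i) <= bound:
                pruned = True
                break
            ax, ay, az = a[i, 0], a[i, 1], a[i, 2]
            for j in range(m):
                dx = ax - bt[j, 0]
                dy = ay - bt[j, 1]
                dz = az - bt[j, 2]
                if dx * dx + dy * dy + dz * dz <= cutoff2:
                    count += 1
                    break
        if pruned:
            continue
        if count > best_counts[bk, 0]:
            best_counts[bk, 1] = best_counts[bk, 0]
            best_idx[bk, 1] = best_idx[bk, 0]
            best_counts[bk, 0] = count
            best_idx[bk, 0] = k
        elif count > best_counts[bk, 1]:
            best_counts[bk, 1] = count
            best_idx[bk, 1] = k
    return best_counts, best_idx


def _best_seeds(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float,
                frag_len: int, stride: int, n_seeds: int):
    """Top fragment-pair seed transforms across alignment registers.

    Fragment starts advance by `stride` in the first structure but by 1
    in the second: with both grids strided, only register offsets that
    are multiples of the stride are reachable, and an insertion or
    deletion near a terminus can leave the true register without any
    gapless seed fragment.  Returns up to `n_seeds`
    (rotation, translation, count) triples in decreasing
    within-cutoff count order.
    """
    starts_a = np.arange(0, len(coords_a) - frag_len + 1, stride)
    starts_b = np.arange(0, len(coords_b) - frag_len + 1, 1)
    idx = np.arange(frag_len)
    frags_a = coords_a[starts_a[:, None] + idx]  # (Ka, L, 3)
    frags_b = coords_b[starts_b[:, None] + idx]
    ka, kb = len(starts_a), len(starts_b)
    pa = np.repeat(np.arange(ka), kb)
    pb = np.tile(np.arange(kb), ka)
    rots, transs = _batched_kabsch(frags_a[pa], frags_b[pb])

    offsets = starts_a[pa] - starts_b[pb]
    bucket_width = max(frag_len, 1)
    buckets = (offsets - offsets.min()) // bucket_width
    counts, best_idx = _score_seeds(rots, transs, buckets.astype(np.int64),
                                    int(buckets.max()) + 1,
                                    coords_a, coords_b, cutoff * cutoff)
    counts, best_idx = counts.ravel(), best_idx.ravel()
    order = [k for k in np.argsort(-counts, kind="stable") if best_idx[k] >= 0]
    return [(rots[best_idx[k]], transs[best_idx[k]], int(counts[k]))
            for k in order[:n_seeds]]


def _empty_alignment(a: DomainStructure, b: DomainStructure, cutoff: float,
                     n_iterations: int = 0) -> StructuralAlignment:
    return StructuralAlignment(
        id_a=a.id, id_b=b.id, pairs=[], rotation=np.eye(3),
        translation=np.zeros(3), rmsd=0.0, converged=True,
        n_iterations=n_iterations, cutoff=cutoff,
    )


def _iterate_equivalences(ca_a: np.ndarray, ca_b: np.ndarray, rot, trans,
                          cutoff: float, max_iter: int, gap_penalty: float):
    """Superpose-DP-refit loop from one seed transform.

    Returns ``(pairs_arr, converged, iterations)``; pairs may be empty
    when the register collapses under the order-preserving DP.
    """
    cutoff2 = cutoff * cutoff
    seen: set[frozenset] = set()
    prev: frozenset | None = None
    best_state = None  # (n_pairs, -rmsd, pairs)
    converged = False
    iterations = 0
    pairs_arr = np.empty((0, 2), dtype=np.int64)
    for iterations in range(1, max_iter + 1):
        bt = ca_b @ rot.T + trans
        dist = cdist(ca_a, bt)
        score = np.maximum(0.0, cutoff - dist)
        aligned = _dp_traceback(score, gap_penalty)
        if len(aligned):
            d2 = ((ca_a[aligned[:, 0]] - bt[aligned[:, 1]]) ** 2).sum(axis=1)
            pairs_arr = aligned[d2 <= cutoff2]
        else:
            pairs_arr = aligned
        key = frozenset(map(tuple, pairs_arr.tolist()))
        if prev is not None and key == prev:
            converged = True
            break
        if len(pairs_arr) < 3:
            return pairs_arr, True, iterations
        sel_rot, sel_trans, sel_rmsd = kabsch_superpose(
            ca_a[pairs_arr[:, 0]], ca_b[pairs_arr[:, 1]])
        state = (len(pairs_arr), -sel_rmsd, pairs_arr)
        if best_state is None or state[:2] > best_state[:2]:
            best_state = state
        if key in seen:  # oscillation: revisited a non-adjacent state
            break
        seen.add(key)
        prev = key
        rot, trans = sel_rot, sel_trans

    if not converged and best_state is not None:
        pairs_arr = best_state[2]
    return pairs_arr, converged, iterations


def iterative_align(
    a: DomainStructure,
    b: DomainStructure,
    cutoff: float = DEFAULT_CUTOFF,
    max_iter: int = 50,
    gap_penalty: float = GAP_PENALTY,
    fragment_length: int = FRAGMENT_LENGTH,
    fragment_stride: int = FRAGMENT_STRIDE,
    n_seeds: int = 8,
) -> StructuralAlignment:
    """Align two domains; returns equivalences, transform and RMSD.

    The iteration is run from the best seed of each of the `n_seeds`
    highest-scoring alignment registers, and the final alignment with
    the most equivalences (ties: lower RMSD) is kept.
    """
    if a.length < fragment_length or b.length < fragment_length:
        raise DegenerateInputError(
            f"structures shorter than the seed fragment length {fragment_length}"
        )
    ca_a, ca_b = a.coords, b.coords
    seeds = _best_seeds(ca_a, ca_b, cutoff, fragment_length, fragment_stride,
                        n_seeds)
    if not seeds or seeds[0][2] < MIN_SEED_PAIRS:
        return _empty_alignment(a, b, cutoff)

    cutoff2 = cutoff * cutoff
    best = None  # (n_pairs, -rmsd, pairs, rot, trans, rmsd, converged, iters)
    for rot, trans, seed_count in seeds:
        if seed_count < MIN_SEED_PAIRS:
            continue
        pairs_arr, converged, iterations = _iterate_equivalences(
            ca_a, ca_b, rot, trans, cutoff, max_iter, gap_penalty)
        # enforce the equivalence contract: refit, drop pairs drifting past
        # the cutoff under the refit transform, repeat until stable
        while len(pairs_arr) >= 3:
            f_rot, f_trans, f_rmsd = kabsch_superpose(
                ca_a[pairs_arr[:, 0]], ca_b[pairs_arr[:, 1]])
            bt = ca_b @ f_rot.T + f_trans
            d2 = ((ca_a[pairs_arr[:, 0]] - bt[pairs_arr[:, 1]]) ** 2).sum(axis=1)
            keep = d2 <= cutoff2
            if keep.all():
                state = (len(pairs_arr), -f_rmsd, pairs_arr, f_rot, f_trans,
                         f_rmsd, converged, iterations)
                if best is None or state[:2] > best[:2]:
                    best = state
                break
            pairs_arr = pairs_arr[keep]

    if best is None:
        return _empty_alignment(a, b, cutoff)
    _, _, pairs_arr, rot, trans, rmsd, converged, iterations = best
    return StructuralAlignment(
        id_a=a.id, id_b=b.id,
        pairs=[(int(i), int(j)) for i, j in pairs_arr],
        rotation=rot, translation=trans, rmsd=rmsd,
        converged=converged, n_iterations=iterations, cutoff=cutoff,
    )


def import_alignment(path: str | Path, a: DomainStructure, b: DomainStructure,
                     cutoff: float = DEFAULT_CUTOFF) -> StructuralAlignment:
    """Load residue equivalences from a TSV (columns index_a, index_b).

    Indices are 0-based positions in the Calpha-filtered residue lists.
    The rigid transform and RMSD are recomputed by Kabsch superposition
    over the imported pairs; the file's own superposition (if any) is
    ignored.  Pairs must be strictly increasing in both columns.
    """
    path = Path(path)
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().replace(" ", "").startswith("index_a"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            try:
                i, j = int(fields[0]), int(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer index")
            if not (0 <= i < a.length and 0 <= j < b.length):
                raise FormatError(
                    f"{path}:{lineno}: index ({i}, {j}) out of range for lengths "
                    f"({a.length}, {b.length})"
                )
            if pairs and not (i > pairs[-1][0] and j > pairs[-1][1]):
                raise FormatError(f"{path}:{lineno}: crossing or non-increasing pair ({i}, {j})")
            pairs.append((i, j))
    if not pairs:
        raise FormatError(f"{path}: no equivalence pairs found")
    if len(pairs) < 3:
        raise DegenerateInputError(f"{path}: need >= 3 pairs to superpose")
    arr = np.array(pairs)
    rot, trans, rmsd = kabsch_superpose(a.coords[arr[:, 0]], b.coords[arr[:, 1]])
    return StructuralAlignment(
        id_a=a.id, id_b=b.id, pairs=pairs, rotation=rot, translation=trans,
        rmsd=rmsd, converged=True, n_iterations=0, cutoff=cutoff,
    )


def write_alignment_tsv(aln: StructuralAlignment, path: str | Path) -> None:
    """Write the equivalence table in the importable TSV format."""
    with open(path, "w") as fh:
        fh.write("index_a\tindex_b\n")
        for i, j in aln.pairs:
            fh.write(f"{i}\t{j}\n")
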