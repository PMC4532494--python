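"""Sequence-side analyses: pairwise identities and identity distances.

Percent identity is computed either over the residue pairs of a
structural alignment (the structure-guided convention) or from a global
Needleman-Wunsch alignment (match +1, mismatch -1, linear gap -2).  The
denominator is always the number of aligned non-gap positions, never the
full alignment length, so terminal gaps cannot deflate identity.
Identity distances (100 - percent identity) feed the neighbor-joining
sequence tree that the structure tree is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from sdm_phylo.align import StructuralAlignment
from sdm_phylo.errors import InputError
from sdm_phylo.sdm import DissimilarityMatrix
from sdm_phylo.structure_io import DomainStructure


@dataclass(frozen=True)
class IdentityRecord:
    id_a: str
    id_b: str
    n_identical: int
    n_aligned: int  # aligned non-gap pairs
    percent_identity: float  # [0, 100]
    source: str  # "structural" or "global-sequence"
    undefined: bool = False  # True when no positions were aligned


def identity_from_structural_alignment(
    aln: StructuralAlignment, a: DomainStructure, b: DomainStructure
) -> IdentityRecord:
    """Percent identity over the topologically equivalent residue pairs."""
    seq_a, seq_b = a.sequence, b.sequence
    n_aligned = aln.n_equivalent
    if n_aligned == 0:
        return IdentityRecord(aln.id_a, aln.id_b, 0, 0, 0.0, "structural", undefined=True)
    n_identical = sum(1 for i, j in aln.pairs if seq_a[i] == seq_b[j])
    return IdentityRecord(
        aln.id_a, aln.id_b, n_identical, n_aligned,
        100.0 * n_identical / n_aligned, "structural",
    )


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    id_a: str = "a",
    id_b: str = "b",
) -> tuple[tuple[str, str], IdentityRecord]:
    """Optimal global (Needleman-Wunsch) alignment under linear gap scoring.

    Returns the gapped sequence pair and the identity record over
    aligned non-gap positions.  Among co-optimal alignments the
    canonical traceback of Biopython's PairwiseAligner is reported; the
    score is unique regardless.
    """
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    alignment = aligner.align(seq_a, seq_b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    n_aligned = n_identical = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            n_aligned += 1
            if x == y:
                n_identical += 1
    pct = 100.0 * n_identical / n_aligned if n_aligned else 0.0
    record = IdentityRecord(id_a, id_b, n_identical, n_aligned, pct,
                            "global-sequence", undefined=n_aligned == 0)
    return (ga, gb), record


def nw_score(seq_a: str, seq_b: str, match: float = 1.0, mismatch: float = -1.0,
             gap: float = -2.0) -> float:
    """Optimal global alignment score only (unique, traceback-free)."""
    if not seq_a or not seq_b:
        raise InputError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return float(aligner.score(seq_a, seq_b))


def identity_histogram(records: list[IdentityRecord], bin_width: float = 10.0):
    """Bin percent identities into half-open decade bins.

    Bins are [0, 10), [10, 20), ..., [90, 100] (the last bin is closed).
    Returns a dict with bin edges, counts, fractions, and a function-like
    mapping `cumulative_below` from each right edge to the fraction of
    pairs strictly below it.
    """
    if not records:
        raise InputError("no identity records")
    values = np.array([r.percent_identity for r in records])
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    fractions = counts / counts.sum()
    cumulative = {float(edges[i + 1]): float((values < edges[i + 1]).mean())
                  for i in range(len(counts))}
    return {
        "edges": edges,
        "counts": counts,
        "fractions": fractions,
        "cumulative_below": cumulative,
    }


def identity_distance_matrix(records: list[IdentityRecord],
                             labels: list[str]) -> DissimilarityMatrix:
    """Distance matrix with d = 100 - percent identity (no correction)."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    for rec in records:
        if rec.id_a not in index or rec.id_b not in index:
            raise InputError(f"record ({rec.id_a}, {rec.id_b}) has unknown labels")
        i, j = index[rec.id_a], index[rec.id_b]
        values[i, j] = values[j, i] = 100.0 - rec.percent_identity
    return DissimilarityMatrix(labels, values)
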