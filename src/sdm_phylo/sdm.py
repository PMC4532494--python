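"""The structural dissimilarity metric (SDM) and all-pairs matrices.

For a pair of superposed domains with ``n`` topologically equivalent
residues and superposition quality ``RMSD`` (computed over those
residues only), the metric combines two fractions:

    PFTE = n / length of the smaller domain
    SRMS = 1 - RMSD / 3.0            (clamped to [0, 1])

and self-weights them,

    w1 = ((1 - PFTE) + (1 - SRMS)) / 2
    w2 = (PFTE + SRMS) / 2           (w1 + w2 = 1 identically)

    SDM = -100 * log10(w1 * PFTE + w2 * SRMS)

SDM is 0 exactly when PFTE = SRMS = 1 (structurally identical domains)
and grows as either fraction degrades; it is monotone non-increasing in
both arguments.  The logarithm argument is clamped below at EPS = 1e-4,
capping SDM at 400 for totally dissimilar pairs so that distance-based
tree methods always receive finite values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from sdm_phylo.align import StructuralAlignment
from sdm_phylo.errors import CompletenessError, ConsistencyError, FormatError, InputError
from sdm_phylo.structure_io import DomainStructure

RMSD_SCALE = 3.0  # A, matches the topological-equivalence cutoff
EPS = 1e-4  # floor of the SDM logarithm argument
SDM_CAP = -100.0 * math.log10(EPS)  # = 400.0


@dataclass(frozen=True)
class SDMRecord:
    """Per-pair dissimilarity summary."""

    id_a: str
    id_b: str
    n_equivalent: int
    rmsd: float
    pfte: float
    srms: float
    w1: float
    w2: float
    sdm: float


def compute_pfte(n_equivalent: int, len_a: int, len_b: int) -> float:
    """Fraction of topologically equivalent residues of the smaller domain."""
    if min(len_a, len_b) < 3:
        raise InputError(f"domain lengths must be >= 3, got ({len_a}, {len_b})")
    smaller = min(len_a, len_b)
    if n_equivalent > smaller:
        raise ConsistencyError(
            f"{n_equivalent} equivalences exceed the smaller length {smaller}"
        )
    return n_equivalent / smaller


def compute_srms(rmsd: float) -> float:
    """Scaled superposition quality 1 - RMSD/3.0, clamped to [0, 1]."""
    if rmsd < 0:
        raise InputError(f"negative RMSD: {rmsd}")
    return max(0.0, min(1.0, 1.0 - rmsd / RMSD_SCALE))


def compute_sdm(pfte: float, srms: float) -> tuple[float, float, float]:
    """Weights and SDM value for one pair; returns ``(w1, w2, sdm)``."""
    if not (0.0 <= pfte <= 1.0 and 0.0 <= srms <= 1.0):
        raise InputError(f"PFTE and SRMS must lie in [0, 1], got ({pfte}, {srms})")
    w1 = ((1.0 - pfte) + (1.0 - srms)) / 2.0
    w2 = (pfte + srms) / 2.0
    g = w1 * pfte + w2 * srms
    sdm = -100.0 * math.log10(max(g, EPS))
    return w1, w2, max(0.0, sdm)


def pair_record(aln: StructuralAlignment, a: DomainStructure, b: DomainStructure) -> SDMRecord:
    """Full SDM record for one aligned pair."""
    pfte = compute_pfte(aln.n_equivalent, a.length, b.length)
    srms = compute_srms(aln.rmsd) if aln.n_equivalent else 0.0
    w1, w2, sdm = compute_sdm(pfte, srms)
    return SDMRecord(
        id_a=aln.id_a, id_b=aln.id_b, n_equivalent=aln.n_equivalent,
        rmsd=aln.rmsd, pfte=pfte, srms=srms, w1=w1, w2=w2, sdm=sdm,
    )


class DissimilarityMatrix:
    """Symmetric labelled dissimilarity matrix with a zero diagonal."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise InputError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise InputError("duplicate labels")
        if not np.allclose(values, values.T, atol=1e-9):
            raise InputError("matrix is not symmetric (tolerance 1e-9)")
        if (values < 0).any():
            raise InputError("negative dissimilarities")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise InputError("nonzero diagonal")
        self.labels = list(labels)
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_phylip(self, path: str | Path) -> None:
        """Write as a square PHYLIP distance matrix (names padded to 10)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels):5d}\n")
            for label, row in zip(self.labels, self.values):
                name = label[:10].ljust(10)
                fh.write(name + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DissimilarityMatrix":
        with open(path) as fh:
            tokens = fh.read().split()
        if not tokens:
            raise FormatError(f"{path}: empty file")
        try:
            n = int(tokens[0])
        except ValueError:
            raise FormatError(f"{path}: first token must be the taxon count")
        expected = 1 + n * (n + 1)
        if len(tokens) != expected:
            raise FormatError(f"{path}: expected {expected} tokens for a square "
                              f"{n}-taxon matrix, found {len(tokens)}")
        labels, rows = [], []
        pos = 1
        for _ in range(n):
            labels.append(tokens[pos])
            rows.append([float(t) for t in tokens[pos + 1:pos + 1 + n]])
            pos += 1 + n
        return cls(labels, np.array(rows))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6f"
        )


def expected_pair_count(n: int) -> int:
    return n * (n - 1) // 2


def build_matrix(
    records: Iterable[SDMRecord],
    labels: list[str],
) -> tuple[DissimilarityMatrix, pd.DataFrame]:
    """Assemble the symmetric SDM matrix from per-pair records.

    Requires exactly one record per unordered label pair; raises
    :class:`CompletenessError` naming any absent pairs.  Also returns
    the per-pair table as a DataFrame (one row per unordered pair).
    """
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))
    seen: set[frozenset] = set()
    rows = []
    for rec in records:
        if rec.id_a not in index or rec.id_b not in index:
            raise InputError(f"record ({rec.id_a}, {rec.id_b}) has unknown labels")
        key = frozenset((rec.id_a, rec.id_b))
        if len(key) == 1:
            raise InputError(f"self-pair record for {rec.id_a}")
        if key in seen:
            raise InputError(f"duplicate record for pair ({rec.id_a}, {rec.id_b})")
        seen.add(key)
        i, j = index[rec.id_a], index[rec.id_b]
        values[i, j] = values[j, i] = rec.sdm
        rows.append(rec.__dict__)
    missing = [
        (labels[i], labels[j])
        for i in range(n) for j in range(i + 1, n)
        if frozenset((labels[i], labels[j])) not in seen
    ]
    if missing:
        raise CompletenessError(f"missing {len(missing)} pair(s): {missing[:10]}")
    table = pd.DataFrame(
        rows, columns=["id_a", "id_b", "n_equivalent", "rmsd", "pfte",
                       "srms", "w1", "w2", "sdm"],
    )
    return DissimilarityMatrix(labels, values), table
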