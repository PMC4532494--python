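"""End-to-end orchestration: ingest -> align all pairs -> SDM matrix ->
trees -> clusters -> structure-vs-sequence comparison.

The pipeline is deterministic given its configuration and inputs:
re-running with the same config over the same files reproduces the
matrix and Newick outputs byte for byte.  Pairwise alignments dominate
the runtime (n(n-1)/2 of them), so each result is cached on disk keyed
by the two structure files' content hashes and the aligner parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from sdm_phylo import align as _align
from sdm_phylo import sdm as _sdm
from sdm_phylo import seqphylo as _seq
from sdm_phylo import trees as _trees
from sdm_phylo.errors import InputError
from sdm_phylo.structure_io import DomainStructure, read_structure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    cutoff: float = _align.DEFAULT_CUTOFF
    fragment_length: int = _align.FRAGMENT_LENGTH
    fragment_stride: int = _align.FRAGMENT_STRIDE
    gap_penalty: float = _align.GAP_PENALTY
    max_iter: int = 50
    power: float = 2.0
    tree_methods: list[str] = field(default_factory=lambda: ["fm_clock", "nj"])
    cluster_k: Optional[int] = None
    cluster_height: Optional[float] = None
    seed: int = 0
    cache: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gap_penalty < 0 or self.max_iter < 1:
            raise InputError("cutoff must be > 0, gap_penalty >= 0, max_iter >= 1")
        bad = set(self.tree_methods) - {"fm_clock", "nj", "upgma"}
        if bad:
            raise InputError(f"unknown tree methods: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def read_manifest(path: str | Path) -> list[dict]:
    """Manifest TSV: columns id, path, chain, range (range empty or 'a:b')."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["id", "path", "chain"]:
            raise InputError(f"{path}: manifest must start with id/path/chain columns")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            fields += [""] * (4 - len(fields))
            rng = None
            if fields[3]:
                lo, hi = fields[3].split(":")
                rng = (int(lo), int(hi))
            rows.append({
                "id": fields[0],
                "path": path.parent / fields[1],
                "chain": fields[2] or "A",
                "range": rng,
            })
    if len(rows) < 3:
        raise InputError(f"{path}: manifest must list >= 3 domains")
    if len({r["id"] for r in rows}) != len(rows):
        raise InputError(f"{path}: duplicate domain ids")
    return rows


def _file_hash(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:16]


def _align_pair(a: DomainStructure, b: DomainStructure, config: RunConfig,
                cache_dir: Optional[Path], hash_a: str, hash_b: str):
    params = (f"{config.cutoff}:{config.fragment_length}:{config.fragment_stride}"
              f":{config.gap_penalty}:{config.max_iter}")
    key = hashlib.sha1(f"{hash_a}:{hash_b}:{params}".encode()).hexdigest()[:24]
    cache_file = cache_dir / f"{key}.json" if cache_dir is not None else None
    if cache_file is not None and cache_file.exists():
        data = json.loads(cache_file.read_text())
        return _align.StructuralAlignment(
            id_a=a.id, id_b=b.id, pairs=[tuple(p) for p in data["pairs"]],
            rotation=np.array(data["rotation"]), translation=np.array(data["translation"]),
            rmsd=data["rmsd"], converged=data["converged"],
            n_iterations=data["n_iterations"], cutoff=config.cutoff,
        )
    aln = _align.iterative_align(
        a, b, cutoff=config.cutoff, max_iter=config.max_iter,
        gap_penalty=config.gap_penalty, fragment_length=config.fragment_length,
        fragment_stride=config.fragment_stride,
    )
    if cache_file is not None:
        cache_file.write_text(json.dumps({
            "pairs": aln.pairs, "rotation": aln.rotation.tolist(),
            "translation": aln.translation.tolist(), "rmsd": aln.rmsd,
            "converged": aln.converged, "n_iterations": aln.n_iterations,
        }))
    return aln


def run_pipeline(config: RunConfig,
                 structures: Optional[dict[str, DomainStructure]] = None) -> dict:
    """Run the full workflow; returns the JSON-serializable run report.

    `structures` may be passed directly (e.g. from the simulator) to
    bypass file ingestion; otherwise the manifest is read.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if structures is None:
        rows = read_manifest(config.manifest)
        structures = {}
        hashes = {}
        for row in rows:
            structures[row["id"]] = read_structure(row["path"], row["chain"], row["range"])
            structures[row["id"]].id = row["id"]
            hashes[row["id"]] = _file_hash(row["path"])
    else:
        hashes = {
            dom_id: hashlib.sha1(
                dom.coords.tobytes() + dom.sequence.encode()
            ).hexdigest()[:16]
            for dom_id, dom in structures.items()
        }
    labels = list(structures)
    if len(labels) < 3:
        raise InputError("need >= 3 domains")
    timings["ingest"] = time.perf_counter() - t0

    cache_dir = None
    if config.cache:
        cache_dir = out / "cache"
        cache_dir.mkdir(exist_ok=True)

    t0 = time.perf_counter()
    alignments = {}
    n_converged = 0
    for la, lb in combinations(labels, 2):
        try:
            aln = _align_pair(structures[la], structures[lb], config,
                              cache_dir, hashes[la], hashes[lb])
        except Exception as exc:
            raise RuntimeError(f"alignment stage failed on pair ({la}, {lb}): {exc}") from exc
        alignments[(la, lb)] = aln
        n_converged += aln.converged
        logger.info("pair %s-%s: n_equiv=%d rmsd=%.3f iters=%d converged=%s",
                    la, lb, aln.n_equivalent, aln.rmsd, aln.n_iterations, aln.converged)
    timings["align"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records = [_sdm.pair_record(aln, structures[la], structures[lb])
               for (la, lb), aln in alignments.items()]
    matrix, table = _sdm.build_matrix(records, labels)
    if np.allclose(matrix.values, 0.0):
        logger.warning("all SDM values are zero: the domains are structurally identical")
    table.to_csv(out / "sdm_pairs.tsv", sep="\t", index=False, float_format="%.6f")
    matrix.to_phylip(out / "matrix.phy")
    matrix.to_tsv(out / "matrix.tsv")
    timings["sdm"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    trees_out: dict[str, str] = {}
    fit_score = None
    fm_tree = None
    for method in config.tree_methods:
        if method == "fm_clock":
            fm_tree, fit_score = _trees.fm_clock(matrix, power=config.power)
            tree = fm_tree
        elif method == "nj":
            tree = _trees.neighbor_joining(matrix)
        else:
            tree = _trees.upgma(matrix)
        newick = _trees.write_newick(tree)
        (out / f"tree_{method}.nwk").write_text(newick + "\n")
        trees_out[method] = newick
    timings["trees"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    id_records = [_seq.identity_from_structural_alignment(aln, structures[la], structures[lb])
                  for (la, lb), aln in alignments.items()]
    pd_rows = [[r.id_a, r.id_b, r.n_identical, r.n_aligned,
                f"{r.percent_identity:.2f}", r.source] for r in id_records]
    with open(out / "identities.tsv", "w") as fh:
        fh.write("id_a\tid_b\tn_identical\tn_aligned\tpercent_identity\tsource\n")
        for row in pd_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    hist = _seq.identity_histogram(id_records)
    seq_matrix = _seq.identity_distance_matrix(id_records, labels)
    seq_tree = _trees.neighbor_joining(seq_matrix)
    seq_newick = _trees.write_newick(seq_tree)
    (out / "tree_sequence_nj.nwk").write_text(seq_newick + "\n")
    timings["sequence"] = time.perf_counter() - t0

    rf = None
    reference = fm_tree if fm_tree is not None else None
    if reference is not None:
        rf = _trees.robinson_foulds(reference, seq_tree)

    clusters = outliers = None
    if reference is not None and (config.cluster_k or config.cluster_height):
        blocks, outliers = _trees.extract_clusters(
            reference, height=config.cluster_height, k=config.cluster_k)
        clusters = blocks
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("leaf\tcluster_id\n")
            for cid, block in enumerate(blocks, start=1):
                for leaf in block:
                    fh.write(f"{leaf}\t{cid}\n")

    report = {
        "n_domains": len(labels),
        "n_pairs": len(alignments),
        "n_converged": int(n_converged),
        "fm_clock_fit_score": fit_score,
        "structure_vs_sequence_rf": rf,
        "identity_fraction_below_20": hist["cumulative_below"][20.0],
        "clusters": clusters,
        "outliers": outliers,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "summary.json").write_text(json.dumps(report, indent=2) + "\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    return report
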