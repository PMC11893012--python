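"""Intergenomic similarity, species/genus demarcation, protein clusters and
viral genome clusters (VGC).

The nucleotide side mirrors similarity-matrix phage taxonomy: pairwise
identity-weighted, length-normalised genome similarity with single-linkage
demarcation at 95% (species) and 70% (genus).  The protein side clusters
proteins across proteomes into protein clusters (PCs), derives a Dice-
complement intergenomic distance from shared PC content, and cuts an
average-linkage (UPGMA) dendrogram at a distance threshold to assign VGCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster, to_tree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .alignment import anchor_block_align, protein_alignment_stats
from .genome_io import AnnotatedGenome

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "ProteinCluster",
    "intergenomic_similarity",
    "similarity_matrix",
    "demarcate",
    "cluster_proteins",
    "pc_distance",
    "pc_distance_matrix",
    "hierarchical_vgc",
]


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # percent similarity, symmetric, diagonal 100
    aligned_fraction: np.ndarray  # symmetric in [0,1], diagonal 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def fraction_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.aligned_fraction, index=self.labels, columns=self.labels)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric in [0,1], zero diagonal

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class ProteinCluster:
    pc_id: str
    members: tuple[tuple[str, int], ...]  # (genome id, gene rank)


def intergenomic_similarity(
    genome_a: AnnotatedGenome | str,
    genome_b: AnnotatedGenome | str,
    k: int = 13,
    min_block: int = 30,
) -> tuple[float, float, float]:
    """Block-based intergenomic similarity of two genomes.

    similarity = 100 x (matches on A + matches on B) / (len A + len B);
    the aligned fraction of each genome is the covered length over its length.
    Ungapped blocks mean matches on A equal matches on B.
    """
    a = genome_a.sequence if isinstance(genome_a, AnnotatedGenome) else genome_a
    b = genome_b.sequence if isinstance(genome_b, AnnotatedGenome) else genome_b
    blocks = anchor_block_align(a, b, k=k, min_block=min_block)
    matches = sum(bl.matches for bl in blocks)
    cov_a = sum(bl.a_end - bl.a_start for bl in blocks)
    cov_b = sum(bl.b_end - bl.b_start for bl in blocks)
    sim = 100.0 * 2 * matches / (len(a) + len(b))
    return sim, cov_a / len(a), cov_b / len(b)


def similarity_matrix(genomes: list[AnnotatedGenome], k: int = 13, min_block: int = 30) -> SimilarityMatrix:
    n = len(genomes)
    sim = np.full((n, n), 100.0)
    frac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s, fa, fb = intergenomic_similarity(genomes[i], genomes[j], k=k, min_block=min_block)
            sim[i, j] = sim[j, i] = s
            frac[i, j] = fa
            frac[j, i] = fb
    return SimilarityMatrix([g.id for g in genomes], sim, frac)


def _threshold_components(labels: list[str], values: np.ndarray, threshold: float) -> dict[str, str]:
    """Single-linkage clusters: connected components of the >= threshold graph,
    each named after its lexicographically smallest member."""
    adj = csr_matrix(values >= threshold)
    _, comp = connected_components(adj, directed=False)
    clusters: dict[int, list[str]] = {}
    for lab, c in zip(labels, comp):
        clusters.setdefault(int(c), []).append(lab)
    out = {}
    for members in clusters.values():
        name = min(members)
        for m in members:
            out[m] = name
    return out


def demarcate(
    matrix: SimilarityMatrix,
    species_threshold: float = 95.0,
    genus_threshold: float = 70.0,
) -> tuple[dict[str, str], dict[str, str], int, int]:
    """Species and genus assignment by single-linkage threshold clustering.

    Returns (species labels, genus labels, n_species, n_genera).  Because
    species_threshold >= genus_threshold, the species partition refines the
    genus partition.
    """
    if species_threshold < genus_threshold:
        raise ValueError("species threshold must be >= genus threshold")
    species = _threshold_components(matrix.labels, matrix.values, species_threshold)
    genera = _threshold_components(matrix.labels, matrix.values, genus_threshold)
    return species, genera, len(set(species.values())), len(set(genera.values()))


# ---------------------------------------------------------------------------
# protein clusters

def _kmer_set(p: str, k: int = 4) -> set[str]:
    return {p[i : i + k] for i in range(len(p) - k + 1)}


def _edit_similarity_bound(p1: str, p2: str) -> float:
    """Cheap upper-bound proxy for percent identity from the unit-cost edit
    distance; used only to skip hopeless pairs before exact alignment."""
    d = edlib.align(p1, p2, task="distance")["editDistance"]
    hi = max(len(p1), len(p2))
    return 100.0 * (hi - d) / hi


def cluster_proteins(
    proteomes: dict[str, list[str]],
    min_identity: float = 50.0,
    min_coverage: float = 0.5,
) -> list[ProteinCluster]:
    """Cluster all proteins across proteomes into PCs.

    A hit requires global percent identity >= min_identity with aligned
    residue pairs covering >= min_coverage of the longer protein; PCs are the
    connected components of the hit graph, singletons included.  Candidate
    pairs are prefiltered by length ratio and shared 4-mers, which cannot
    exclude a true hit at these thresholds in practice.
    """
    keys: list[tuple[str, int]] = []
    seqs: list[str] = []
    for gid in proteomes:
        for rank, p in enumerate(proteomes[gid]):
            keys.append((gid, rank))
            seqs.append(p)
    n = len(seqs)
    kmers = [_kmer_set(p) for p in seqs]
    lengths = np.array([len(p) for p in seqs])
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = sorted((lengths[i], lengths[j]))
            if lo / hi < min_coverage:
                continue
            if find(i) == find(j):
                continue
            if not (kmers[i] & kmers[j]):
                continue
            # the edit-distance bound is generous: a true >=50%-identity hit
            # can never fall below ~40% unit-cost similarity
            if _edit_similarity_bound(seqs[i], seqs[j]) < min_identity - 12.0:
                continue
            identity, coverage = protein_alignment_stats(seqs[i], seqs[j])
            if identity >= min_identity and coverage >= min_coverage:
                union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda idxs: min(keys[i] for i in idxs))
    return [
        ProteinCluster(
            pc_id=f"PC{c + 1:04d}",
            members=tuple(sorted(keys[i] for i in idxs)),
        )
        for c, idxs in enumerate(ordered)
    ]


def _pc_sets(pcs: list[ProteinCluster]) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for pc in pcs:
        for gid, _rank in pc.members:
            sets.setdefault(gid, set()).add(pc.pc_id)
    return sets


def pc_distance(genome_a: str, genome_b: str, pcs: list[ProteinCluster]) -> float:
    """Dice-complement distance on PC presence sets:
    d = 1 - 2|shared| / (|A| + |B|)."""
    sets = _pc_sets(pcs)
    sa, sb = sets.get(genome_a, set()), sets.get(genome_b, set())
    if not sa and not sb:
        return 0.0
    return 1.0 - 2.0 * len(sa & sb) / (len(sa) + len(sb))


def pc_distance_matrix(labels: list[str], pcs: list[ProteinCluster]) -> DistanceMatrix:
    sets = _pc_sets(pcs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = sets.get(labels[i], set()), sets.get(labels[j], set())
            dij = 0.0 if not sa and not sb else 1.0 - 2.0 * len(sa & sb) / (len(sa) + len(sb))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(labels), d)


def _newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    # ultrametric: branch length is half the merge-height difference
    parts = []
    for child in (node.left, node.right):
        bl = (node.dist - child.dist) / 2.0
        parts.append(f"{_newick(child, labels)}:{bl:.6f}")
    return "(" + ",".join(parts) + ")"


def hierarchical_vgc(distances: DistanceMatrix, cut: float = 0.7) -> tuple[str, dict[str, str]]:
    """Average-linkage (UPGMA) clustering of the PC distance matrix.

    Returns a newick dendrogram and VGC labels obtained by cutting the tree
    at the given height; VGCs are numbered by first appearance in label
    order.  Lowering the cut only refines the partition.
    """
    if not np.all(np.isfinite(distances.values)):
        raise ValueError("distance matrix contains non-finite values")
    n = len(distances.labels)
    if n == 1:
        return f"{distances.labels[0]};", {distances.labels[0]: "VGC1"}
    z = linkage(squareform(distances.values, checks=False), method="average")
    flat = fcluster(z, t=cut, criterion="distance")
    order: dict[int, str] = {}
    labels_out: dict[str, str] = {}
    for lab, c in zip(distances.labels, flat):
        if int(c) not in order:
            order[int(c)] = f"VGC{len(order) + 1}"
        labels_out[lab] = order[int(c)]
    tree = to_tree(z)
    newick = _newick(tree, distances.labels) + ";"
    return newick, labels_out
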