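"""Synteny-anchored pangenome construction and core/flexible/unique classification.

The family builder operationalises a manual curation protocol: for each
reference gene, candidate orthologs in the other genomes are screened by the
similarity of either terminal protein segment, anchored by gene order
(rank offsets relative to the nearest already-matched neighbour, which
tolerates insertions in variable regions), and verified by full-length
percent identity against the reference homolog.  Genes matching no reference
family are grouped among themselves by the same rule; remainders become
unique singleton families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .alignment import protein_identity
from .genome_io import AnnotatedGenome

__all__ = [
    "GeneFamily",
    "PangenomeSummary",
    "build_families",
    "classify_and_summarize",
    "percent",
    "reference_identity_matrix",
    "intersect_core",
]


def percent(count: int, total: int, decimals: int) -> float:
    """100 x count/total rounded half-up to the requested decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass
class GeneFamily:
    family_id: str
    reference_member: tuple[str, int] | None  # (reference genome id, gene rank)
    members: dict[str, int]  # genome id -> gene rank (at most one per genome)
    klass: str = ""  # core | flexible | unique
    ref_identity: dict[str, float] = field(default_factory=dict)
    representative: str = ""  # protein sequence of the reference/founding member

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PangenomeSummary:
    """Gene-level pangenome composition (counts are genes, not families)."""

    n_genomes: int
    total_genes: int
    core_genes: int
    flexible_genes: int
    unique_genes: int
    n_core_families: int
    core_pct: float
    flexible_pct: float
    unique_pct: float


def _terminal_screen(p1: str, p2: str, window: int, threshold: float) -> bool:
    """True when either terminal segment reaches the screening identity."""
    for a, b in ((p1[:window], p2[:window]), (p1[-window:], p2[-window:])):
        if a and b and protein_identity(a, b) >= threshold:
            return True
    return False


def _match_genome(
    ref_genes: list,
    genome: AnnotatedGenome,
    terminal_window: int,
    terminal_identity: float,
    rank_window: int,
    verify_identity: float,
) -> dict[int, tuple[int, float]]:
    """Match reference gene ranks to ranks of one genome.

    Walks reference genes in order; the expected position of the next
    ortholog is anchored on the previously matched neighbour, and candidates
    within ``rank_window`` of it are screened and verified.  Returns
    {ref_rank: (genome_rank, identity)}.
    """
    out: dict[int, tuple[int, float]] = {}
    used: set[int] = set()
    prev_ref, prev_g = -1, -1
    for rg in ref_genes:
        expect = prev_g + (rg.rank - prev_ref)
        lo, hi = expect - rank_window, expect + rank_window
        best: tuple[float, int] | None = None
        for cand in genome.genes:
            if cand.rank in used or not lo <= cand.rank <= hi:
                continue
            if not _terminal_screen(rg.protein, cand.protein, terminal_window, terminal_identity):
                continue
            ident = protein_identity(rg.protein, cand.protein)
            if ident <= verify_identity:
                continue
            if best is None or ident > best[0] or (ident == best[0] and cand.rank < best[1]):
                best = (ident, cand.rank)
        if best is not None:
            out[rg.rank] = (best[1], best[0])
            used.add(best[1])
            prev_ref, prev_g = rg.rank, best[1]
    return out


def build_families(
    genomes: list[AnnotatedGenome],
    reference_id: str,
    terminal_window: int = 30,
    terminal_identity: float = 60.0,
    rank_window: int = 5,
    verify_identity: float = 58.0,
) -> list[GeneFamily]:
    """Build ortholog gene families anchored on a reference genome.

    Every gene ends up in exactly one family; membership requires full
    protein identity strictly greater than ``verify_identity`` against the
    family's reference (or founding) member.
    """
    by_id = {g.id: g for g in genomes}
    if reference_id not in by_id:
        raise ValueError(f"reference genome {reference_id!r} not in collection")
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    reference = by_id[reference_id]

    families: list[GeneFamily] = []
    assigned: dict[str, set[int]] = {g.id: set() for g in genomes}

    # reference-anchored families
    ref_families: dict[int, GeneFamily] = {}
    for rg in reference.genes:
        fam = GeneFamily(
            family_id=f"FAM{rg.rank + 1:04d}",
            reference_member=(reference_id, rg.rank),
            members={reference_id: rg.rank},
            ref_identity={reference_id: 100.0},
            representative=rg.protein,
        )
        ref_families[rg.rank] = fam
        families.append(fam)
    assigned[reference_id] = {rg.rank for rg in reference.genes}

    for genome in genomes:
        if genome.id == reference_id:
            continue
        matches = _match_genome(
            reference.genes, genome, terminal_window, terminal_identity,
            rank_window, verify_identity,
        )
        for ref_rank, (g_rank, ident) in matches.items():
            fam = ref_families[ref_rank]
            fam.members[genome.id] = g_rank
            fam.ref_identity[genome.id] = ident
            assigned[genome.id].add(g_rank)

    # reference-free families among the leftovers, grouped by the same rule
    novel: list[GeneFamily] = []
    for genome in genomes:
        if genome.id == reference_id:
            continue
        leftovers = [g for g in genome.genes if g.rank not in assigned[genome.id]]
        for gene in leftovers:
            best: tuple[float, GeneFamily] | None = None
            for fam in novel:
                if genome.id in fam.members:
                    continue
                if not _terminal_screen(
                    fam.representative, gene.protein, terminal_window, terminal_identity
                ):
                    continue
                ident = protein_identity(fam.representative, gene.protein)
                if ident <= verify_identity:
                    continue
                if best is None or ident > best[0]:
                    best = (ident, fam)
            if best is not None:
                best[1].members[genome.id] = gene.rank
                best[1].ref_identity[genome.id] = best[0]
            else:
                fam = GeneFamily(
                    family_id=f"NOV{len(novel) + 1:04d}",
                    reference_member=None,
                    members={genome.id: gene.rank},
                    ref_identity={genome.id: 100.0},
                    representative=gene.protein,
                )
                novel.append(fam)
            assigned[genome.id].add(gene.rank)
    families.extend(novel)

    n = len(genomes)
    for fam in families:
        fam.klass = "core" if fam.size == n else ("unique" if fam.size == 1 else "flexible")
    return families


def classify_and_summarize(
    families: list[GeneFamily] | tuple[int, int, int],
    n_genomes: int,
    decimals: tuple[int, int, int] = (2, 2, 1),
) -> PangenomeSummary:
    """Aggregate gene-level pangenome counts and percentages.

    Accepts either built families or raw (core, flexible, unique) gene
    counts.  Percentages are rounded half-up at the requested precision
    (two decimals for core/flexible, one for unique, by default).
    """
    if isinstance(families, tuple):
        core, flexible, unique = families
        n_core_families = 0
    else:
        core = flexible = unique = 0
        n_core_families = 0
        for fam in families:
            if fam.size > n_genomes:
                raise ValueError(
                    f"family {fam.family_id} has {fam.size} members for {n_genomes} genomes"
                )
            if fam.klass == "core":
                core += fam.size
                n_core_families += 1
            elif fam.klass == "unique":
                unique += fam.size
            else:
                flexible += fam.size
    total = core + flexible + unique
    return PangenomeSummary(
        n_genomes=n_genomes,
        total_genes=total,
        core_genes=core,
        flexible_genes=flexible,
        unique_genes=unique,
        n_core_families=n_core_families,
        core_pct=percent(core, total, decimals[0]),
        flexible_pct=percent(flexible, total, decimals[1]),
        unique_pct=percent(unique, total, decimals[2]),
    )


def reference_identity_matrix(families: list[GeneFamily], reference_id: str) -> pd.DataFrame:
    """Genomes x reference-anchored-core-family matrix of percent identity to
    the reference homolog (columns in reference gene order; absent -> NaN)."""
    core = [
        f for f in families
        if f.klass == "core" and f.reference_member and f.reference_member[0] == reference_id
    ]
    core.sort(key=lambda f: f.reference_member[1])
    genome_ids = sorted({gid for f in families for gid in f.members})
    genome_ids.remove(reference_id)
    genome_ids.insert(0, reference_id)
    data = np.full((len(genome_ids), len(core)), np.nan)
    for j, fam in enumerate(core):
        for i, gid in enumerate(genome_ids):
            if gid in fam.ref_identity:
                data[i, j] = fam.ref_identity[gid]
    return pd.DataFrame(data, index=genome_ids, columns=[f.family_id for f in core])


def intersect_core(
    core_a: list[str] | int,
    core_b: list[str] | int,
    n_shared: int | None = None,
    match_identity: float = 80.0,
) -> tuple[int, float, float]:
    """Intersect two core gene sets.

    With representative protein lists, families are matched across sets by
    best reciprocal identity >= ``match_identity``; with integer set sizes
    and an explicit ``n_shared``, only the coincidence arithmetic is done.
    Returns (n_shared, coincidence_A %, coincidence_B %), percentages rounded
    half-up to one decimal.
    """
    if isinstance(core_a, int) and isinstance(core_b, int):
        if n_shared is None:
            raise ValueError("n_shared required with integer set sizes")
        if core_a <= 0 or core_b <= 0:
            raise ValueError("core sets must be non-empty")
        return n_shared, percent(n_shared, core_a, 1), percent(n_shared, core_b, 1)
    if not core_a or not core_b:
        raise ValueError("core sets must be non-empty")
    best_ab: dict[int, tuple[float, int]] = {}
    best_ba: dict[int, tuple[float, int]] = {}
    for i, pa in enumerate(core_a):
        for j, pb in enumerate(core_b):
            ident = protein_identity(pa, pb)
            if ident < match_identity:
                continue
            if i not in best_ab or ident > best_ab[i][0]:
                best_ab[i] = (ident, j)
            if j not in best_ba or ident > best_ba[j][0]:
                best_ba[j] = (ident, i)
    shared = sum(
        1 for i, (_, j) in best_ab.items() if best_ba.get(j, (None, None))[1] == i
    )
    return shared, percent(shared, len(core_a), 1), percent(shared, len(core_b), 1)
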