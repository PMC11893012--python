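"""Feature scanners and classifiers: lipobox motifs, sequence typing,
attachment-site reconstruction, nut-site search and consensus profiles,
positional conservation, and mean pairwise identity.

The lipobox is the [LVI][ASTVI][GAS][C] tetrapeptide recognised by
lipoprotein signal peptidase; cleavage occurs before the invariant cysteine.
Attachment sites are reconstructed from lysogens by locating the prophage via
its terminal anchors and reading the duplicated core at the attL/attR
junctions.  nut sites (boxA + spacer + boxB) are searched ungapped on both
strands and summarised as a position weight matrix with per-column
information content.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import protein_identity
from .genome_io import AnnotatedGenome, reverse_complement

__all__ = [
    "MotifHit",
    "AttSite",
    "NutQuery",
    "NutHit",
    "NutProfile",
    "LIPOBOX_PATTERN",
    "scan_lipobox",
    "genome_has_lipoprotein",
    "type_sequences",
    "associate_types_with_loci",
    "detect_att",
    "scan_nut",
    "build_nut_profile",
    "align_proteins",
    "positional_conservation",
    "mean_pairwise_identity",
]

LIPOBOX_PATTERN = re.compile(r"(?=([LVI][ASTVI][GAS]C))")


@dataclass(frozen=True)
class MotifHit:
    genome_id: str
    gene_rank: int
    position: int  # 0-based protein position of the motif start
    matched: str  # the tetrapeptide
    cleavage_index: int  # position of the invariant C (= position + 3)


@dataclass
class AttSite:
    phage_id: str
    attL: tuple[int, int]  # lysogen coordinates of the left core copy
    attR: tuple[int, int]  # lysogen coordinates of the right core copy
    core: str
    host_locus: str  # host gene label or "unmapped"
    motif_class: str
    note: str = ""


@dataclass(frozen=True)
class NutQuery:
    name: str
    sequence: str
    boxA: tuple[int, int]  # span within the query, 0-based half-open
    boxB: tuple[int, int]


@dataclass(frozen=True)
class NutHit:
    site: str
    genome_id: str
    position: int
    strand: str
    mismatches: int
    matched: str  # query-oriented genomic sequence at the hit


@dataclass
class NutProfile:
    site: str
    hits: list[NutHit]
    pwm: pd.DataFrame  # position x {A,C,G,T}, rows sum to 1
    information_content: np.ndarray  # bits per column, in [0, 2]
    boxA: tuple[int, int] = (0, 0)
    boxB: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# lipobox

def scan_lipobox(
    genome: AnnotatedGenome,
    window: tuple[int, int] = (5, 40),
) -> list[MotifHit]:
    """All lipobox matches whose cysteine lies within ``window`` (0-based
    residue indices from the initiator Met), across every gene."""
    hits = []
    for gene in genome.genes:
        for m in LIPOBOX_PATTERN.finditer(gene.protein):
            c_idx = m.start() + 3
            if window[0] <= c_idx <= window[1]:
                hits.append(
                    MotifHit(
                        genome_id=genome.id,
                        gene_rank=gene.rank,
                        position=m.start(),
                        matched=m.group(1),
                        cleavage_index=c_idx,
                    )
                )
    return hits


def genome_has_lipoprotein(genome: AnnotatedGenome, window: tuple[int, int] = (5, 40)) -> bool:
    return bool(scan_lipobox(genome, window))


# ---------------------------------------------------------------------------
# sequence typing

def type_sequences(proteins: dict[str, str], typing_identity: float = 80.0) -> dict[str, str]:
    """Single-linkage sequence typing: connected components of the graph with
    edges at identity >= threshold.  Type labels are assigned by descending
    component size, ties broken by smallest member id."""
    if not proteins:
        raise ValueError("no sequences to type")
    ids = sorted(proteins)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(ids, 2):
        if find(a) != find(b) and protein_identity(proteins[a], proteins[b]) >= typing_identity:
            ra, rb = find(a), find(b)
            parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(), key=lambda ms: (-len(ms), min(ms)))
    out = {}
    for t, members in enumerate(ordered):
        for m in members:
            out[m] = f"T{t + 1}"
    return out


def associate_types_with_loci(
    types: dict[str, str], loci: dict[str, str]
) -> tuple[pd.DataFrame, bool]:
    """Cross-tabulate sequence types against host integration loci.

    Returns the contingency table and a flag that is true iff the mapping
    type -> locus is a function (each type integrates at exactly one locus).
    """
    common = sorted(set(types) & set(loci))
    if not common:
        raise ValueError("type and locus labelings share no genomes")
    table = pd.crosstab(
        pd.Series({g: types[g] for g in common}, name="type"),
        pd.Series({g: loci[g] for g in common}, name="locus"),
    )
    perfect = bool(((table > 0).sum(axis=1) == 1).all())
    return table, perfect


# ---------------------------------------------------------------------------
# attachment sites

def detect_att(
    lysogen_seq: str,
    host: AnnotatedGenome,
    phage_seq: str,
    phage_id: str = "",
    anchor: int = 200,
    junction_window: int = 60,
    min_core: int = 8,
) -> AttSite:
    """Reconstruct the attL/attR junctions of a prophage in a lysogen.

    The prophage is located by exact match of the phage terminal anchors; the
    integration core is the longest duplication shared by both junctions
    (site-specific integration duplicates the attB/attP core).  The core is
    then mapped back to the host reference; cores of different length at the
    same locus receive distinct motif classes (e.g. the 3-bp-extended
    variant).
    """
    left = phage_seq[:anchor]
    right = phage_seq[-anchor:]
    s = lysogen_seq.find(left)
    r = lysogen_seq.find(right)
    if s < 0 or r < 0:
        raise ValueError(f"phage {phage_id or '?'} terminal anchors not found in lysogen")
    e = r + anchor  # one past the phage 3' terminus == start of the right core copy
    # duplicated core: identical run from the prophage start and from e
    max_l = min(junction_window, len(lysogen_seq) - e)
    core_len = 0
    while core_len < max_l and lysogen_seq[s + core_len] == lysogen_seq[e + core_len]:
        core_len += 1
    core = lysogen_seq[s : s + core_len]
    site = AttSite(
        phage_id=phage_id,
        attL=(s, s + core_len),
        attR=(e, e + core_len),
        core=core,
        host_locus="unmapped",
        motif_class="unmapped",
    )
    if core_len < min_core:
        site.note = f"junction duplication shorter than {min_core} nt"
        return site
    occurrences = [m.start() for m in re.finditer(re.escape(core), host.sequence)]
    if len(occurrences) != 1:
        site.note = (
            "core absent from host reference" if not occurrences
            else f"core ambiguous in host ({len(occurrences)} occurrences)"
        )
        return site
    b = occurrences[0]
    # attB must be flanked identically in host and lysogen
    locus = "unmapped"
    for gene in host.genes:
        if gene.start - junction_window <= b < gene.end + junction_window:
            locus = gene.product
            break
    site.host_locus = locus
    site.motif_class = f"{locus}:{core_len}nt" if locus != "unmapped" else "unmapped"
    return site


# ---------------------------------------------------------------------------
# nut sites

def scan_nut(
    genome: AnnotatedGenome | str,
    queries: list[NutQuery],
    max_mismatch: int | None = None,
) -> dict[str, NutHit]:
    """Best ungapped hit of each nut-site query on either strand.

    The default mismatch tolerance is 30% of the query length; a query with
    no hit within tolerance is simply absent from the result.  Ties go to the
    smallest genomic position (plus strand preferred).
    """
    gid = genome.id if isinstance(genome, AnnotatedGenome) else ""
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out: dict[str, NutHit] = {}
    for q in queries:
        qarr = np.frombuffer(q.sequence.upper().encode(), dtype=np.uint8)
        L = len(qarr)
        tol = int(0.3 * L) if max_mismatch is None else max_mismatch
        best: NutHit | None = None
        for strand in "+-":
            target = qarr if strand == "+" else np.frombuffer(
                reverse_complement(q.sequence.upper()).encode(), dtype=np.uint8
            )
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mism = (windows != target).sum(axis=1)
            pos = int(np.argmin(mism))
            mm = int(mism[pos])
            if mm > tol:
                continue
            matched = seq[pos : pos + L]
            if strand == "-":
                matched = reverse_complement(matched)
            hit = NutHit(q.name, gid, pos, strand, mm, matched)
            if best is None or mm < best.mismatches or (
                mm == best.mismatches and pos < best.position
            ):
                best = hit
        if best is not None:
            out[q.name] = best
    return out


def build_nut_profile(
    site: str,
    hits: list[NutHit],
    boxA: tuple[int, int] = (0, 0),
    boxB: tuple[int, int] = (0, 0),
    pseudocount: float = 0.01,
) -> NutProfile:
    """Stack query-oriented hits column-wise into a PWM (pseudocount added to
    each base count) and per-column information content
    IC = 2 + sum_b p_b log2 p_b, in bits."""
    if not hits:
        raise ValueError(f"no hits to profile for site {site!r}")
    mat = np.array([list(h.matched) for h in hits])
    n = mat.shape[0]
    counts = np.stack([(mat == b).sum(axis=0) for b in "ACGT"], axis=1).astype(float)
    counts += pseudocount
    pwm = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.nansum(pwm * np.log2(pwm), axis=1)
    df = pd.DataFrame(pwm, columns=list("ACGT"))
    df.index.name = "position"
    return NutProfile(site=site, hits=list(hits), pwm=df,
                      information_content=ic, boxA=boxA, boxB=boxB)


# ---------------------------------------------------------------------------
# conservation

def align_proteins(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple protein alignment via mafft; returns id -> aligned sequence."""
    if len(seqs) == 1:
        return dict(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.faa"
        with open(fin, "w") as fh:
            for k in seqs:
                fh.write(f">{k}\n{seqs[k]}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", "--anysymbol", str(fin)],
            capture_output=True, text=True, check=True,
        )
    out: dict[str, str] = {}
    key = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            key = line[1:].strip()
            out[key] = ""
        elif key is not None:
            out[key] += line.strip().upper()
    if set(out) != set(seqs):
        raise RuntimeError("alignment lost sequences")
    return out


def positional_conservation(
    aligned: dict[str, str],
    positions: list[int],
    residue: str,
    one_based: bool = True,
) -> dict[int, int]:
    """Count sequences carrying ``residue`` at each queried alignment column."""
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (width,) = lengths
    out = {}
    for pos in positions:
        col = pos - 1 if one_based else pos
        if not 0 <= col < width:
            raise ValueError(f"position {pos} beyond alignment width {width}")
        out[pos] = sum(1 for s in aligned.values() if s[col] == residue)
    return out


def mean_pairwise_identity(proteins: list[str]) -> float:
    """Mean global percent identity over all unordered pairs, rounded half-up
    to two decimals."""
    if len(proteins) < 2:
        raise ValueError("need at least two sequences")
    vals = [protein_identity(a, b) for a, b in combinations(proteins, 2)]
    mean = Decimal(sum(vals)) / Decimal(len(vals))
    return float(mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
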