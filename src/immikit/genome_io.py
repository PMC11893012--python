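"""Genome and gene-table I/O and the shared data model.

Coordinates are 0-based half-open throughout the package; GFF3 (1-based,
inclusive) is converted at the parsing boundary.  Minus-strand CDS features
are translated from the reverse complement of their genomic slice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

__all__ = [
    "AnnotatedGenome",
    "GeneFeature",
    "CompositionStats",
    "FastaParseError",
    "GeneTableError",
    "TranslationError",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "read_gff3",
    "write_gene_table",
    "write_gff3",
    "write_protein_fasta",
    "translate_cds",
    "reverse_complement",
    "gc_content",
]

NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TSV_COLUMNS = ["genome_id", "rank", "start", "end", "strand", "product", "protein"]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate ids, bad characters)."""


class GeneTableError(ValueError):
    """Raised for malformed gene tables (bad coordinates, unknown genomes)."""


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated (internal stop, non-triplet length)."""


@dataclass
class GeneFeature:
    """A CDS call: half-open nucleotide coordinates plus its protein product."""

    rank: int
    start: int
    end: int
    strand: str  # "+" or "-"
    product: str
    protein: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GeneTableError(
                f"gene rank {self.rank}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GeneTableError(f"gene rank {self.rank}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A nucleotide genome plus its ordered gene features."""

    id: str
    sequence: str
    topology: str = "linear"
    genes: list[GeneFeature] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_nt(self, gene: GeneFeature) -> str:
        """Coding-strand nucleotide sequence of a gene."""
        nt = self.sequence[gene.start : gene.end]
        return reverse_complement(nt) if gene.strand == "-" else nt

    def proteome(self) -> list[str]:
        return [g.protein for g in self.genes]

    def copy(self) -> "AnnotatedGenome":
        return replace(self, genes=[replace(g) for g in self.genes])


@dataclass(frozen=True)
class CompositionStats:
    gc_fraction: float
    length: int
    n_genes: int

    @property
    def gc_percent(self) -> float:
        return 100.0 * self.gc_fraction


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta_records(path: Path) -> Iterable[tuple[str, str]]:
    header: str | None = None
    chunks: list[str] = []
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            elif line:
                if header is None:
                    raise FastaParseError(f"{path}: sequence data before first header")
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_fasta(path: str | Path) -> list[AnnotatedGenome]:
    """Read a nucleotide FASTA file into genomes with empty gene lists.

    Sequences are upper-cased; characters outside {A,C,G,T,N} are rejected.
    """
    path = Path(path)
    genomes: list[AnnotatedGenome] = []
    seen: set[str] = set()
    for rid, seq in _iter_fasta_records(path):
        if not rid:
            raise FastaParseError(f"{path}: record with empty id")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = seq.upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise FastaParseError(
                f"{path}: record {rid!r} contains illegal characters {sorted(bad)}"
            )
        if not seq:
            raise FastaParseError(f"{path}: record {rid!r} is empty")
        genomes.append(AnnotatedGenome(id=rid, sequence=seq, source=str(path)))
    if not genomes:
        raise FastaParseError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(path: str | Path, records: Iterable[tuple[str, str] | AnnotatedGenome], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, AnnotatedGenome) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_protein_fasta(path: str | Path, genomes: Iterable[AnnotatedGenome], width: int = 60) -> None:
    """Write every gene's protein as ``genome_id|rank`` records."""
    with open(path, "w") as fh:
        for g in genomes:
            for gene in g.genes:
                fh.write(f">{g.id}|{gene.rank}\n")
                for i in range(0, len(gene.protein), width):
                    fh.write(gene.protein[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables (TSV and GFF3)

def _attach(genomes: dict[str, AnnotatedGenome], rows: list[dict]) -> None:
    per_genome: dict[str, list[GeneFeature]] = {gid: [] for gid in genomes}
    for row in rows:
        gid = row["genome_id"]
        if gid not in genomes:
            raise GeneTableError(f"unknown genome_id {gid!r} in gene table")
        genome = genomes[gid]
        start, end = int(row["start"]), int(row["end"])
        if start < 0 or end > len(genome.sequence):
            raise GeneTableError(
                f"{gid}: gene [{start},{end}) outside genome of length {len(genome.sequence)}"
            )
        per_genome[gid].append(
            GeneFeature(
                rank=int(row.get("rank", 0)),
                start=start,
                end=end,
                strand=row["strand"],
                product=row.get("product", ""),
                protein=row.get("protein", ""),
            )
        )
    for gid, feats in per_genome.items():
        feats.sort(key=lambda f: (f.start, f.end))
        for i, f in enumerate(feats):
            f.rank = i
        genomes[gid].genes = feats


def read_gene_table(path: str | Path, genomes: list[AnnotatedGenome]) -> list[AnnotatedGenome]:
    """Attach gene features from a TSV table; features are sorted by start and
    ranks re-indexed from 0.  Returns the same genome objects."""
    path = Path(path)
    by_id = {g.id: g for g in genomes}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise GeneTableError(f"{path}: empty gene table")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise GeneTableError(f"{path}: missing columns {sorted(missing)}")
        rows = [row for row in reader]
    _attach(by_id, rows)
    return genomes


def read_gff3(path: str | Path, protein_fasta: str | Path, genomes: list[AnnotatedGenome]) -> list[AnnotatedGenome]:
    """Attach CDS features from a GFF3 file plus a companion protein FASTA
    keyed by the feature ID attribute."""
    path = Path(path)
    proteins: dict[str, str] = {}
    for rid, seq in _iter_fasta_records(Path(protein_fasta)):
        proteins[rid] = seq.upper()
    by_id = {g.id: g for g in genomes}
    rows: list[dict] = []
    with open(path, newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GeneTableError(f"{path}: malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attrd = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attrd.get("ID", "")
            rows.append(
                {
                    "genome_id": seqid,
                    "rank": 0,
                    "start": int(start) - 1,  # GFF3 is 1-based inclusive
                    "end": int(end),
                    "strand": strand,
                    "product": attrd.get("product", ""),
                    "protein": proteins.get(fid, ""),
                }
            )
    _attach(by_id, rows)
    return genomes


def write_gene_table(path: str | Path, genomes: Iterable[AnnotatedGenome]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for g in genomes:
            for f in g.genes:
                writer.writerow([g.id, f.rank, f.start, f.end, f.strand, f.product, f.protein])


def write_gff3(gff_path: str | Path, faa_path: str | Path, genomes: Iterable[AnnotatedGenome]) -> None:
    genomes = list(genomes)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.id} 1 {len(g.sequence)}\n")
            for f in g.genes:
                fid = f"{g.id}|{f.rank}"
                attrs = f"ID={fid};product={f.product}"
                fh.write(
                    f"{g.id}\timmikit\tCDS\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
                )
    with open(faa_path, "w") as fh:
        for g in genomes:
            for f in g.genes:
                fh.write(f">{g.id}|{f.rank}\n")
                for i in range(0, len(f.protein), 60):
                    fh.write(f.protein[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Translation and composition

_START_CODONS = {"ATG", "GTG", "TTG"}  # bacterial/phage (table 11) initiators


def translate_cds(nt: str, table: int = 11) -> str:
    """Translate a coding-strand CDS with the bacterial code.

    The trailing stop is removed; an internal stop or a non-triplet length
    raises :class:`TranslationError`.  Alternative initiators (GTG/TTG) are
    rendered as Met, as annotation pipelines do.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise TranslationError(f"CDS length {len(nt)} is not a multiple of 3")
    if not nt:
        raise TranslationError("empty CDS")
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise TranslationError(f"internal stop codon at residue {aa.index('*')}")
    if aa and nt[:3] in _START_CODONS:
        aa = "M" + aa[1:]
    return aa


def gc_content(genome: AnnotatedGenome | str) -> CompositionStats:
    """GC fraction over unambiguous bases (N is excluded from the denominator)."""
    if isinstance(genome, AnnotatedGenome):
        seq, n_genes = genome.sequence, len(genome.genes)
    else:
        seq, n_genes = genome, 0
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionStats(gc_fraction=gc / acgt, length=len(seq), n_genes=n_genes)
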