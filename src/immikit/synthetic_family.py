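"""Synthetic temperate-phage family generator with a machine-readable truth record.

The simulator emulates the observed structure of a cohesive coliphage group:
a syntenic gene backbone organised in functional cassettes (regulation |
replication | lysis | structural), a nested genus/species population built by
substitution-only evolution to planted nucleotide identity targets, and a set
of planted biological features -- a highly conserved CI-type repressor, an
N-like antiterminator with conserved arginines, four divergent integrase
sequence types tied to distinct host attachment loci, lipobox-bearing
lipoprotein genes at a controlled prevalence, and three nut sites with
invariant boxA/boxB cores.  A host genome and site-specific-insertion
lysogens (attL = B-core-P', attR = P-core-B') are emitted alongside.

Every planted feature is recorded in :class:`FamilyTruth` with coordinates
that reproduce the planted strings verbatim from the emitted sequences, so
each downstream analysis stage has an exact parameter-recovery oracle.

Gene evolution biases substitutions toward synonymous third-codon-position
changes (knob ``synonymous_bias``) so that nucleotide identity demarcates
genera while proteins remain recognisably homologous family-wide, as in real
temperate-phage families.  The plain uniform-substitution primitive
:func:`mutate_to_identity` is used for intergenic spacers and exposed for
oracle tests.
"""

from __future__ import annotations

import json
import math
import zlib
from functools import lru_cache
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .genome_io import (
    AnnotatedGenome,
    GeneFeature,
    reverse_complement,
    translate_cds,
    write_fasta,
    write_gene_table,
    write_protein_fasta,
)

__all__ = [
    "SimulationConfig",
    "product_label",
    "family_from_product",
    "FamilyTruth",
    "SimulationResult",
    "SimulationConfigError",
    "simulate_family",
    "mutate_to_identity",
    "write_outputs",
]


class SimulationConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


def product_label(family: str) -> str:
    """Annotation string emitted for a planted gene family."""
    return PRODUCT_LABELS.get(family, f"hypothetical protein {family}")


def family_from_product(product: str) -> str:
    """Invert :func:`product_label` (used by truth-comparison code)."""
    for fam, label in PRODUCT_LABELS.items():
        if product == label:
            return fam
    return product.removeprefix("hypothetical protein ").strip()


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {65: 0, 67: 1, 71: 2, 84: 3}

BOXA = "CGCTCTTA"
# boxB hairpins share the adenine-rich recognition loop; the stems are
# site-specific so each nut site is a distinct search target
BOXB = {
    "nutL": "GCCCTGAAAAAGGGC",
    "nutR1": "CAGTCGAAAAAGACT",
    "nutR2": "TTGGCGAAAAAGCCA",
}
NUT_OFFSET = 20  # boxA offset within its intergenic spacer

STOP_CODONS = {"TAA", "TAG", "TGA"}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE11.forward_table)
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)

# lipobox spacing: cleavage C is the 20th residue of the planted lipoprotein
LIPOBOX_MOTIF = "LAGC"
LIPO_C_INDEX = 19  # 0-based residue index of the invariant C

ARG_POSITIONS = (17, 19, 20, 24)  # 1-based, fully conserved
ARG21_POSITION = 21  # 1-based, conserved in a configurable subset

PRODUCT_LABELS = {
    "int": "tyrosine integrase",
    "rep": "CI-like immunity repressor",
    "antiterm": "antiterminator protein",
    "lpp": "membrane lipoprotein",
}

HOST_LOCI = ("ydaM", "abgT", "mppA")
TYPE_TO_LOCUS = {"Ia": "ydaM", "Ib": "ydaM", "II": "abgT", "III": "mppA"}
INTEGRASE_TYPES = ("Ia", "Ib", "II", "III")


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimulationConfig:
    """Planted parameters of the synthetic family.

    Identity targets are pairwise nucleotide percent identities between
    genomes of the stated relationship; they must satisfy
    within_species >= within_genus >= between_genus.
    """

    genus_species_sizes: tuple[tuple[int, ...], ...] = ((2, 2, 1), (2, 2), (2, 1))
    n_core: int = 30
    n_flexible: int = 10
    n_unique: int = 6
    within_species_identity: float = 99.0
    within_genus_identity: float = 85.0
    between_genus_identity: float = 52.0
    gc: float = 0.46
    gene_length: tuple[int, int] = (300, 900)
    lipoprotein_prevalence: float = 40 / 48
    arg21_prevalence: float = 45 / 48
    nut_spacer_variability: float = 0.25
    synonymous_bias: float = 0.85
    repressor_nt_rate: float = 0.009
    integrase_between_type_identity: float = 68.0
    integrase_within_nt_rate: float = 0.005
    indel_rate: float = 0.0
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return sum(sum(g) for g in self.genus_species_sizes)

    def validate(self) -> None:
        ids = (
            self.within_species_identity,
            self.within_genus_identity,
            self.between_genus_identity,
        )
        if not all(0 < x <= 100 for x in ids):
            raise SimulationConfigError(f"identities must lie in (0, 100]: {ids}")
        if not (ids[0] >= ids[1] >= ids[2]):
            raise SimulationConfigError(
                "identity ordering violated: need within-species >= within-genus "
                f">= between-genus, got {ids}"
            )
        if self.n_core < 4:
            raise SimulationConfigError("n_core must be >= 4 (four special genes are core)")
        if self.n_unique > self.n_genomes:
            raise SimulationConfigError("n_unique exceeds the number of genomes")
        if self.n_genomes < 4:
            raise SimulationConfigError("need at least 4 genomes for four integrase types")
        if sum(len(g) for g in self.genus_species_sizes) < 4:
            raise SimulationConfigError(
                "need at least 4 species: integrase types are assigned per species"
            )
        if not 0 <= self.lipoprotein_prevalence <= 1:
            raise SimulationConfigError("lipoprotein_prevalence must lie in [0, 1]")
        if not 0 <= self.arg21_prevalence <= 1:
            raise SimulationConfigError("arg21_prevalence must lie in [0, 1]")
        if not 0 < self.gc < 1:
            raise SimulationConfigError("gc target must lie in (0, 1)")


@dataclass
class FamilyTruth:
    """Planted-parameter record; coordinates index the emitted sequences."""

    seed: int
    n_genomes: int
    reference_id: str
    genome_ids: list[str]
    genus_assignments: dict[str, str]
    species_assignments: dict[str, str]
    family_classes: dict[str, str]
    family_members: dict[str, list[str]]
    per_member_identity: dict[str, dict[str, float]]
    integrase_types: dict[str, str]
    att_assignments: dict[str, str]
    att_cores: dict[str, str]
    att_site_coords: dict[str, dict[str, list[int]]]
    lipobox_positions: dict[str, dict]
    lipoprotein_positive: list[str]
    nut_sites: dict[str, list[dict]]
    host_loci: dict[str, dict]
    arg_positions: list[int]
    arg21_position: int
    arg21_genomes: list[str]
    special_families: dict[str, str] = field(default_factory=dict)

    def n_species(self) -> int:
        return len(set(self.species_assignments.values()))

    def n_genera(self) -> int:
        return len(set(self.genus_assignments.values()))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FamilyTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulationResult:
    genomes: list[AnnotatedGenome]
    host: AnnotatedGenome
    lysogens: list[AnnotatedGenome]
    truth: FamilyTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# low-level sequence helpers

def _rng_for(seed: int, label: str) -> np.random.Generator:
    """Stable per-label substream: seed combined with a CRC of the label."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))
    )


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode()


def mutate_to_identity(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at Bernoulli rate (100-target)/100 per
    position, each hit replaced by a uniformly chosen different base.

    N bases are left untouched.  target 100 returns the sequence unchanged.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must lie in (0, 100]")
    p = (100.0 - target_identity) / 100.0
    if p == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    acgt = np.isin(arr, BASES)
    hit = (rng.random(len(arr)) < p) & acgt
    idx = np.where(hit)[0]
    if idx.size:
        cur = np.array([_B2I[b] for b in arr[idx]])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float(np.mean(aa == bb))


def _codon_weights(gc_bias: float) -> tuple[list[str], np.ndarray, dict[str, np.ndarray]]:
    """Per-codon sampling weights at a given per-base GC bias."""
    pb = {"A": (1 - gc_bias) / 2, "C": gc_bias / 2, "G": gc_bias / 2, "T": (1 - gc_bias) / 2}
    codons = sorted(_CODON_TO_AA)
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
    w /= w.sum()
    per_aa = {}
    for aa, cods in _AA_TO_CODONS.items():
        wa = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in cods])
        per_aa[aa] = wa / wa.sum()
    return codons, w, per_aa


@lru_cache(maxsize=8)
def _gc_calibrated_weights(gc_target: float):
    """Solve for the per-base GC bias whose stop-free codon distribution has
    the requested expected GC content."""
    def realized(bias: float) -> float:
        codons, w, _ = _codon_weights(bias)
        gc_counts = np.array([c.count("G") + c.count("C") for c in codons]) / 3.0
        return float(np.dot(w, gc_counts))

    lo_b, hi_b = 0.05, 0.95
    for _ in range(40):
        mid = (lo_b + hi_b) / 2
        if realized(mid) < gc_target:
            lo_b = mid
        else:
            hi_b = mid
    return _codon_weights((lo_b + hi_b) / 2)


def _random_codons(rng: np.random.Generator, n_codons: int, gc: float) -> list[str]:
    codons, w, _ = _gc_calibrated_weights(round(gc, 4))
    idx = rng.choice(len(codons), size=n_codons, p=w)
    return [codons[int(i)] for i in idx]


def _encode_protein(aa: str, rng: np.random.Generator, gc: float = 0.46) -> str:
    """Back-translate with GC-weighted synonymous codon choices."""
    _, _, per_aa = _gc_calibrated_weights(round(gc, 4))
    out = []
    for a in aa:
        cods = _AA_TO_CODONS[a]
        out.append(cods[int(rng.choice(len(cods), p=per_aa[a]))])
    return "".join(out)


def _random_protein(rng: np.random.Generator, n_res: int) -> str:
    aas = sorted(_AA_TO_CODONS)
    return "M" + "".join(rng.choice(aas) for _ in range(n_res - 1))


def _mutate_gene(
    cds: str,
    rate: float,
    rng: np.random.Generator,
    protected_codons: frozenset[int] = frozenset(),
    synonymous_bias: float = 0.85,
    gc: float = 0.46,
) -> str:
    """Substitution-only gene evolution hitting a per-site substitution rate.

    A fraction ``synonymous_bias`` of substitutions is placed at third codon
    positions as synonymous changes; the rest are GC-calibrated substitutions
    that never create a stop codon.  The initiator and stop codons and any
    ``protected_codons`` (0-based codon indices) are never touched.
    """
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n = len(codons)
    protected = set(protected_codons) | {0, n - 1}
    mutable = [i for i in range(n) if i not in protected]
    n_sites = 3 * len(mutable)
    if n_sites == 0 or rate <= 0:
        return cds
    m = int(rng.binomial(n_sites, min(rate, 1.0)))
    if m == 0:
        return cds
    n_syn = int(rng.binomial(m, synonymous_bias))
    # synonymous changes at third positions
    syn_candidates = []
    for ci in mutable:
        c = codons[ci]
        aa = _CODON_TO_AA.get(c)
        if aa is None:
            continue
        alts = [x for x in _AA_TO_CODONS[aa] if x[:2] == c[:2] and x != c]
        if alts:
            syn_candidates.append(ci)
    n_syn = min(n_syn, len(syn_candidates))
    syn_pick = rng.choice(len(syn_candidates), size=n_syn, replace=False) if n_syn else []
    syn_set = {syn_candidates[i] for i in np.atleast_1d(syn_pick)} if n_syn else set()
    # replacement bases/codons are drawn from the GC-calibrated distribution
    # so base composition is stationary under evolution
    _, _, per_aa = _gc_calibrated_weights(round(gc, 4))
    pb = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    for ci in sorted(syn_set):
        c = codons[ci]
        cods = _AA_TO_CODONS[_CODON_TO_AA[c]]
        w = per_aa[_CODON_TO_AA[c]]
        alts = [(x, float(w[k])) for k, x in enumerate(cods) if x[:2] == c[:2] and x != c]
        weights = np.array([a[1] for a in alts])
        pick = int(rng.choice(len(alts), p=weights / weights.sum()))
        codons[ci] = alts[pick][0]
    # remaining substitutions anywhere (GC-weighted base change, no stops)
    rest = m - len(syn_set)
    flat = [(ci, pos) for ci in mutable if ci not in syn_set for pos in range(3)]
    rest = min(rest, len(flat))
    if rest > 0:
        pick = rng.choice(len(flat), size=rest, replace=False)
        for pi in np.atleast_1d(pick):
            ci, pos = flat[int(pi)]
            c = codons[ci]
            choices = [b for b in "ACGT"
                       if b != c[pos] and c[:pos] + b + c[pos + 1 :] not in STOP_CODONS]
            weights = np.array([pb[b] for b in choices])
            bi = int(rng.choice(len(choices), p=weights / weights.sum()))
            codons[ci] = c[:pos] + choices[bi] + c[pos + 1 :]
    return "".join(codons)


# ---------------------------------------------------------------------------
# family layout

@dataclass
class _Slot:
    family: str
    kind: str  # core | flexible | unique | special
    nut: str | None = None  # nut site planted in the spacer preceding this slot


def _build_layout(cfg: SimulationConfig) -> list[_Slot]:
    n_generic = cfg.n_core - 4
    generic = [f"core{i + 5:02d}" for i in range(n_generic)]
    # split generics across cassettes: regulation, replication, lysis, structural
    reg = generic[: max(1, n_generic * 3 // 10)]
    rest = generic[len(reg):]
    repl = rest[: max(1, len(rest) * 4 // 9)]
    rest = rest[len(repl):]
    lys = rest[: max(1, len(rest) // 3)]
    struct = rest[len(lys):]
    slots: list[_Slot] = [
        _Slot("int", "special"),
        _Slot("rep", "special", nut="nutL"),
        _Slot("antiterm", "special", nut="nutR1"),
    ]
    for i, fam in enumerate(reg):
        slots.append(_Slot(fam, "core", nut="nutR2" if i == 1 else None))
    if len(reg) < 2:  # tiny configurations: keep three nut sites regardless
        slots.append(_Slot("core_pad", "core", nut="nutR2"))
    # variable region: flexible and unique cassettes between regulation and replication
    var: list[_Slot] = [_Slot(f"flex{i + 1:02d}", "flexible") for i in range(cfg.n_flexible)]
    var += [_Slot(f"uniq{i + 1:02d}", "unique") for i in range(cfg.n_unique)]
    slots += var
    slots += [_Slot(f, "core") for f in repl]
    slots += [_Slot(f, "core") for f in lys]
    half = len(struct) // 2
    slots += [_Slot(f, "core") for f in struct[:half]]
    slots.append(_Slot("lpp", "special"))
    slots += [_Slot(f, "core") for f in struct[half:]]
    return slots


def _design_antiterm(rng: np.random.Generator) -> str:
    """72-residue N-like antiterminator with an arginine-rich motif."""
    aa = list(_random_protein(rng, 72))
    for pos in ARG_POSITIONS + (ARG21_POSITION,):
        aa[pos - 1] = "R"
    return "".join(aa)


def _design_lipoprotein(rng: np.random.Generator) -> str:
    """79-residue lipoprotein: MKK + hydrophobic signal peptide + lipobox."""
    aa = list(_random_protein(rng, 79))
    aa[0:3] = list("MKK")
    hydro = "LVAIF"
    for i in range(3, LIPO_C_INDEX - 3):
        aa[i] = hydro[int(rng.integers(len(hydro)))]
    aa[LIPO_C_INDEX - 3 : LIPO_C_INDEX + 1] = list(LIPOBOX_MOTIF)
    return "".join(aa)


# ---------------------------------------------------------------------------
# motif scrubbing

import re

_LIPOBOX_RE = re.compile(r"(?=([LVI][ASTVI][GAS]C))")


def _scrub_lipobox(cds: str, keep_c_index: int | None, window: tuple[int, int] = (5, 40)) -> str:
    """Remove accidental lipobox motifs whose C falls in the signal window by
    recoding the cysteine codon to serine; the planted motif (C at
    ``keep_c_index``) is preserved."""
    aa = translate_cds(cds)
    out = cds
    for m in _LIPOBOX_RE.finditer(aa):
        c_idx = m.start() + 3
        if c_idx == keep_c_index:
            continue
        if not window[0] <= c_idx <= window[1]:
            continue
        codon = out[3 * c_idx : 3 * c_idx + 3]  # TGT or TGC
        out = out[: 3 * c_idx] + "T" + "C" + codon[2] + out[3 * c_idx + 3 :]
    return out


# ---------------------------------------------------------------------------
# main generator

def simulate_family(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate the annotated phage family, host genome, lysogens and truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    seed = cfg.seed
    n = cfg.n_genomes
    genome_ids = [f"syn{i + 1:02d}" for i in range(n)]
    reference_id = genome_ids[0]

    # population structure
    genus_assignments: dict[str, str] = {}
    species_assignments: dict[str, str] = {}
    gi = 0
    sp = 0
    for gidx, genus in enumerate(cfg.genus_species_sizes):
        for ssize in genus:
            sp += 1
            for _ in range(ssize):
                genome_ids[gi]  # bounds check
                genus_assignments[genome_ids[gi]] = f"G{gidx + 1}"
                species_assignments[genome_ids[gi]] = f"S{sp}"
                gi += 1

    # per-branch substitution rates from pairwise identity targets
    p_s = 1 - math.sqrt(cfg.within_species_identity / 100.0)
    p_g = 1 - math.sqrt(cfg.within_genus_identity / 100.0)
    p_f = 1 - math.sqrt(cfg.between_genus_identity / 100.0)
    rate_genome = p_s
    rate_species = 1 - (1 - p_g) / (1 - p_s)
    rate_genus = 1 - (1 - p_f) / (1 - p_g)

    layout = _build_layout(cfg)
    root_rng = _rng_for(seed, "root")

    # root gene sequences
    lo, hi = cfg.gene_length
    root_genes: dict[str, str] = {}
    for slot in layout:
        if slot.family == "rep":
            cds = _encode_protein(_random_protein(root_rng, 210), root_rng, cfg.gc)
        elif slot.family == "antiterm":
            cds = _encode_protein(_design_antiterm(root_rng), root_rng, cfg.gc)
        elif slot.family == "lpp":
            cds = _encode_protein(_design_lipoprotein(root_rng), root_rng, cfg.gc)
        elif slot.family == "int":
            continue  # integrases come from the type ancestors below
        else:
            if slot.kind == "unique":
                # short accessory ORFs: morons barely perturb the planted
                # intergenomic-similarity bands
                n_codons = int(root_rng.integers(lo // 3, (lo + 150) // 3 + 1))
            elif slot.kind == "flexible":
                # mid-length accessory genes keep the within-genus band tight
                n_codons = int(root_rng.integers(lo // 3, (lo + hi) // 6 + 1))
            else:
                n_codons = int(root_rng.integers(lo // 3, hi // 3 + 1))
            cds = "".join(_random_codons(root_rng, n_codons, cfg.gc))
        cds = "ATG" + cds[3:] + "TAA"
        root_genes[slot.family] = _scrub_lipobox(
            cds, LIPO_C_INDEX if slot.family == "lpp" else None
        )

    # integrase type ancestors: conserved N-terminal 30 residues, divergent rest
    int_rng = _rng_for(seed, "integrase")
    int_root_aa = _random_protein(int_rng, 280)
    n_var = 280 - 30 - 1  # exclude conserved N-terminus and the final residue
    target_rest = (cfg.integrase_between_type_identity / 100.0 * 280 - 30) / (280 - 30)
    q_type = 1 - math.sqrt(max(target_rest, 0.05))
    type_ancestors_nt: dict[str, str] = {}
    aas = sorted(_AA_TO_CODONS)
    for t in INTEGRASE_TYPES:
        aa = list(int_root_aa)
        n_mut = int(int_rng.binomial(n_var, q_type))
        sites = int_rng.choice(np.arange(30, 279), size=n_mut, replace=False)
        for s in np.atleast_1d(sites):
            cur = aa[int(s)]
            alt = aas[int(int_rng.integers(len(aas)))]
            while alt == cur:
                alt = aas[int(int_rng.integers(len(aas)))]
            aa[int(s)] = alt
        cds = "ATG" + _encode_protein("".join(aa), int_rng, cfg.gc)[3:] + "TAA"
        type_ancestors_nt[t] = _scrub_lipobox(cds, None)

    # protected codons (0-based codon indices)
    protected: dict[str, frozenset[int]] = {
        "antiterm": frozenset(p - 1 for p in ARG_POSITIONS + (ARG21_POSITION,)),
        "lpp": frozenset(range(LIPO_C_INDEX - 3, LIPO_C_INDEX + 1)),
    }

    # root spacers; nut boxes embedded and masked from evolution
    spacer_specs: list[tuple[str, str | None]] = []  # (root spacer, nut name)
    for slot in layout:
        length = 80 if slot.nut else int(root_rng.integers(40, 81))
        sp_seq = _random_nt(root_rng, length, cfg.gc)
        if slot.nut:
            boxb = BOXB[slot.nut]
            sp_seq = (
                sp_seq[:NUT_OFFSET]
                + BOXA
                + sp_seq[NUT_OFFSET + 8 : NUT_OFFSET + 16]
                + boxb
                + sp_seq[NUT_OFFSET + 16 + len(boxb) :]
            )
        spacer_specs.append((sp_seq, slot.nut))
    terminal_spacer = _random_nt(root_rng, 60, cfg.gc)

    def evolve_spacer(sp_seq: str, nut: str | None, rate: float, rng: np.random.Generator) -> str:
        if nut is None:
            return mutate_to_identity(sp_seq, 100 * (1 - rate), rng)
        a0 = NUT_OFFSET
        var0 = a0 + 8
        b0 = var0 + 8
        b1 = b0 + len(BOXB[nut])
        head = mutate_to_identity(sp_seq[:a0], 100 * (1 - rate), rng)
        tail = mutate_to_identity(sp_seq[b1:], 100 * (1 - rate), rng)
        # boxes invariant; the 8-nt spacer between them is handled per genome
        return head + sp_seq[a0:var0] + sp_seq[var0:b0] + sp_seq[b0:b1] + tail

    # flexible family membership: random unions of whole species with a total
    # genome count in [2, N-1] (accessory content tracks species so planted
    # intergenomic-similarity bands stay separated)
    flex_rng = _rng_for(seed, "flexible")
    species_list = sorted(set(species_assignments.values()), key=lambda s: int(s[1:]))
    species_members = {
        s: [g for g in genome_ids if species_assignments[g] == s] for s in species_list
    }
    family_members: dict[str, list[str]] = {}
    for slot in layout:
        if slot.kind != "flexible":
            continue
        while True:
            order = flex_rng.permutation(len(species_list))
            target = int(flex_rng.integers(2, n))  # in [2, n-1]
            chosen: list[str] = []
            for oi in order:
                chosen += species_members[species_list[int(oi)]]
                if len(chosen) >= target:
                    break
            if 2 <= len(chosen) <= n - 1:
                family_members[slot.family] = sorted(chosen)
                break

    uniq_rng = _rng_for(seed, "unique")
    uniq_slots = [s for s in layout if s.kind == "unique"]
    owners = uniq_rng.choice(n, size=len(uniq_slots), replace=False)
    for slot, oi in zip(uniq_slots, np.atleast_1d(owners)):
        family_members[slot.family] = [genome_ids[int(oi)]]

    for slot in layout:
        if slot.kind in ("core", "special"):
            family_members[slot.family] = list(genome_ids)

    # planted feature subsets
    sub_rng = _rng_for(seed, "subsets")
    n_lipo = round(cfg.lipoprotein_prevalence * n)
    lipo_positive = sorted(
        genome_ids[int(i)] for i in sub_rng.choice(n, size=n_lipo, replace=False)
    )
    n_arg = round(cfg.arg21_prevalence * n)
    arg21_genomes = sorted(
        genome_ids[int(i)] for i in sub_rng.choice(n, size=n_arg, replace=False)
    )
    # integrase types are a species-level trait: all members of a species
    # carry the same type, so integration-module divergence never blurs the
    # planted within-species similarity band
    shuffled_sp = [species_list[int(i)] for i in sub_rng.permutation(len(species_list))]
    integrase_types: dict[str, str] = {}
    for chunk, t in zip(np.array_split(np.arange(len(shuffled_sp)), 4), INTEGRASE_TYPES):
        for ci in chunk:
            for gid in species_members[shuffled_sp[int(ci)]]:
                integrase_types[gid] = t

    # host genome with three attachment loci
    host_rng = _rng_for(seed, "host")
    host_genes: list[GeneFeature] = []
    host_parts: list[str] = []
    pos = 0
    gene_names = ["yaiC", "intQ", "ydaM", "yffL", "abgT", "ompW", "mppA", "rcsB", "uvrY"]
    locus_gene_pos: dict[str, tuple[int, int]] = {}
    for name in gene_names:
        gap = _random_nt(host_rng, int(host_rng.integers(150, 400)), 0.50)
        glen = int(host_rng.integers(700, 1100))
        gseq = _random_nt(host_rng, glen, 0.51)
        host_parts += [gap, gseq]
        gstart = pos + len(gap)
        host_genes.append(GeneFeature(0, gstart, gstart + glen, "+", name, ""))
        locus_gene_pos[name] = (gstart, gstart + glen)
        pos = gstart + glen
    host_parts.append(_random_nt(host_rng, 300, 0.50))
    host_seq = "".join(host_parts)

    core_long = _random_nt(host_rng, 17, 0.45)
    cores = {"Ia": core_long[:14], "Ib": core_long, "II": _random_nt(host_rng, 14, 0.45),
             "III": _random_nt(host_rng, 14, 0.45)}
    att_positions = {
        "ydaM": locus_gene_pos["ydaM"][0] + 10,   # 5'-terminal region
        "abgT": locus_gene_pos["abgT"][1] - 40,   # 3'-terminal region
        "mppA": locus_gene_pos["mppA"][0] - 3,    # initiation region
    }
    for locus in HOST_LOCI:
        core = core_long if locus == "ydaM" else cores["II" if locus == "abgT" else "III"]
        b = att_positions[locus]
        host_seq = host_seq[:b] + core + host_seq[b + len(core) :]

    def occurs_elsewhere(seq: str, sub: str, allowed: set[int]) -> list[int]:
        out = []
        start = 0
        while True:
            i = seq.find(sub, start)
            if i < 0:
                return out
            if i not in allowed:
                out.append(i)
            start = i + 1

    # scrub accidental att-core occurrences from the host background
    for locus in HOST_LOCI:
        core = core_long if locus == "ydaM" else cores["II" if locus == "abgT" else "III"]
        allowed = {att_positions[locus]}
        if locus == "ydaM":
            pass
        for i in occurs_elsewhere(host_seq, core[:14], {att_positions[l] for l in HOST_LOCI}):
            j = i + 7
            old = host_seq[j]
            new = "A" if old != "A" else "C"
            host_seq = host_seq[:j] + new + host_seq[j + 1 :]

    host = AnnotatedGenome(id="hostK12", sequence=host_seq, genes=host_genes,
                           source="immikit synthetic host")
    for i, g in enumerate(host.genes):
        g.rank = i

    host_loci_truth = {
        locus: {
            "gene": locus,
            "core": core_long if locus == "ydaM" else cores["II" if locus == "abgT" else "III"],
            "start": att_positions[locus],
            "end": att_positions[locus]
            + len(core_long if locus == "ydaM" else cores["II" if locus == "abgT" else "III"]),
        }
        for locus in HOST_LOCI
    }

    # ancestral gene/spacer sets per genus and species, then per genome
    def evolve_geneset(genes: dict[str, str], spacers: list[str], rate: float,
                       rng: np.random.Generator) -> tuple[dict[str, str], list[str]]:
        new_genes = {}
        for fam, cds in genes.items():
            new_genes[fam] = _mutate_gene(
                cds, rate, rng, protected.get(fam, frozenset()),
                cfg.synonymous_bias, cfg.gc,
            )
        new_spacers = [
            evolve_spacer(sp_seq, layout[i].nut if i < len(layout) else None, rate, rng)
            for i, sp_seq in enumerate(spacers)
        ]
        return new_genes, new_spacers

    root_spacers = [s for s, _ in spacer_specs] + [terminal_spacer]
    lineage_genes = {f: c for f, c in root_genes.items()}

    genus_sets: dict[str, tuple[dict[str, str], list[str]]] = {}
    for gname in sorted(set(genus_assignments.values())):
        rng = _rng_for(seed, f"genus:{gname}")
        genus_sets[gname] = evolve_geneset(lineage_genes, root_spacers, rate_genus, rng)
    species_sets: dict[str, tuple[dict[str, str], list[str]]] = {}
    for sname in species_list:
        gname = genus_assignments[species_members[sname][0]]
        rng = _rng_for(seed, f"species:{sname}")
        species_sets[sname] = evolve_geneset(*genus_sets[gname], rate_species, rng)

    genomes: list[AnnotatedGenome] = []
    lysogens: list[AnnotatedGenome] = []
    per_genome_genes: dict[str, dict[str, str]] = {}
    truth_nut: dict[str, list[dict]] = {}
    truth_lipo: dict[str, dict] = {}
    att_cores: dict[str, str] = {}
    att_assignments: dict[str, str] = {}
    att_site_coords: dict[str, dict[str, list[int]]] = {}

    for gid in genome_ids:
        rng = _rng_for(seed, f"genome:{gid}")
        genes, spacers = evolve_geneset(*species_sets[species_assignments[gid]],
                                        rate_genome, rng)

        # integrase: inherited from the type ancestor, not the lineage
        itype = integrase_types[gid]
        genes["int"] = _mutate_gene(
            type_ancestors_nt[itype], cfg.integrase_within_nt_rate, rng,
            synonymous_bias=0.0, gc=cfg.gc,
        )
        # repressor: near-frozen, evolved directly from the root copy
        genes["rep"] = _mutate_gene(
            root_genes["rep"], cfg.repressor_nt_rate, rng,
            synonymous_bias=0.0, gc=cfg.gc,
        )
        # antiterminator arginine 21: lysine in the non-conserved subset
        if gid not in arg21_genomes:
            c = genes["antiterm"]
            i = 3 * (ARG21_POSITION - 1)
            genes["antiterm"] = c[:i] + "AAA" + c[i + 3 :]
        # lipobox: intact only in the prevalence subset (C -> S otherwise)
        if gid not in lipo_positive:
            c = genes["lpp"]
            i = 3 * LIPO_C_INDEX
            genes["lpp"] = c[:i] + "AGC" + c[i + 3 :]
        # scrub lipobox motifs created by drift
        for fam in list(genes):
            keep = LIPO_C_INDEX if (fam == "lpp" and gid in lipo_positive) else None
            genes[fam] = _scrub_lipobox(genes[fam], keep)

        # per-genome nut spacer variability (relative to the planted root)
        nut_spacers: dict[str, str] = {}
        for i, slot in enumerate(layout):
            if slot.nut:
                var0 = NUT_OFFSET + 8
                root_var = root_spacers[i][var0 : var0 + 8]
                nut_spacers[slot.nut] = mutate_to_identity(
                    root_var, 100 * (1 - cfg.nut_spacer_variability), rng
                )

        # assemble: att core | (spacer + gene)* | terminal spacer
        core = cores[itype]
        parts = [core]
        feats: list[GeneFeature] = []
        nut_records: list[dict] = []
        pos = len(core)
        for i, slot in enumerate(layout):
            if gid not in family_members[slot.family]:
                continue
            sp_seq = spacers[i]
            if slot.nut:
                var0 = NUT_OFFSET + 8
                sp_seq = sp_seq[:var0] + nut_spacers[slot.nut] + sp_seq[var0 + 8 :]
                a_start = pos + NUT_OFFSET
                b_start = a_start + 16
                b_end = b_start + len(BOXB[slot.nut])
                nut_records.append(
                    {
                        "name": slot.nut,
                        "start": a_start,
                        "end": b_end,
                        "boxA": [a_start, a_start + 8],
                        "boxB": [b_start, b_end],
                        "strand": "+",
                    }
                )
            cds = genes[slot.family]
            strand = "-" if slot.family == "int" else "+"
            start = pos + len(sp_seq)
            feats.append(
                GeneFeature(
                    rank=len(feats),
                    start=start,
                    end=start + len(cds),
                    strand=strand,
                    product=product_label(slot.family),
                    protein=translate_cds(cds),
                )
            )
            parts.append(sp_seq)
            parts.append(reverse_complement(cds) if strand == "-" else cds)
            pos = start + len(cds)
        parts.append(spacers[-1])
        seq = "".join(parts)

        # keep the att core unique: scrub accidental occurrences in the interior
        for i in occurs_elsewhere(seq, core, {0}):
            j = max(i + len(core) - 1, len(core))
            old = seq[j]
            new = "A" if old != "A" else "C"
            seq = seq[:j] + new + seq[j + 1 :]
        # prevent coincidental core extension at the lysogen junctions
        locus = TYPE_TO_LOCUS[itype]
        b = att_positions[locus]
        lc = len(core)
        interior = seq[lc:]
        right_host = host.sequence[b + lc]
        if interior[0] == right_host:
            interior = ("A" if right_host != "A" else "C") + interior[1:]
        left_host = host.sequence[b - 1]
        if interior[-1] == left_host:
            interior = interior[:-1] + ("A" if left_host != "A" else "C")
        seq = core + interior

        genome = AnnotatedGenome(id=gid, sequence=seq, genes=feats,
                                 source="immikit synthetic phage")
        genomes.append(genome)
        per_genome_genes[gid] = genes
        truth_nut[gid] = nut_records
        if gid in lipo_positive:
            lpp_rank = next(f.rank for f in feats if f.product == product_label("lpp"))
            truth_lipo[gid] = {
                "rank": lpp_rank,
                "cleavage_index": LIPO_C_INDEX,
                "motif": translate_cds(genes["lpp"])[LIPO_C_INDEX - 3 : LIPO_C_INDEX + 1],
            }
        att_cores[gid] = core
        att_assignments[gid] = locus

        # lysogen: attL = B-core-P', attR = P-core-B'
        lys_seq = host.sequence[:b] + core + interior + core + host.sequence[b + lc :]
        lid = f"lysogen_{gid}"
        lysogens.append(AnnotatedGenome(id=lid, sequence=lys_seq,
                                        source="immikit synthetic lysogen"))
        s = b
        e = b + lc + len(interior)
        att_site_coords[lid] = {"attL": [s, s + lc], "attR": [e, e + lc]}

    # realized per-member protein identity to the reference homolog
    ref_genes = per_genome_genes[reference_id]
    per_member_identity: dict[str, dict[str, float]] = {}
    for slot in layout:
        fam = slot.family
        members = family_members[fam]
        if reference_id not in members:
            continue
        ref_aa = translate_cds(ref_genes[fam])
        per_member_identity[fam] = {
            gid: round(_hamming_identity(ref_aa, translate_cds(per_genome_genes[gid][fam])), 4)
            for gid in members
        }

    family_classes = {}
    for slot in layout:
        m = len(family_members[slot.family])
        family_classes[slot.family] = (
            "core" if m == n else ("unique" if m == 1 else "flexible")
        )

    truth = FamilyTruth(
        seed=seed,
        n_genomes=n,
        reference_id=reference_id,
        genome_ids=genome_ids,
        genus_assignments=genus_assignments,
        species_assignments=species_assignments,
        family_classes=family_classes,
        family_members={k: sorted(v) for k, v in family_members.items()},
        per_member_identity=per_member_identity,
        integrase_types=integrase_types,
        att_assignments=att_assignments,
        att_cores=att_cores,
        att_site_coords=att_site_coords,
        lipobox_positions=truth_lipo,
        lipoprotein_positive=lipo_positive,
        nut_sites=truth_nut,
        host_loci=host_loci_truth,
        arg_positions=list(ARG_POSITIONS),
        arg21_position=ARG21_POSITION,
        arg21_genomes=arg21_genomes,
        special_families={
            "integrase": "int",
            "repressor": "rep",
            "antiterminator": "antiterm",
            "lipoprotein": "lpp",
        },
    )
    return SimulationResult(genomes=genomes, host=host, lysogens=lysogens,
                            truth=truth, config=cfg)


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write genomes.fasta, proteins.faa, genes.tsv, host.fasta,
    host_genes.tsv, lysogens.fasta and truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "proteins": outdir / "proteins.faa",
        "genes": outdir / "genes.tsv",
        "host": outdir / "host.fasta",
        "host_genes": outdir / "host_genes.tsv",
        "lysogens": outdir / "lysogens.fasta",
        "truth": outdir / "truth.json",
    }
    write_fasta(paths["genomes"], result.genomes)
    write_protein_fasta(paths["proteins"], result.genomes)
    write_gene_table(paths["genes"], result.genomes)
    write_fasta(paths["host"], [result.host])
    write_gene_table(paths["host_genes"], [result.host])
    write_fasta(paths["lysogens"], result.lysogens)
    result.truth.to_json(paths["truth"])
    return paths
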