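"""End-to-end pipeline: simulate/load -> taxonomy -> pangenome -> feature scans.

Produces TSV/JSON/newick artifacts plus a machine-readable report; re-running
with an identical configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .features import (
    NutQuery,
    align_proteins,
    associate_types_with_loci,
    build_nut_profile,
    detect_att,
    genome_has_lipoprotein,
    mean_pairwise_identity,
    positional_conservation,
    scan_lipobox,
    scan_nut,
    type_sequences,
)
from .genome_io import AnnotatedGenome, gc_content, read_fasta, read_gene_table
from .pangenome import build_families, classify_and_summarize, reference_identity_matrix
from .synthetic_family import (
    SimulationConfig,
    SimulationResult,
    simulate_family,
    write_outputs,
)
from .taxonomy import (
    cluster_proteins,
    demarcate,
    hierarchical_vgc,
    pc_distance_matrix,
    similarity_matrix,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("immikit")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All pipeline knobs with their documented defaults."""

    # inputs: either simulate, or load from these paths
    simulate: bool = True
    genomes_fasta: str | None = None
    genes_tsv: str | None = None
    host_fasta: str | None = None
    host_genes_tsv: str | None = None
    lysogens_fasta: str | None = None
    reference_id: str | None = None  # defaults to the first genome

    # module knobs
    k: int = 13
    min_block: int = 30
    species_threshold: float = 95.0
    genus_threshold: float = 70.0
    pc_min_identity: float = 50.0
    pc_min_coverage: float = 0.5
    vgc_cut: float = 0.7
    terminal_window: int = 30
    terminal_identity: float = 60.0
    rank_window: int = 5
    verify_identity: float = 58.0
    typing_identity: float = 80.0
    lipobox_window: tuple[int, int] = (5, 40)
    att_anchor: int = 200
    junction_window: int = 60
    arg_positions: tuple[int, ...] = (17, 19, 20, 24, 21)
    arg_residue: str = "R"

    seed: int = 0
    outdir: str = "immikit_out"
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.species_threshold < self.genus_threshold:
            raise PipelineError(
                "config",
                f"species_threshold ({self.species_threshold}) must be >= "
                f"genus_threshold ({self.genus_threshold})",
            )
        if not 0 <= self.vgc_cut <= 1:
            raise PipelineError("config", "vgc_cut must lie in [0, 1]")
        if not self.simulate and not (self.genomes_fasta and self.genes_tsv):
            raise PipelineError(
                "config", "non-simulated runs require genomes_fasta and genes_tsv"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # output location is not part of the analysis
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _header(stage: str, cfg: RunConfig, params: str = "") -> str:
    return (
        f"# immikit {__version__} stage={stage} seed={cfg.seed} "
        f"config={cfg.config_hash()}" + (f" {params}" if params else "") + "\n"
    )


def _write_matrix_tsv(path: Path, df, stage: str, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(stage, cfg))
        df.to_csv(fh, sep="\t", float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the report dict and
    writes all artifacts under ``config.outdir``."""
    cfg = config
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "tool": "immikit",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
        }
    }
    with open(out / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")

    # ----- stage: inputs -------------------------------------------------
    sim_result: SimulationResult | None = None
    if cfg.simulate:
        log.info("stage=simulate n_genomes=%d seed=%d", cfg.sim.n_genomes, cfg.seed)
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        sim_result = simulate_family(sim_cfg)
        write_outputs(sim_result, out / "simulated")
        genomes = sim_result.genomes
        host = sim_result.host
        lysogens = sim_result.lysogens
    else:
        log.info("stage=load genomes=%s", cfg.genomes_fasta)
        try:
            genomes = read_fasta(cfg.genomes_fasta)
            read_gene_table(cfg.genes_tsv, genomes)
        except Exception as exc:  # noqa: BLE001 - re-tag with stage
            raise PipelineError("load", str(exc)) from exc
        host = None
        lysogens = []
        if cfg.host_fasta:
            host = read_fasta(cfg.host_fasta)[0]
            if cfg.host_genes_tsv:
                read_gene_table(cfg.host_genes_tsv, [host])
        if cfg.lysogens_fasta:
            lysogens = read_fasta(cfg.lysogens_fasta)

    reference_id = cfg.reference_id or genomes[0].id
    labels = [g.id for g in genomes]
    stats = [gc_content(g) for g in genomes]
    report["composition"] = {
        "n_genomes": len(genomes),
        "mean_gc_fraction": round(float(np.mean([s.gc_fraction for s in stats])), 4),
        "sd_gc_fraction": round(float(np.std([s.gc_fraction for s in stats])), 4),
        "mean_gc_percent": round(100 * float(np.mean([s.gc_fraction for s in stats])), 2),
        "genes_per_genome": [s.n_genes for s in stats],
    }

    # ----- stage: nucleotide taxonomy ------------------------------------
    log.info("stage=similarity n=%d", len(genomes))
    sm = similarity_matrix(genomes, k=cfg.k, min_block=cfg.min_block)
    _write_matrix_tsv(out / "similarity.tsv", sm.to_dataframe(), "similarity", cfg)
    _write_matrix_tsv(out / "aligned_fraction.tsv", sm.fraction_dataframe(), "similarity", cfg)
    species, genera, n_species, n_genera = demarcate(
        sm, cfg.species_threshold, cfg.genus_threshold
    )
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(_header("demarcate", cfg,
                         f"species>={cfg.species_threshold} genus>={cfg.genus_threshold}"))
        fh.write("genome\tspecies\tgenus\n")
        for lab in labels:
            fh.write(f"{lab}\t{species[lab]}\t{genera[lab]}\n")
    report["taxonomy"] = {"n_species": n_species, "n_genera": n_genera}

    # ----- stage: protein clusters and VGC --------------------------------
    log.info("stage=pc-cluster")
    proteomes = {g.id: [f.protein for f in g.genes] for g in genomes}
    pcs = cluster_proteins(proteomes, cfg.pc_min_identity, cfg.pc_min_coverage)
    with open(out / "pcs.tsv", "w") as fh:
        fh.write(_header("pc-cluster", cfg,
                         f"identity>={cfg.pc_min_identity} coverage>={cfg.pc_min_coverage}"))
        fh.write("pc_id\tgenome\trank\n")
        for pc in pcs:
            for gid, rank in pc.members:
                fh.write(f"{pc.pc_id}\t{gid}\t{rank}\n")
    dm = pc_distance_matrix(labels, pcs)
    _write_matrix_tsv(out / "distances.tsv", dm.to_dataframe(), "pc-distance", cfg)
    newick, vgc = hierarchical_vgc(dm, cut=cfg.vgc_cut)
    (out / "tree.nwk").write_text(newick + "\n")
    with open(out / "vgc.tsv", "w") as fh:
        fh.write(_header("vgc", cfg, f"cut={cfg.vgc_cut}"))
        fh.write("genome\tvgc\n")
        for lab in labels:
            fh.write(f"{lab}\t{vgc[lab]}\n")
    report["protein_clusters"] = {
        "n_pcs": len(pcs),
        "n_multi_genome_pcs": sum(1 for pc in pcs if len({g for g, _ in pc.members}) > 1),
        "n_vgcs": len(set(vgc.values())),
    }

    # ----- stage: pangenome ------------------------------------------------
    log.info("stage=pangenome reference=%s", reference_id)
    families = build_families(
        genomes, reference_id,
        terminal_window=cfg.terminal_window,
        terminal_identity=cfg.terminal_identity,
        rank_window=cfg.rank_window,
        verify_identity=cfg.verify_identity,
    )
    summary = classify_and_summarize(families, len(genomes))
    with open(out / "families.tsv", "w") as fh:
        fh.write(_header("pangenome", cfg, f"verify>{cfg.verify_identity}"))
        fh.write("family_id\tclass\tgenome\trank\tref_identity\n")
        for fam in families:
            for gid, rank in sorted(fam.members.items()):
                fh.write(
                    f"{fam.family_id}\t{fam.klass}\t{gid}\t{rank}\t"
                    f"{fam.ref_identity.get(gid, float('nan')):.2f}\n"
                )
    idm = reference_identity_matrix(families, reference_id)
    _write_matrix_tsv(out / "identity_matrix.tsv", idm, "pangenome", cfg)
    report["pangenome"] = {
        "n_families": len(families),
        "n_core_families": summary.n_core_families,
        "total_genes": summary.total_genes,
        "core_genes": summary.core_genes,
        "flexible_genes": summary.flexible_genes,
        "unique_genes": summary.unique_genes,
        "core_pct": summary.core_pct,
        "flexible_pct": summary.flexible_pct,
        "unique_pct": summary.unique_pct,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(report["pangenome"], fh, indent=1, sort_keys=True)
        fh.write("\n")

    # ----- stage: feature scans -------------------------------------------
    log.info("stage=features")
    lipo_rows = []
    lipo_positive = []
    for g in genomes:
        hits = scan_lipobox(g, cfg.lipobox_window)
        lipo_rows += hits
        if hits:
            lipo_positive.append(g.id)
    with open(out / "lipobox.tsv", "w") as fh:
        fh.write(_header("lipobox", cfg, f"window={cfg.lipobox_window}"))
        fh.write("genome\trank\tposition\tmotif\tcleavage_index\n")
        for h in lipo_rows:
            fh.write(f"{h.genome_id}\t{h.gene_rank}\t{h.position}\t{h.matched}\t{h.cleavage_index}\n")
    report["lipoproteins"] = {
        "n_positive_genomes": len(lipo_positive),
        "positive_genomes": sorted(lipo_positive),
        "prevalence": round(len(lipo_positive) / len(genomes), 4),
    }

    def _by_product(token: str) -> dict[str, str]:
        out_d = {}
        for g in genomes:
            for f in g.genes:
                if token in f.product:
                    out_d[g.id] = f.protein
                    break
        return out_d

    integrases = _by_product("integrase")
    report["integrases"] = {}
    types: dict[str, str] = {}
    if integrases:
        types = type_sequences(integrases, cfg.typing_identity)
        with open(out / "types.tsv", "w") as fh:
            fh.write(_header("type", cfg, f"identity>={cfg.typing_identity}"))
            fh.write("genome\ttype\n")
            for gid in sorted(types):
                fh.write(f"{gid}\t{types[gid]}\n")
        report["integrases"]["n_types"] = len(set(types.values()))

    att_rows = []
    loci: dict[str, str] = {}
    if host is not None and lysogens:
        by_id = {g.id: g for g in genomes}
        for lys in lysogens:
            pid = lys.id.removeprefix("lysogen_")
            phage = by_id.get(pid)
            if phage is None:
                continue
            try:
                site = detect_att(
                    lys.sequence, host, phage.sequence, phage_id=pid,
                    anchor=cfg.att_anchor, junction_window=cfg.junction_window,
                )
            except ValueError as exc:
                raise PipelineError("attsite", str(exc)) from exc
            att_rows.append(site)
            loci[pid] = site.host_locus
        with open(out / "attsites.tsv", "w") as fh:
            fh.write(_header("attsite", cfg, f"anchor={cfg.att_anchor}"))
            fh.write("phage\tattL_start\tattL_end\tattR_start\tattR_end\tcore\thost_locus\tmotif_class\n")
            for s in att_rows:
                fh.write(
                    f"{s.phage_id}\t{s.attL[0]}\t{s.attL[1]}\t{s.attR[0]}\t{s.attR[1]}\t"
                    f"{s.core}\t{s.host_locus}\t{s.motif_class}\n"
                )
        report["att_sites"] = {
            "n_detected": len(att_rows),
            "loci": {s.phage_id: s.host_locus for s in att_rows},
            "motif_classes": sorted({s.motif_class for s in att_rows}),
        }
        if types and loci:
            table, perfect = associate_types_with_loci(types, loci)
            report["type_locus_association"] = {
                "perfect": perfect,
                "table": {str(t): row.to_dict() for t, row in table.iterrows()},
            }

    # nut sites: query sequences from the reference genome's annotated sites
    nut_queries: list[NutQuery] = []
    if sim_result is not None:
        ref_records = sim_result.truth.nut_sites[reference_id]
        ref_seq = next(g.sequence for g in genomes if g.id == reference_id)
        for rec in ref_records:
            nut_queries.append(
                NutQuery(
                    rec["name"],
                    ref_seq[rec["start"] : rec["end"]],
                    (rec["boxA"][0] - rec["start"], rec["boxA"][1] - rec["start"]),
                    (rec["boxB"][0] - rec["start"], rec["boxB"][1] - rec["start"]),
                )
            )
    if nut_queries:
        per_site: dict[str, list] = {q.name: [] for q in nut_queries}
        for g in genomes:
            for name, hit in scan_nut(g, nut_queries).items():
                per_site[name].append(hit)
        ic_report = {}
        with open(out / "nut_hits.tsv", "w") as fh:
            fh.write(_header("nutscan", cfg))
            fh.write("site\tgenome\tposition\tstrand\tmismatches\n")
            for q in nut_queries:
                for h in per_site[q.name]:
                    fh.write(f"{h.site}\t{h.genome_id}\t{h.position}\t{h.strand}\t{h.mismatches}\n")
        for q in nut_queries:
            if not per_site[q.name]:
                continue
            prof = build_nut_profile(q.name, per_site[q.name], q.boxA, q.boxB)
            _write_matrix_tsv(out / f"nut_pwm_{q.name}.tsv", prof.pwm, "nutscan", cfg)
            ic = prof.information_content
            box_cols = list(range(*q.boxA)) + list(range(*q.boxB))
            spacer_cols = [i for i in range(len(ic)) if i not in box_cols]
            ic_report[q.name] = {
                "n_hits": len(per_site[q.name]),
                "mean_box_ic": round(float(np.mean(ic[box_cols])), 4),
                "mean_spacer_ic": round(float(np.mean(ic[spacer_cols])), 4),
            }
        report["nut_sites"] = ic_report

    # conserved regulators: repressor identity and antiterminator arginines
    reps = _by_product("repressor")
    if len(reps) >= 2:
        report["repressor"] = {
            "n": len(reps),
            "mean_pairwise_identity": mean_pairwise_identity(list(reps.values())),
        }
    antiterms = _by_product("antiterminator")
    if len(antiterms) >= 2:
        aligned = align_proteins(antiterms)
        cons = positional_conservation(
            aligned, list(cfg.arg_positions), cfg.arg_residue, one_based=True
        )
        report["antiterminator"] = {
            "n": len(antiterms),
            "arginine_conservation": {str(k): v for k, v in cons.items()},
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", out / "report.json")
    return report
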