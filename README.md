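# immikit

Comparative genomics of temperate coliphage families: intergenomic-similarity
taxonomy, protein-cluster genome clustering, synteny-anchored pangenomes, and
scanners for the biological features that characterise a phage group —
lipobox-bearing exclusion lipoproteins, integrase sequence types and their
attachment (att) sites, and nut-site antitermination elements.

## Who this is for

Phage genomicists delineating a new group of related phages and prophages:
given a set of annotated genomes (FASTA + gene tables with protein
translations), a host reference, and lysogen sequences, `immikit` answers the
questions such a study asks:

- **Taxonomy.** How many species and genera do the genomes represent?
  Pairwise intergenomic similarity is computed from ungapped seed-and-extend
  block alignments as `S(A,B) = 100 · (m_A + m_B) / (|A| + |B|)`, where `m_X`
  is the number of identically aligned bases on genome `X`; single-linkage
  clustering at the standard demarcation thresholds (≥95% for species,
  ≥70% for genus) yields the partition. On the proteome side, proteins are
  grouped into protein clusters (PCs; global identity ≥50% covering ≥50% of
  the longer protein), genomes are compared by the Dice complement
  `d(A,B) = 1 − 2|PC_A ∩ PC_B| / (|PC_A| + |PC_B|)`, and viral genome
  clusters (VGCs) are read off a UPGMA dendrogram cut at `d = 0.7`.
- **Pangenome.** Which genes are core (all genomes), flexible (some), or
  unique (one)? Ortholog families are built by a synteny-anchored screen —
  candidate genes must lie near the gene-order position predicted by the
  previously matched neighbour and share ≥60% identity over either terminal
  30 residues — and verified at >58% full-length identity against the
  reference homolog. Two core sets (e.g. manual vs automated annotation) are
  intersected by reciprocal best identity.
- **Features.** Which genomes encode a lipoprotein (lipobox
  `[LVI][ASTVI][GAS][C]` with the cleavage cysteine in the signal-peptide
  window)? How many integrase sequence types exist, and does each type map to
  exactly one host integration locus? Where are attL/attR and what is the
  duplicated core? How conserved are the nut-site boxA/boxB elements
  (position weight matrix, per-column information content) and the
  antiterminator's arginine-rich motif?

Because real phage collections are large and annotations heterogeneous, the
package ships a **synthetic family generator** that plants all of the above —
nested genus/species structure with controlled nucleotide identities, a
syntenic cassette backbone, four integrase types wired to three host att
loci, a near-frozen CI-type repressor, lipobox prevalence, three nut sites —
and emits a machine-readable truth record, so the entire pipeline is testable
end-to-end by exact parameter recovery.

## Worked example

```python
from immikit import SimulationConfig, simulate_family, similarity_matrix, demarcate
from immikit.pangenome import build_families, classify_and_summarize, percent, intersect_core

fam = simulate_family(SimulationConfig(seed=1))          # 12 genomes, 3 genera, 7 species
sm = similarity_matrix(fam.genomes)
species, genera, n_sp, n_gen = demarcate(sm)
print(f"recovered {n_sp} species and {n_gen} genera "
      f"(planted: {fam.truth.n_species()}, {fam.truth.n_genera()})")

families = build_families(fam.genomes, fam.truth.reference_id)
s = classify_and_summarize(families, len(fam.genomes))
print(f"core families: {s.n_core_families}; gene-level composition: "
      f"{s.core_pct}% core, {s.flexible_pct}% flexible, {s.unique_pct}% unique")

print(f"published counts 2813/5965 -> {percent(2813, 5965, 2)}% core genes")
n, ca, cb = intersect_core(59, 56, n_shared=50)
print(f"core-set coincidence: {ca}% (manual), {cb}% (automated)")
```

prints

```
recovered 7 species and 3 genera (planted: 7, 3)
core families: 30; gene-level composition: 83.72% core, 14.88% flexible, 1.4% unique
published counts 2813/5965 -> 47.16% core genes
core-set coincidence: 84.7% (manual), 89.3% (automated)
```

The first two lines are measured on the simulated family: the demarcation and
the family builder recover exactly the planted population structure and the
30 planted core families. The last two lines evaluate the package's summary
arithmetic on gene counts reported for a real 48-genome coliphage group: the
core genome is 47.16% of 5,965 genes, and of the 59 manually curated vs 56
automatically derived core products, 50 are shared (84.7% and 89.3%
coincidence; note 100·50/56 = 89.29, which rounds half-up to 89.3).

## Command line

```bash
immikit simulate --out sim --seed 1
immikit similarity sim/genomes.fasta --out matrix.tsv
immikit demarcate matrix.tsv --out clusters.tsv
immikit vgc sim/genomes.fasta sim/genes.tsv
immikit pangenome sim/genomes.fasta sim/genes.tsv --reference syn01
immikit lipobox sim/genomes.fasta sim/genes.tsv
immikit type sim/genomes.fasta sim/genes.tsv --what integrase
immikit attsite sim/lysogens.fasta sim/host.fasta sim/host_genes.tsv sim/genomes.fasta
immikit run --seed 1 --out full_run     # the whole pipeline + report.json
```

All outputs are TSV/JSON/newick with a header comment recording the stage,
parameters and tool version; re-running with the same seed and configuration
reproduces every file byte for byte.

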