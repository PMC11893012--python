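# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `immikit`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Intergenomic similarity and demarcation

Pairwise genome similarity is computed from ungapped aligned blocks obtained
by seed-and-extend: exact shared 13-mers (both strands of the second genome)
seed ungapped extensions that continue while a sliding 16-column window
retains ≥50% matches, and each block is trimmed back to the last match at
which its cumulative identity is ≥70%. Candidate blocks are selected
greedily by descending match count (ties by coordinates); a candidate that
overlaps already-selected intervals on either genome is clipped to its
non-overlapping part (matches recounted) rather than discarded, because a
single long syntenic block otherwise loses to a shorter high-identity block
that shares a few edge bases. Blocks shorter than 30 nt are dropped.

The defaults `k = 13` and `min_block = 30` make random ~25-kb genome pairs at
~46% GC essentially block-free (the expected number of shared 13-mers is a
handful, and their extensions die inside the 30-nt floor), while
substitution-only pairs at ≥85% identity are recovered to within one point of
the whole-genome Hamming identity (asserted in the test suite). Both are
configuration knobs.

Similarity is `100 · (m_A + m_B)/(|A| + |B|)` with `m_X` the identical
aligned bases on genome X (equal for both genomes since blocks are
ungapped); the aligned fraction of each genome is its covered length over
its length. Species and genera are single-linkage connected components of
the ≥95% and ≥70% similarity graphs; single linkage mirrors how
threshold-based intergenomic-similarity classification behaves, and
guarantees that the species partition refines the genus partition. Clusters
are named after their lexicographically smallest member so output is
deterministic.

A consequence worth knowing: on synonymous-saturated coding sequences the
block aligner — like any local nucleotide aligner — still chains codon
skeletons at ~60–70% identity, so the measured similarity of distantly
related genomes is dominated by first/second codon positions rather than the
raw substitution count. The simulator's identity bands account for this
(below).

## Protein clusters, PC distance and VGCs

Protein percent identity is global (Needleman–Wunsch) with match +1,
mismatch 0, gap open −10, gap extension −0.5; identity is
`100 · identical columns / alignment columns`, i.e. gap columns count in the
denominator. The heavy gap penalties make alignments of homologous phage
proteins essentially gapless, which matches the indel-free simulator and
keeps the 58% pangenome verification threshold interpretable.

Protein clusters (PCs) are connected components of the graph with edges
where identity ≥50% and the aligned residue pairs cover ≥50% of the longer
protein; singletons form singleton PCs. Candidate pairs are prefiltered by
length ratio, one shared amino-acid 4-mer, and a unit-cost edit-distance
bound (via edlib) set 12 points below the identity threshold — generous
enough that no qualifying pair can be excluded, and it cuts the all-pairs
alignment cost by an order of magnitude.

Genome-level distance is the Dice complement on PC presence sets,
`d = 1 − 2|shared|/(|A|+|B|)`. The dendrogram is average-linkage (UPGMA) on
this matrix, exported as newick with ultrametric branch lengths
(half the merge-height difference); viral genome clusters (VGCs) are the
leaves of the subtrees below the 0.7 cut. Different published tools use
different PC-distance formulas; the Dice complement is documented here as
this package's definition and exact numerical agreement with other tools is
not claimed.

## Synteny-anchored pangenome

The family builder walks the reference genome's genes in order. For each
reference gene the expected position of its ortholog in another genome is
anchored on the previously matched neighbour (`expected = previous match +
rank offset`), tolerating insertions in variable regions; candidates within
±5 ranks are screened by ≥60% identity over either terminal 30 residues and
verified at >58% full-length identity, with the best identity winning (ties
to the smaller rank) and at most one member per genome. Genes matching no
reference family are grouped among themselves by the same screen+verify
rule, founding reference-free families; remainders become unique singleton
families. Classes follow membership: core = all genomes, unique = one,
flexible = otherwise; summaries count genes (not families), and percentages
are rounded half-up at the printed precision. The 58% figure is treated as a
strict verification threshold although it originates as an observed minimum
in manual curation; it is exposed as a knob. Note that half-up rounding of
100·50/56 gives 89.3, not the sometimes-printed 89.2 (a truncation); the
package reports half-up values.

Core-set intersection matches families across two analyses by best
reciprocal protein identity ≥80% between representative proteins, and
reports `100 · shared/|set|` per side at one decimal.

## Feature scanners

- **Lipobox.** All (overlapping) matches of `[LVI][ASTVI][GAS]C` whose
  cysteine lies within residues 5–40 of the initiator Met — a typical
  signal-peptide span; the window is a knob because it changes genome-level
  prevalence counts. Cleavage index = motif start + 3.
- **Sequence typing.** Single-linkage components at ≥80% identity, labelled
  by descending size. 80% sits midway between the simulator's within-type
  (~95%) and between-type (~68%) integrase identities and well separates
  deeply diverged integrase classes; a threshold below the between-type
  identity merges everything (monotone in the threshold).
- **att sites.** The prophage is located in a lysogen by exact match of the
  phage's 200-nt terminal anchors; the integration core is the maximal
  identical run read simultaneously from the prophage start and from the
  position just past its end (site-specific recombination duplicates the
  core at attL and attR). Cores shorter than 8 nt, absent from the host, or
  ambiguous in it yield `host_locus = "unmapped"` with a diagnostic rather
  than an error. The host locus is the annotated gene overlapping (or within
  60 nt of) the attB position; cores of different length at the same locus
  get distinct motif classes, capturing 3-bp-extended core variants.
- **nut sites.** Ungapped sliding-window search of each query on both
  strands; the best (fewest-mismatch) hit is reported if within 30% of the
  query length, ties to the smallest position. Hits are stacked
  query-oriented into a PWM with pseudocount 0.01 per base count; information
  content per column is `2 + Σ_b p_b log2 p_b` bits.
- **Positional conservation.** Proteins are multiple-aligned with mafft
  (`--auto`); conservation is counted at 1-based alignment columns. For the
  gap-free simulated antiterminators alignment columns coincide with residue
  positions.
- **Mean pairwise identity** over all unordered pairs, half-up to two
  decimals, is used for repressor conservation. How a published
  "similarity" percentage was computed by any particular alignment viewer is
  generally not recoverable, so exact agreement with such figures on real
  data is not promised.
- The type→locus association is reported descriptively (a contingency table
  and a "mapping is a function" flag), not as a hypothesis test: with a
  dozen genomes an exact correspondence is the relevant observation.

## The synthetic family generator

The generator is the package's study population. Defaults are chosen once to
mirror the structure of a real temperate coliphage group at desk scale:

| parameter | default | rationale |
|---|---|---|
| population | 12 genomes; genera of 5/4/3 genomes; 7 species | small enough for seconds-scale analysis, rich enough for 3-genus/7-species recovery |
| genes per genome | ~35 (30 core families, 10 flexible, 6 unique) | compact phage genomes, genes ≈90% of sequence |
| gene length | 300–900 nt (flexible 300–600, unique 300–450) | accessory genes are short morons; keeps similarity bands tight |
| GC target | 0.46 | the compositional signature of the emulated group |
| within-species / within-genus / between-genus nt identity | 99 / 85 / 52 | keeps the *measured* similarity bands ≥2 points clear of the 95/70 thresholds (see below) |
| synonymous bias | 0.85 | proteins stay ≥~70% identical family-wide while nucleotides demarcate genera, as in real phage families |
| lipobox prevalence | 40/48 | prevalence of lipoprotein-positive genomes in the emulated group |
| arginine-21 prevalence | 45/48 | partially conserved ARM position |
| integrase types | 4 (Ia, Ib, II, III), ~68% between / ~95.5% within | below any genus-style threshold, far from the 80% typing threshold on both sides |
| nut sites | 3 (boxA 8 nt, spacer 8 nt, boxB 15 nt), spacer mutated at 0.25/genome | invariant boxes, variable spacers |
| repressor | ~96% mean pairwise aa identity | one immunity group ⇒ near-frozen repressor |

Evolution is substitution-only along a root → genus ancestor → species
ancestor → genome tree; per-branch rates are derived from the pairwise
identity targets by `p = 1 − sqrt(target)` composed along the path. Genes
evolve with a synonymous bias: 85% of substitutions are placed at third
codon positions as synonymous changes, the remainder anywhere with the
replacement base drawn from the GC-calibrated base distribution (never
creating a stop), so amino-acid divergence is ~5× slower than nucleotide
divergence and base composition is stationary. Intergenic spacers evolve by
the plain uniform-substitution primitive `mutate_to_identity`. Codons are
sampled from a stop-free codon distribution solved (by bisection) to hit the
genome GC target exactly in expectation.

Because the nucleotide aligner chains codon skeletons (see above), the
*measured* between-genus similarity at a planted 52% nucleotide identity
lands around 45–62 — safely below the 70% genus threshold — while a planted
62% would graze it. Planted within-species identity is 99% so that the
accessory-content penalty (unique genes appear in the denominator of the
similarity but never match) leaves same-species pairs at ~97, above the 95%
species threshold. Two deliberate structural choices protect these bands and
are design decisions of this package: flexible-gene complements are unions
of whole species (a random genome-level assignment would make conspecific
genomes differ by kilobases of content and push their similarity below the
species threshold), and integrase types are a species-level trait (so a
divergent integration module never sits inside a conspecific pair). Both
have natural biological readings — accessory content and integration sites
track close phylogeny — but they are stronger than what real data
guarantees.

Truth-record fidelity is absolute: every planted string (boxA/boxB, att
cores, lipobox tetrapeptide, host loci) is present verbatim at its recorded
coordinates, lysogens are exactly `host[..b] + core + interior + core +
host[b+|core|..]`, and excising the prophage plus one core copy restores the
host byte-for-byte. To keep recovery exact rather than merely likely, the
generator deterministically scrubs coincidences that would otherwise create
ambiguity: accidental lipobox matches in the 5–40 window anywhere in any
proteome, accidental att-core occurrences in host or phage, and single-base
coincidences at lysogen junctions that would extend the apparent core. The
planted conserved codons (arginine positions, lipobox, nut boxes, integrase
N-terminal 30 residues) are masked from mutation. The whole generator is a
pure function of the seed: substreams are derived per genome/stage by
hashing `(seed, label)`, and identical seeds give byte-identical outputs.
An optional spacer-indel mode exists via `indel_rate` but is off by default;
all identity oracles assume the indel-free default.

### What the simulator does not emulate

No recombination or mosaicism (real phage genomes exchange modules; the
synteny anchor would tolerate it but the identity bands would not be
tree-like), no tree-based substitution-model realism (no rate heterogeneity,
no transition/transversion bias), no codon-usage realism beyond GC, no gene
gain/loss along the tree (accessory content is assigned, not evolved), no
sequencing or annotation error, and intergenic spacers evolve freely (no
regulatory conservation except the planted nut sites) — downstream analyses
must not rely on spacer conservation. Passing the recovery tests therefore
shows the pipeline is correct under clean, substitution-only divergence with
exact annotations; it does not show robustness to mosaicism, indels or
annotation noise.

## Numerical and procedural conventions

- Coordinates are 0-based half-open everywhere; GFF3 (1-based inclusive) is
  converted at the parser boundary. Minus-strand CDS are translated from the
  reverse complement.
- GC content excludes N from the denominator; composition is reported both
  as a fraction and as a percentage to avoid the fraction/percent ambiguity
  that a value like "46 ± 0.003%" invites (the ±0.003 reads as the standard
  deviation of the *fraction*).
- Rounding of reported percentages is decimal half-up at the stated
  precision (two decimals for core/flexible percentages, one elsewhere).
- Tie-breaks are always deterministic: block selection by (matches, a_start,
  b_start); family matching by (identity, smaller rank); typing labels by
  (component size, smallest member id); nut hits by (mismatches, position,
  plus strand first); cluster names by smallest member id.
- Degenerate inputs: empty FASTA, all-N sequences, non-triplet CDS, internal
  stops, out-of-range gene coordinates and unknown genome ids raise named
  errors; a nut query with no hit within tolerance is absent from the result
  (not an error); an att core that cannot be mapped yields "unmapped" with a
  diagnostic note.
- The pipeline validates its configuration (e.g. species threshold ≥ genus
  threshold) before doing any work and tags stage failures with the stage
  name. Reports and artifacts contain no timestamps, so identical
  configurations reproduce identical bytes.

## Problem sizes

The shipped defaults — 12 genomes of ~22–24 kb with ~35 genes each, and a
24-genome two-family set for the VGC separation check — were chosen as the
smallest population on which every recovery question (3 genera, 7 species,
4 integrase types on 3 loci, prevalence subsets) is non-trivially posed. At
these sizes the full test suite runs in well under a minute and
`scripts/acceptance.py` in under half a minute on one CPU. All analyses
scale quadratically in the number of genomes (pairwise similarity) and in
the number of proteins (PC clustering, with the edit-distance prefilter
keeping the constant small).

## Known limitations

- Exact agreement with published similarity heatmaps produced by other
  tools is not expected: the underlying local-alignment engines and their
  parameters differ, and the PC-distance formulas of published clustering
  tools are not fully specified in print.
- The block aligner is ungapped; genomes with real indels fragment into more
  blocks and lose a little similarity relative to a gapped aligner. It is a
  deliberate match to the indel-free generator, not a general-purpose
  replacement for BLASTn.
- `intersect_core` assumes the two analyses annotate comparable proteins; at
  reference choices spanning deep divergence the 80% reciprocal-match
  threshold becomes the binding constraint.
- The att-site detector requires exact terminal anchors; assembly errors at
  prophage termini would need a relaxed (alignment-based) anchor step.
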