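"""Feature scanners: lipobox, typing, att sites, nut sites, conservation."""

import numpy as np
import pytest

from immikit.features import (
    NutHit,
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
from immikit.genome_io import AnnotatedGenome, GeneFeature, reverse_complement

from conftest import partition


def _one_gene_genome(gid: str, protein: str) -> AnnotatedGenome:
    L = 3 * (len(protein) + 1)
    return AnnotatedGenome(
        gid, "A" * (L + 20),
        genes=[GeneFeature(0, 10, 10 + L, "+", "x", protein)],
    )


class TestLipobox:
    def test_hit_on_signal_peptide(self):
        g = _one_gene_genome("g", "MKKLLLAGCSSKAAAAAAAA")
        hits = scan_lipobox(g)
        assert len(hits) == 1
        h = hits[0]
        assert h.matched == "LAGC"
        assert h.cleavage_index == h.position + 3
        assert g.genes[0].protein[h.cleavage_index] == "C"

    def test_no_hit_without_motif(self):
        assert scan_lipobox(_one_gene_genome("g", "MAAAAAAAAAA")) == []

    def test_window_excludes_late_cysteines(self):
        prot = "M" + "A" * 60 + "LAGC" + "A" * 10  # C at residue 64
        assert scan_lipobox(_one_gene_genome("g", prot)) == []
        assert scan_lipobox(_one_gene_genome("g", prot), window=(5, 80))

    def test_reported_hits_rematch_pattern(self, family):
        import re

        pat = re.compile(r"[LVI][ASTVI][GAS]C")
        for g in family.genomes:
            for h in scan_lipobox(g):
                assert pat.fullmatch(h.matched)

    def test_planted_subset_recovered_exactly(self, family):
        t = family.truth
        positive = sorted(g.id for g in family.genomes if genome_has_lipoprotein(g))
        assert positive == t.lipoprotein_positive


class TestTyping:
    def test_identical_set_one_type(self):
        assert set(type_sequences({"a": "MKLV" * 20, "b": "MKLV" * 20}).values()) == {"T1"}

    def test_simulated_integrase_types_recovered(self, family):
        t = family.truth
        ints = {
            g.id: next(f.protein for f in g.genes if "integrase" in f.product)
            for g in family.genomes
        }
        types = type_sequences(ints)
        assert len(set(types.values())) == 4
        assert partition(types) == partition(t.integrase_types)

    def test_threshold_monotonicity(self, family):
        ints = {
            g.id: next(f.protein for f in g.genes if "integrase" in f.product)
            for g in family.genomes
        }
        low = type_sequences(ints, typing_identity=60.0)
        high = type_sequences(ints, typing_identity=80.0)
        assert len(set(low.values())) <= len(set(high.values()))
        assert len(set(low.values())) == 1  # below between-type identity: all merge

    def test_order_invariance(self, family):
        ints = {
            g.id: next(f.protein for f in g.genes if "integrase" in f.product)
            for g in family.genomes
        }
        reversed_input = dict(reversed(list(ints.items())))
        assert type_sequences(ints) == type_sequences(reversed_input)


class TestAssociation:
    def test_planted_association_is_perfect(self, family):
        t = family.truth
        table, perfect = associate_types_with_loci(t.integrase_types, t.att_assignments)
        assert perfect
        assert int(table.values.sum()) == t.n_genomes

    def test_single_relabel_breaks_function_property(self, family):
        t = family.truth
        loci = dict(t.att_assignments)
        gid = t.genome_ids[0]
        loci[gid] = "abgT" if loci[gid] != "abgT" else "mppA"
        _, perfect = associate_types_with_loci(t.integrase_types, loci)
        assert not perfect

    def test_trivial_one_by_one(self):
        table, perfect = associate_types_with_loci({"g": "T1"}, {"g": "ydaM"})
        assert perfect and table.shape == (1, 1)

    def test_disjoint_labelings_rejected(self):
        with pytest.raises(ValueError):
            associate_types_with_loci({"a": "T1"}, {"b": "ydaM"})


class TestAttSites:
    def test_planted_sites_recovered_exactly(self, family):
        t = family.truth
        for g, lys in zip(family.genomes, family.lysogens):
            site = detect_att(lys.sequence, family.host, g.sequence, phage_id=g.id)
            coords = t.att_site_coords[lys.id]
            assert list(site.attL) == coords["attL"]
            assert list(site.attR) == coords["attR"]
            assert site.core == t.att_cores[g.id]
            assert site.host_locus == t.att_assignments[g.id]

    def test_long_core_variant_gets_distinct_motif_class(self, family):
        """The 3-nt-extended core at the same host locus yields a different
        motif class (the Ia/Ib analogue)."""
        t = family.truth
        classes = {}
        for g, lys in zip(family.genomes, family.lysogens):
            site = detect_att(lys.sequence, family.host, g.sequence, phage_id=g.id)
            classes.setdefault(t.integrase_types[g.id], set()).add(site.motif_class)
        assert classes["Ia"] != classes["Ib"]
        assert all(len(v) == 1 for v in classes.values())

    def test_host_without_core_unmapped(self, family):
        g, lys = family.genomes[0], family.lysogens[0]
        scrambled = AnnotatedGenome(
            "host2",
            "".join(np.random.default_rng(0).choice(list("ACGT"), size=len(family.host.sequence))),
            genes=family.host.genes,
        )
        site = detect_att(lys.sequence, scrambled, g.sequence, phage_id=g.id)
        assert site.host_locus == "unmapped"
        assert site.motif_class == "unmapped"

    def test_missing_termini_raise(self, family):
        with pytest.raises(ValueError, match="anchor"):
            detect_att("ACGT" * 300, family.host, family.genomes[0].sequence)

    def test_excision_restores_host(self, family):
        for g, lys in zip(family.genomes[:4], family.lysogens[:4]):
            site = detect_att(lys.sequence, family.host, g.sequence, phage_id=g.id)
            excised = lys.sequence[: site.attL[0]] + lys.sequence[site.attR[0] :]
            assert excised == family.host.sequence


def _queries_from_truth(result):
    ref_id = result.truth.reference_id
    ref = next(g for g in result.genomes if g.id == ref_id)
    queries = []
    for rec in result.truth.nut_sites[ref_id]:
        queries.append(
            NutQuery(
                rec["name"],
                ref.sequence[rec["start"] : rec["end"]],
                (rec["boxA"][0] - rec["start"], rec["boxA"][1] - rec["start"]),
                (rec["boxB"][0] - rec["start"], rec["boxB"][1] - rec["start"]),
            )
        )
    return queries


class TestNutScan:
    def test_verbatim_query_zero_mismatch(self, family):
        ref = family.genomes[0]
        queries = _queries_from_truth(family)
        hits = scan_nut(ref, queries)
        for q in queries:
            assert hits[q.name].mismatches == 0
            assert hits[q.name].strand == "+"

    def test_hits_found_at_planted_coordinates_family_wide(self, family):
        queries = _queries_from_truth(family)
        for g in family.genomes:
            hits = scan_nut(g, queries)
            for rec in family.truth.nut_sites[g.id]:
                assert hits[rec["name"]].position == rec["start"]

    def test_minus_strand_hit_found(self, family):
        queries = _queries_from_truth(family)
        g = family.genomes[1]
        flipped = AnnotatedGenome(g.id, reverse_complement(g.sequence))
        fwd = scan_nut(g, queries)
        rev = scan_nut(flipped, queries)
        for q in queries:
            assert rev[q.name].strand == "-"
            assert rev[q.name].mismatches == fwd[q.name].mismatches
            assert rev[q.name].matched == fwd[q.name].matched

    def test_no_hit_beyond_tolerance(self):
        genome = AnnotatedGenome("g", "A" * 500)
        q = NutQuery("q", "CGCTCTTAGGGGCCCC", (0, 8), (8, 16))
        assert scan_nut(genome, [q]) == {}


class TestNutProfile:
    def test_ic_against_frequency_count_oracle(self):
        """PWM information content equals the closed-form computed directly
        from base frequencies, to 1e-9."""
        seqs = ["ACGTAC", "ACGTAA", "ACGAAC", "ACGTAC"]
        hits = [NutHit("s", f"g{i}", 0, "+", 0, s) for i, s in enumerate(seqs)]
        prof = build_nut_profile("s", hits)
        n = len(seqs)
        for col in range(6):
            probs = []
            for b in "ACGT":
                count = sum(1 for s in seqs if s[col] == b)
                probs.append((count + 0.01) / (n + 0.04))
            expected = 2.0 + sum(p * np.log2(p) for p in probs)
            assert abs(prof.information_content[col] - expected) < 1e-9

    def test_uniform_column_zero_bits(self):
        hits = [NutHit("s", f"g{i}", 0, "+", 0, b) for i, b in enumerate("ACGT")]
        prof = build_nut_profile("s", hits)
        assert prof.information_content[0] == pytest.approx(0.0, abs=1e-6)

    def test_invariant_boxes_near_two_bits_spacers_lower(self, family):
        queries = _queries_from_truth(family)
        per_site = {q.name: [] for q in queries}
        for g in family.genomes:
            for name, h in scan_nut(g, queries).items():
                per_site[name].append(h)
        for q in queries:
            prof = build_nut_profile(q.name, per_site[q.name], q.boxA, q.boxB)
            ic = prof.information_content
            box_cols = list(range(*q.boxA)) + list(range(*q.boxB))
            spacer_cols = [i for i in range(len(ic)) if i not in box_cols]
            assert min(ic[box_cols]) > 1.9
            assert np.mean(ic[spacer_cols]) < min(ic[box_cols]) - 0.3

    def test_ic_decreases_with_mutation_rate(self):
        """Frequency-count oracle: stacking columns with increasing planted
        per-column mutation counts yields strictly decreasing IC."""
        n = 40
        ics = []
        for n_mut in (0, 9, 18, 30):
            col = ["A"] * (n - n_mut) + [("CGT")[i % 3] for i in range(n_mut)]
            hits = [NutHit("s", f"g{i}", 0, "+", 0, b) for i, b in enumerate(col)]
            ics.append(build_nut_profile("s", hits).information_content[0])
        assert all(a > b for a, b in zip(ics, ics[1:]))

    def test_rows_sum_to_one(self, family):
        queries = _queries_from_truth(family)
        hits = [scan_nut(g, queries)["nutL"] for g in family.genomes]
        prof = build_nut_profile("nutL", hits)
        assert np.allclose(prof.pwm.sum(axis=1), 1.0)


class TestConservation:
    def test_identical_set_full_count(self):
        aligned = {f"g{i}": "MRRAR" for i in range(7)}
        assert positional_conservation(aligned, [2, 3], "R") == {2: 7, 3: 7}

    def test_absent_residue_zero(self):
        aligned = {"a": "MAAA", "b": "MAAA"}
        assert positional_conservation(aligned, [2], "W") == {2: 0}

    def test_position_beyond_alignment_rejected(self):
        with pytest.raises(ValueError):
            positional_conservation({"a": "MA"}, [5], "R")

    def test_simulated_arginine_conservation(self, family):
        t = family.truth
        antiterms = {
            g.id: next(f.protein for f in g.genes if "antiterminator" in f.product)
            for g in family.genomes
        }
        aligned = align_proteins(antiterms)
        counts = positional_conservation(
            aligned, t.arg_positions + [t.arg21_position], "R"
        )
        for pos in t.arg_positions:
            assert counts[pos] == t.n_genomes
        assert counts[t.arg21_position] == len(t.arg21_genomes)


class TestMeanPairwiseIdentity:
    def test_identical_set(self):
        assert mean_pairwise_identity(["MKLV"] * 4 ) == 100.00

    def test_arithmetic_mean_oracle(self):
        s1 = "MKLVAGHEDT"
        s2 = "MKLVAGHEDA"  # 90 vs s1
        s3 = "MKLVAGHEWW"  # 80 vs s1, 70 vs s2... constructed below
        from immikit.alignment import protein_identity

        vals = [protein_identity(a, b) for a, b in ((s1, s2), (s1, s3), (s2, s3))]
        expected = round(sum(vals) / 3, 2)
        assert mean_pairwise_identity([s1, s2, s3]) == pytest.approx(expected, abs=0.01)

    def test_simulated_repressors_near_planted_conservation(self, family):
        reps = [
            next(f.protein for f in g.genes if "repressor" in f.product)
            for g in family.genomes
        ]
        assert mean_pairwise_identity(reps) == pytest.approx(96.0, abs=1.0)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_identity(["MK"])
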