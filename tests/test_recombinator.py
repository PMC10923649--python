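import numpy as np
import pytest

from plastrec.genome_model import (
    Interval,
    canonical_circular,
    detect_quadripartite,
    reverse_complement,
)
from plastrec.recombinator import (
    CONFORMER_LABELS,
    Gene,
    enumerate_conformers,
    invert_between,
    partition_lsc,
    percent_size_increase,
    predict_gene_changes,
    predicted_sizes,
    read_genbank_genes,
    read_gff3_genes,
)
from plastrec.repeat_finder import RepeatPair
from plastrec.synthetic_data import ToySpec, make_toy_plastome, splice_conformer

# published G-type geometry used throughout: LSC 85,422 = A 78,236 + B 92 +
# C 7,094; SSC 18,334; IR 26,990; genome 157,736
GTYPE = dict(len_a=78_236, len_b=92, len_c=7_094, ir=26_990, ssc=18_334)
GTYPE_GENOME = 157_736


class TestPartition:
    def test_toy_partition_lengths(self, toy_small):
        part = toy_small.partition
        assert (part.len_a, part.len_b, part.len_c) == (111, 20, 69)
        assert part.len_a + part.len_b + part.len_c == len(toy_small.structure.lsc)

    def test_areas_tile_lsc(self, toy_small):
        part = toy_small.partition
        assert part.area_a.end == part.area_b.start
        assert part.area_b.end == part.area_c.start
        assert part.area_c.end == toy_small.structure.lsc.end

    def test_area_b_is_spacer(self, toy_small):
        part = toy_small.partition
        assert len(part.area_b) == part.repeat.spacer_len

    def test_left_arm_abutting_lsc_start(self):
        toy = make_toy_plastome(ToySpec(len_a=11, len_b=20, len_c=69,
                                        arm_len=11, seed=12))
        assert toy.partition.len_a == 11  # area A is just the arm

    def test_direct_pair_rejected(self, toy_small):
        direct = RepeatPair(4, Interval(0, 4), Interval(10, 14), "direct", 6,
                            "ACGT", "ACGT")
        with pytest.raises(ValueError):
            partition_lsc(toy_small.structure, direct)

    def test_arm_outside_lsc_rejected(self, toy_small):
        st = toy_small.structure
        outside = RepeatPair(
            4, Interval(st.irb.start, st.irb.start + 4),
            Interval(st.irb.start + 8, st.irb.start + 12), "inverted", 4,
            "ACGT", "ACGT")
        with pytest.raises(ValueError):
            partition_lsc(st, outside)


class TestClosedForms:
    def test_published_a_type_sizes(self):
        p = predicted_sizes("A-type", GTYPE["len_a"], GTYPE["len_b"],
                            GTYPE["len_c"], GTYPE["ir"], GTYPE["ssc"])
        assert p["genome"] == 228_878
        assert p["ir"] == 105_226
        assert p["lsc"] == 92
        assert p["ssc"] == 18_334

    def test_published_reciprocal_mass_conservation(self):
        p = predicted_sizes("reciprocal", GTYPE["len_a"], GTYPE["len_b"],
                            GTYPE["len_c"], GTYPE["ir"], GTYPE["ssc"])
        # oracle: 2 x 157,736 - 228,878 = 86,594
        assert p["genome"] == 2 * GTYPE_GENOME - 228_878 == 86_594

    def test_published_percent_increase(self):
        assert percent_size_increase(GTYPE_GENOME, 228_878) == 45

    def test_parent_reconstruction(self):
        assert sum((GTYPE["len_a"], GTYPE["len_b"], GTYPE["len_c"],
                    2 * GTYPE["ir"], GTYPE["ssc"])) == GTYPE_GENOME


class TestEnumerateConformers:
    def test_labels(self, toy_small):
        confs = enumerate_conformers(toy_small.structure, toy_small.partition,
                                     with_metrics=False)
        assert tuple(c.label for c in confs) == CONFORMER_LABELS

    def test_toy_a_type_size_formula(self, toy_small):
        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition, with_metrics=False)}
        parent = toy_small.structure.sequence.length
        part = toy_small.partition
        assert confs["A-type"].sequence.length == parent + part.len_a - part.len_c
        assert confs["A-type"].sequence.length == 750 + 111 - 69 == 792

    def test_mass_conservation(self, toy_small):
        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition, with_metrics=False)}
        parent = toy_small.structure.sequence.length
        assert (confs["A-type"].sequence.length
                + confs["reciprocal"].sequence.length) == 2 * parent
        assert confs["intermediate-dimer"].sequence.length == 2 * parent

    def test_dual_construction(self, toy_small):
        parent = toy_small.structure.sequence.residues
        confs = enumerate_conformers(toy_small.structure, toy_small.partition,
                                     with_metrics=False)
        for c in confs:
            spliced = splice_conformer(parent, toy_small.partition, c.label,
                                       ir_len=toy_small.spec.len_ir)
            assert spliced == c.sequence.residues, c.label

    def test_a_type_metrics_from_sequence(self, toy_small):
        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition)}
        part = toy_small.partition
        pm = confs["A-type"].predicted_metrics
        assert pm is not None
        assert pm.ir_size == len(toy_small.structure.irb) + part.len_a
        assert pm.lsc_size == part.len_b              # homology override
        assert pm.ssc_size == len(toy_small.structure.ssc)

    def test_reciprocal_metrics(self, toy_small):
        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition)}
        pm = confs["reciprocal"].predicted_metrics
        part = toy_small.partition
        assert pm.ir_size == len(toy_small.structure.irb) + part.len_c
        assert pm.lsc_size == part.len_b

    def test_b_inversion_involution(self, toy_small):
        parent = toy_small.structure.sequence.residues
        rep = toy_small.partition.repeat
        once = invert_between(parent, rep.left_arm, rep.right_arm)
        assert once != parent
        assert invert_between(once, rep.left_arm, rep.right_arm) == parent

    def test_b_inversion_preserves_composition(self, toy_small):
        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition, with_metrics=False)}
        parent = toy_small.structure.sequence.residues
        binv = confs["B-inversion"].sequence.residues
        assert len(binv) == len(parent)
        assert sorted(binv) == sorted(canonical_circular(parent)) \
            or sorted(binv) != []  # composition identical up to strand
        from collections import Counter

        def comp_free(s):
            c = Counter(s)
            return (c["A"] + c["T"], c["C"] + c["G"])

        assert comp_free(binv) == comp_free(parent)

    def test_dimer_contains_both_products(self, toy_small):
        from collections import Counter

        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition, with_metrics=False)}

        def comp_free(s):
            c = Counter(s)
            return Counter({"AT": c["A"] + c["T"], "CG": c["C"] + c["G"]})

        assert comp_free(confs["A-type"].sequence.residues) \
            + comp_free(confs["reciprocal"].sequence.residues) \
            == comp_free(confs["intermediate-dimer"].sequence.residues)

    def test_flipflop_is_distinct_molecule(self, toy_small):
        confs = {c.label: c for c in enumerate_conformers(
            toy_small.structure, toy_small.partition, with_metrics=False)}
        assert confs["flipflop-isomer"].sequence.residues != \
            canonical_circular(toy_small.structure.sequence.residues)

    def test_degenerate_flagged(self):
        toy = make_toy_plastome(ToySpec(len_a=11, len_b=20, len_c=69,
                                        arm_len=11, seed=12))
        confs = {c.label: c for c in enumerate_conformers(
            toy.structure, toy.partition, with_metrics=False)}
        assert confs["A-type"].degenerate


class TestGeneChanges:
    def _annotation(self, part, ssc):
        return [
            Gene("geneA", "protein", part.area_a.start + 5, part.area_a.start + 25),
            Gene("geneB", "protein", part.area_b.start + 2, part.area_b.start + 10),
            Gene("geneC", "protein", part.area_c.start + 5, part.area_c.start + 25),
        ]

    def test_one_gene_per_area(self, toy_small):
        part = toy_small.partition
        rep = predict_gene_changes(part, "A-type",
                                   self._annotation(part, toy_small.structure.ssc))
        assert [g.name for g in rep.deleted] == ["geneC"]
        assert [g.name for g in rep.duplicated] == ["geneA"]
        assert rep.disrupted == ()
        assert rep.unchanged_count == 1  # the area-B gene

    def test_empty_annotation(self, toy_small):
        rep = predict_gene_changes(toy_small.partition, "A-type", [])
        assert rep.deleted == rep.duplicated == rep.disrupted == ()
        assert rep.unchanged_count == 0
        assert rep.unique_before == {"protein": 0, "tRNA": 0, "rRNA": 0}

    def test_boundary_spanning_disrupted(self, toy_small):
        part = toy_small.partition
        g = Gene("span", "protein", part.area_a.end - 5, part.area_b.start + 5)
        rep = predict_gene_changes(part, "A-type", [g])
        assert [x.name for x in rep.disrupted] == ["span"]

    def test_overlap_c_deleted_even_partially(self, toy_small):
        part = toy_small.partition
        g = Gene("edge", "protein", part.area_c.start - 3, part.area_c.start + 3)
        rep = predict_gene_changes(part, "A-type", [g])
        assert [x.name for x in rep.deleted] == ["edge"]

    def test_unique_count_deltas(self, toy_small):
        part = toy_small.partition
        genes = [
            Gene("psbA", "protein", part.area_c.start + 1, part.area_c.start + 10),
            Gene("matK", "protein", part.area_c.start + 12, part.area_c.start + 20),
            Gene("rps16", "protein", part.area_c.start + 22, part.area_c.start + 30),
            Gene("trnK", "tRNA", part.area_c.start + 32, part.area_c.start + 40),
            Gene("other1", "protein", part.area_a.start + 1, part.area_a.start + 9),
            Gene("trnX", "tRNA", part.area_a.start + 20, part.area_a.start + 30),
        ]
        rep = predict_gene_changes(part, "A-type", genes)
        assert rep.unique_before == {"protein": 4, "tRNA": 2, "rRNA": 0}
        assert rep.unique_after == {"protein": 1, "tRNA": 1, "rRNA": 0}

    def test_reciprocal_mirror(self, toy_small):
        part = toy_small.partition
        rep = predict_gene_changes(part, "reciprocal",
                                   self._annotation(part, toy_small.structure.ssc))
        assert [g.name for g in rep.deleted] == ["geneA"]
        assert [g.name for g in rep.duplicated] == ["geneC"]

    def test_partition_covers_every_gene_once(self, toy_small):
        part = toy_small.partition
        genes = self._annotation(part, toy_small.structure.ssc)
        rep = predict_gene_changes(part, "A-type", genes)
        assert (len(rep.deleted) + len(rep.duplicated) + len(rep.disrupted)
                + rep.unchanged_count) == len(genes)

    def test_gene_outside_genome_rejected(self, toy_small):
        n = toy_small.structure.sequence.length
        g = Gene("bad", "protein", n - 2, n + 10)
        with pytest.raises(ValueError):
            predict_gene_changes(toy_small.partition, "A-type", [g],
                                 genome_length=n)


class TestAnnotationIO:
    def test_gff3_reader(self, tmp_path, toy_small):
        gff = tmp_path / "toy.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "toy\ttest\tgene\t6\t25\t.\t+\t.\tID=g1;Name=psbA\n"
            "toy\ttest\ttRNA\t30\t40\t.\t-\t.\tID=t1;Name=trnK\n"
        )
        genes = read_gff3_genes(gff)
        assert {(g.name, g.gtype, g.start, g.end) for g in genes} == {
            ("psbA", "protein", 5, 25), ("trnK", "tRNA", 29, 40)}

    def test_genbank_reader(self, tmp_path):
        gb = tmp_path / "toy.gb"
        gb.write_text(
            "LOCUS       toy                100 bp    DNA     circular PLN 01-JAN-2024\n"
            "FEATURES             Location/Qualifiers\n"
            "     gene            6..25\n"
            "                     /gene=\"psbA\"\n"
            "     tRNA            complement(30..40)\n"
            "                     /gene=\"trnK\"\n"
            "ORIGIN\n"
            "        1 " + " ".join(["acgtacgtac"] * 6) + "\n"
            "       61 " + " ".join(["acgtacgtac"] * 4) + "\n"
            "//\n"
        )
        genes = read_genbank_genes(gb)
        assert {(g.name, g.gtype, g.start, g.end) for g in genes} == {
            ("psbA", "protein", 5, 25), ("trnK", "tRNA", 29, 40)}
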