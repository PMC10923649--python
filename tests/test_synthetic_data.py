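import numpy as np
import pytest

from plastrec.genome_model import detect_quadripartite, reverse_complement
from plastrec.recombinator import CONFORMER_LABELS, enumerate_conformers
from plastrec.repeat_finder import find_repeat_pairs
from plastrec.synthetic_data import (
    SimulatedReadSet,
    ToySpec,
    ToySpecError,
    make_toy_plastome,
    simulate_reads,
    splice_conformer,
    write_fastq_pair,
    write_truth_tsv,
)


class TestToySpec:
    def test_additivity(self):
        spec = ToySpec(len_a=111, len_b=20, len_c=69, arm_len=11,
                       len_ssc=150, len_ir=200, gc=0.375, seed=5)
        assert spec.genome_size == 111 + 20 + 69 + 150 + 2 * 200 == 750

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ToySpec(arm_len=3)
        with pytest.raises(ValueError):
            ToySpec(len_a=5, arm_len=11)
        with pytest.raises(ValueError):
            ToySpec(len_ir=10)
        with pytest.raises(ValueError):
            ToySpec(gc=0.0)


class TestMakeToyPlastome:
    def test_genome_size(self, toy_small):
        assert toy_small.structure.sequence.length == 750

    def test_detection_recovers_recipe(self, toy_small):
        st = detect_quadripartite(toy_small.structure.sequence.residues,
                                  min_ir_len=50)
        spec = toy_small.spec
        assert [len(st.region(r)) for r in ("lsc", "irb", "ssc", "ira")] == \
            [spec.len_lsc, spec.len_ir, spec.len_ssc, spec.len_ir]

    def test_exactly_one_inverted_pair(self, toy_small):
        spec = toy_small.spec
        lsc = toy_small.structure.region_seq("lsc")
        pairs = find_repeat_pairs(lsc, min_arm=spec.arm_len, max_arm=len(lsc),
                                  min_spacer=0, max_spacer=len(lsc),
                                  orientation="inverted")
        assert len(pairs) == 1
        assert pairs[0].arm_len == spec.arm_len
        assert pairs[0].spacer_len == spec.len_b

    def test_planted_right_arm_is_revcomp(self, toy_small):
        rep = toy_small.repeat
        assert rep.right_seq == reverse_complement(rep.left_seq)

    def test_same_seed_byte_identical(self):
        a = make_toy_plastome(ToySpec(seed=5))
        b = make_toy_plastome(ToySpec(seed=5))
        assert a.structure.sequence.residues == b.structure.sequence.residues

    def test_different_seed_differs(self):
        a = make_toy_plastome(ToySpec(seed=5))
        b = make_toy_plastome(ToySpec(seed=6))
        assert a.structure.sequence.residues != b.structure.sequence.residues

    def test_explicit_arm_seq(self):
        toy = make_toy_plastome(ToySpec(arm_seq="TTTTTTTTTTC", seed=20))
        assert toy.repeat.left_seq == "TTTTTTTTTTC"
        assert toy.repeat.right_seq == "GAAAAAAAAAA"

    def test_gene_placement(self):
        spec = ToySpec(len_a=200, len_b=30, len_c=150, len_ssc=200, seed=30,
                       genes=(("gA", "A", "protein"), ("gC", "C", "protein"),
                              ("tS", "SSC", "tRNA"), ("rI", "IR", "rRNA")))
        toy = make_toy_plastome(spec)
        names = [g.name for g in toy.annotation]
        assert names.count("rI") == 2  # mirrored into both IR copies
        by_name = {g.name: g for g in toy.annotation}
        part = toy.partition
        assert part.area_a.contains(by_name["gA"].interval)
        assert part.area_c.contains(by_name["gC"].interval)
        assert toy.structure.ssc.contains(by_name["tS"].interval)

    def test_impossible_spec_raises(self):
        # a 4-bp arm inside a nearly all-AT LSC cannot be unique
        with pytest.raises(ToySpecError):
            make_toy_plastome(ToySpec(len_a=30, len_b=10, len_c=30, arm_len=4,
                                      len_ssc=60, len_ir=50, gc=0.02, seed=1),
                              max_attempts=5)


class TestSpliceConformer:
    def test_a_type_closed_form(self, toy_small):
        parent = toy_small.structure.sequence.residues
        sp = splice_conformer(parent, toy_small.partition, "A-type",
                              ir_len=toy_small.spec.len_ir)
        assert len(sp) == 750 + 111 - 69 == 792

    def test_b_inversion_conserves_length_and_content(self, toy_small):
        from collections import Counter

        parent = toy_small.structure.sequence.residues
        sp = splice_conformer(parent, toy_small.partition, "B-inversion",
                              ir_len=toy_small.spec.len_ir)
        assert len(sp) == len(parent)
        c1, c2 = Counter(sp), Counter(parent)
        assert c1["A"] + c1["T"] == c2["A"] + c2["T"]
        assert c1["C"] + c1["G"] == c2["C"] + c2["G"]

    def test_dimer_doubles(self, toy_small):
        parent = toy_small.structure.sequence.residues
        sp = splice_conformer(parent, toy_small.partition,
                              "intermediate-dimer",
                              ir_len=toy_small.spec.len_ir)
        assert len(sp) == 2 * len(parent)

    def test_unknown_label_rejected(self, toy_small):
        with pytest.raises(ValueError):
            splice_conformer(toy_small.structure.sequence.residues,
                             toy_small.partition, "nonsense")

    def test_ir_len_inference_matches_explicit(self, toy_small):
        parent = toy_small.structure.sequence.residues
        for label in CONFORMER_LABELS:
            assert splice_conformer(parent, toy_small.partition, label) == \
                splice_conformer(parent, toy_small.partition, label,
                                 ir_len=toy_small.spec.len_ir)


class TestCrossImplementationOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_splice_equals_events(self, seed):
        rng = np.random.default_rng(seed + 100)
        spec = ToySpec(
            len_a=int(rng.integers(20, 200)),
            len_b=int(rng.integers(8, 60)),
            len_c=int(rng.integers(15, 150)),
            arm_len=int(rng.integers(8, 14)),
            len_ssc=int(rng.integers(60, 250)),
            len_ir=int(rng.integers(60, 250)),
            seed=seed,
        )
        toy = make_toy_plastome(spec)
        parent = toy.structure.sequence.residues
        confs = enumerate_conformers(toy.structure, toy.partition,
                                     with_metrics=False)
        for c in confs:
            assert splice_conformer(parent, toy.partition, c.label,
                                    ir_len=spec.len_ir) == c.sequence.residues


class TestSimulateReads:
    def test_pure_parent_exact_substrings(self, toy_small):
        parent = toy_small.structure.sequence.residues
        doubled = parent + parent
        rs = simulate_reads({"G-type": parent}, {"G-type": 1.0},
                            depth=30, error_rate=0.0, seed=1)
        for r in rs.reads:
            assert r.sequence in doubled or \
                reverse_complement(r.sequence) in doubled

    def test_same_seed_byte_identical(self, toy_small):
        parent = toy_small.structure.sequence.residues
        a = simulate_reads({"G-type": parent}, {"G-type": 1.0}, depth=10, seed=8)
        b = simulate_reads({"G-type": parent}, {"G-type": 1.0}, depth=10, seed=8)
        assert a.sequences() == b.sequences()
        assert [(r.read_id, r.origin, r.start_1based, r.strand)
                for r in a.reads] == \
            [(r.read_id, r.origin, r.start_1based, r.strand) for r in b.reads]

    def test_realized_depth_near_target(self, toy_mid):
        parent = toy_mid.structure.sequence.residues
        depth = 100
        rs = simulate_reads({"G-type": parent}, {"G-type": 1.0},
                            depth=depth, seed=8)
        realized = len(rs.reads) * rs.read_len / len(parent)
        # Poisson-style oracle on total coverage
        assert abs(realized - depth) <= 4 * np.sqrt(depth * rs.read_len / len(parent)) + 1

    def test_mixture_tag_fractions(self, toy_mid, toy_mid_atype):
        parent = toy_mid.structure.sequence.residues
        rs = simulate_reads({"G-type": parent, "A-type": toy_mid_atype},
                            {"G-type": 0.3, "A-type": 0.7},
                            depth=150, seed=9)
        counts = rs.origin_counts()
        total = sum(counts.values())
        # molecule proportions weighted by genome length (multinomial oracle)
        wg = 0.3 * len(parent)
        wa = 0.7 * len(toy_mid_atype)
        p = wa / (wg + wa)
        # 99.9% binomial bounds
        sd = np.sqrt(total * p * (1 - p))
        assert abs(counts["A-type"] - total * p) <= 3.3 * sd

    def test_error_rate_applied(self, toy_mid):
        parent = toy_mid.structure.sequence.residues
        doubled = parent + parent
        rs = simulate_reads({"G-type": parent}, {"G-type": 1.0},
                            depth=20, error_rate=0.05, seed=10)
        exact = sum(1 for r in rs.reads
                    if r.sequence in doubled
                    or reverse_complement(r.sequence) in doubled)
        assert exact < len(rs.reads)  # ~0.05*150 errors/read: most differ

    def test_read_longer_than_genome_rejected(self, toy_small):
        parent = toy_small.structure.sequence.residues
        with pytest.raises(ValueError):
            simulate_reads({"G-type": parent}, {"G-type": 1.0},
                           read_len=10_000, depth=1, seed=0)

    def test_mixture_must_sum_to_one(self, toy_small):
        parent = toy_small.structure.sequence.residues
        with pytest.raises(ValueError):
            simulate_reads({"G-type": parent}, {"G-type": 0.5}, depth=1, seed=0)

    def test_writers(self, tmp_path, toy_small):
        parent = toy_small.structure.sequence.residues
        rs = simulate_reads({"G-type": parent}, {"G-type": 1.0}, depth=5, seed=2)
        write_fastq_pair(rs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        write_truth_tsv(rs, tmp_path / "truth.tsv")
        r1 = (tmp_path / "r1.fq").read_text().splitlines()
        assert len(r1) % 4 == 0
        assert r1[0].startswith("@sim")
        truth = (tmp_path / "truth.tsv").read_text().splitlines()
        assert truth[0] == "read_id\torigin\tstart_1based\tstrand"
        assert len(truth) == len(rs.reads) + 1
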