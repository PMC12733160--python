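"""Parsing, quadripartite detection, CDS filters, structure and synteny."""

import pytest

from plastevo.genetics import revcomp
from plastevo.plastome_io import (
    NoQuadripartiteError,
    detect_quadripartite,
    extract_cds,
    gene_order_synteny,
    parse_plastome,
    region_stats,
    write_annotation_tsv,
    write_fasta,
    write_genbank,
)
from plastevo.records import GeneAnnotation, PlastomeRecord

MINI_GENBANK = """\
LOCUS       toy                       60 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  toy record.
FEATURES             Location/Qualifiers
     source          1..60
     CDS             join(3..8,13..18)
                     /gene="demoA"
     misc_feature    20..25
ORIGIN
        1 atggcatgca aaatgggcat gcaaaatggg catgcaaaat gggcatgcaa aatgggcatg
//
"""


class TestParsing:
    def test_genbank_two_exon_cds(self, tmp_path):
        """A join() CDS becomes one gene with 2 exons and 1 intron, in
        0-based half-open coordinates."""
        path = tmp_path / "toy.gb"
        path.write_text(MINI_GENBANK)
        record = parse_plastome(path)
        assert len(record.genes) == 1
        gene = record.genes[0]
        assert gene.name == "demoA"
        assert gene.exons == ((2, 8), (12, 18))
        assert gene.introns == ((8, 12),)
        assert len(record.sequence) == 60

    def test_fasta_without_annotation_has_no_genes(self, tmp_path):
        path = tmp_path / "toy.fasta"
        path.write_text(">sp1\nACGTACGTACGT\n")
        record = parse_plastome(path)
        assert record.genes == []
        assert record.species_id == "sp1"

    def test_genbank_round_trip_is_identity(self, small_sim, tmp_path):
        _, record, _ = small_sim
        path = tmp_path / "sim.gb"
        write_genbank(record, path)
        again = parse_plastome(path, species_id=record.species_id)
        assert again.canonical() == record.canonical()

    def test_fasta_tsv_round_trip_is_identity(self, small_sim, tmp_path):
        _, record, _ = small_sim
        write_fasta(record, tmp_path / "sim.fasta")
        write_annotation_tsv(record, tmp_path / "sim.tsv")
        again = parse_plastome(
            tmp_path / "sim.fasta", annotation=tmp_path / "sim.tsv"
        )
        assert again.canonical() == record.canonical()

    def test_missing_file_raises_parse_error(self, tmp_path):
        with pytest.raises(ValueError, match="no such file"):
            parse_plastome(tmp_path / "absent.gb")


def _toy_circle(rng, ir=100, lsc=700, ssc=100):
    """Random circle with one planted inverted-repeat pair."""
    def rand(n):
        return "".join(rng.choice(list("ACGT"), n))

    while True:
        p = rand(ir)
        seq = rand(lsc) + p + rand(ssc) + revcomp(p)
        rec = PlastomeRecord("toy", seq)
        try:
            b = detect_quadripartite(rec, min_ir=ir // 2)
        except ValueError:
            continue
        if b.lengths() == {"lsc": lsc, "irb": ir, "ssc": ssc, "ira": ir}:
            return rec, b


class TestQuadripartite:
    def test_planted_toy_circle(self, rng):
        rec, b = _toy_circle(rng)
        assert b.lengths() == {"lsc": 700, "irb": 100, "ssc": 100, "ira": 100}

    def test_partition_and_ir_symmetry(self, small_sim):
        _, record, truth = small_sim
        b = detect_quadripartite(record, min_ir=500)
        assert b.lengths() == truth["boundaries"]
        assert sum(b.lengths().values()) == len(record)
        assert revcomp(b.ira.extract(record.sequence)) == b.irb.extract(
            record.sequence
        )

    def test_rotation_and_revcomp_invariance(self, small_sim):
        _, record, _ = small_sim
        ref = detect_quadripartite(record, min_ir=500).lengths()
        for shift in (1, 137, len(record) // 2):
            rotated = PlastomeRecord(
                "rot", record.sequence[shift:] + record.sequence[:shift]
            )
            assert detect_quadripartite(rotated, min_ir=500).lengths() == ref
        flipped = PlastomeRecord("rc", revcomp(record.sequence))
        assert detect_quadripartite(flipped, min_ir=500).lengths() == ref

    def test_no_repeat_raises(self, rng):
        seq = "".join(rng.choice(list("AC"), 2000))  # no G/T: no revcomp match
        with pytest.raises(NoQuadripartiteError):
            detect_quadripartite(PlastomeRecord("flat", seq), min_ir=100)


class TestExtractCds:
    def _record(self, seq, genes):
        return PlastomeRecord("sp", seq, genes)

    def test_length_not_multiple_of_three_rejected(self):
        seq = "ATG" + "GCT" * 99 + "GA" + "TTTT"
        rec = self._record(
            seq, [GeneAnnotation("bad", "CDS", "+", ((0, 301),))]
        )
        genes, rejections = extract_cds(rec)
        assert genes == []
        assert rejections[0].reason == "length not multiple of 3"

    def test_minus_strand_is_reverse_complemented(self):
        rec = self._record(
            "TTACATCCC", [GeneAnnotation("neg", "CDS", "-", ((0, 6),))]
        )
        genes, _ = extract_cds(rec)
        assert genes[0].cds == "ATGTAA"

    def test_internal_stop_rejected(self):
        cds = "ATG" + "GCT" * 3 + "TAA" + "GCT" * 4 + "TAA"
        rec = self._record(cds, [GeneAnnotation("stopper", "CDS", "+", ((0, len(cds)),))])
        genes, rejections = extract_cds(rec)
        assert genes == []
        assert rejections[0].reason == "internal stop"

    def test_ir_duplicates_keep_lower_start_copy(self):
        cds = "ATGGCTTAA"
        seq = cds + "C" * 10 + revcomp(cds)
        rec = self._record(
            seq,
            [
                GeneAnnotation("dup", "CDS", "+", ((0, 9),)),
                GeneAnnotation("dup", "CDS", "-", ((19, 28),)),
            ],
        )
        genes, rejections = extract_cds(rec)
        assert len(genes) == 1 and not rejections
        assert genes[0].cds == cds

    def test_simulated_genes_all_pass_filters(self, small_sim):
        _, record, truth = small_sim
        genes, rejections = extract_cds(record)
        assert rejections == []
        assert {g.gene_name for g in genes} == {
            g["name"] for g in truth["genes"]
        }


class TestRegionStats:
    def test_all_at_genome_has_zero_gc(self):
        rec = PlastomeRecord("at", "ATATATAT" * 10)
        assert region_stats(rec)["gc_percent"] == 0.0

    def test_gc_is_sum_of_g_and_c_shares(self):
        seq = "A" * 3115 + "T" * 3194 + "C" * 1869 + "G" * 1822
        stats = region_stats(PlastomeRecord("comp", seq))
        assert stats["gc_percent"] == pytest.approx(36.91, abs=1e-9)

    def test_region_lengths_partition_genome(self, small_sim):
        _, record, _ = small_sim
        rec = record.with_boundaries(detect_quadripartite(record, min_ir=500))
        stats = region_stats(rec)
        assert (
            stats["lsc_len"] + stats["ssc_len"] + 2 * stats["ir_len"]
            == stats["length"]
        )


def _linear_record(names_strands):
    """Equal-size dummy genes laid along a sequence, in the given order."""
    genes = []
    pos = 0
    for name, strand in names_strands:
        genes.append(GeneAnnotation(name, "CDS", strand, ((pos, pos + 10),)))
        pos += 15
    return PlastomeRecord("x", "A" * pos, genes)


def _breakpoint_oracle(order_a, order_b):
    """Brute-force signed breakpoint count: adjacencies of a absent from
    b in both orientations."""
    adj_b = set()
    for x, y in zip(order_b, order_b[1:]):
        adj_b.add((x, y))
        adj_b.add(((y[0], "-" if y[1] == "+" else "+"), (x[0], "-" if x[1] == "+" else "+")))
    return sum(
        1 for x, y in zip(order_a, order_a[1:]) if (x, y) not in adj_b
    )


class TestSynteny:
    def test_identical_orders_one_block(self):
        order = [(f"g{i}", "+") for i in range(10)]
        a, b = _linear_record(order), _linear_record(order)
        rep = gene_order_synteny(a, b)
        assert rep["n_blocks"] == 1
        assert rep["breakpoints"] == 0
        assert rep["collinear_fraction"] == 1.0

    def test_internal_inversion_three_blocks_two_breakpoints(self):
        order_a = [(f"g{i}", "+") for i in range(10)]
        inverted = [(name, "-") for name, _ in reversed(order_a[3:7])]
        order_b = order_a[:3] + inverted + order_a[7:]
        rep = gene_order_synteny(_linear_record(order_a), _linear_record(order_b))
        assert rep["n_blocks"] == 3
        assert rep["breakpoints"] == 2
        assert rep["breakpoints"] == _breakpoint_oracle(order_a, order_b)

    def test_disjoint_gene_sets_raise(self):
        a = _linear_record([("g1", "+"), ("g2", "+")])
        b = _linear_record([("h1", "+"), ("h2", "+")])
        with pytest.raises(ValueError, match="insufficient shared annotation"):
            gene_order_synteny(a, b)
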