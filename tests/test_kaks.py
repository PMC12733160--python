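"""Codon alignment, NG86 counting and selection-category statistics."""

import itertools
import math

import pytest

from plastevo.genetics import CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from plastevo.kaks import (
    CodonAlignment,
    KaKsPair,
    SYN_SITES,
    align_proteins,
    all_pairs,
    classify_ratio,
    codon_align,
    ng86,
    selection_summary,
    _pathway_counts,
)
from plastevo.records import GeneSequence


def _gap_score(g):
    return -5 - g


def brute_force_alignment_score(a, b):
    """Exhaustive enumeration of global alignments (affine gaps scored
    open -5, extend -1 per residue)."""
    best = -(10**9)
    stack = [(0, 0, 0, None)]  # i, j, score, last_move

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = 1 if a[i] == b[j] else -1
            rec(i + 1, j + 1, score + s, "d")
        if i < len(a):
            extra = -1 if last == "u" else -6
            rec(i + 1, j, score + extra, "u")
        if j < len(b):
            extra = -1 if last == "l" else -6
            rec(i, j + 1, score + extra, "l")

    rec(0, 0, 0, None)
    return best


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        a = GeneSequence("s1", "g", "ATGGCTAAACCTTAA")
        b = GeneSequence("s2", "g", "ATGGCTAAACCTTAA")
        aln = codon_align(a, b)
        assert all(c1 == c2 for c1, c2 in aln.codon_columns)
        assert len(aln) == 4  # terminal stop stripped

    def test_single_codon_deletion_is_trimmed(self):
        a = GeneSequence("s1", "g", "ATGGCTGCTAAATAA")
        b = GeneSequence("s2", "g", "ATGGCTAAATAA")
        aln = codon_align(a, b)
        assert len(aln) == 3
        assert all(c1 == c2 for c1, c2 in aln.codon_columns)

    def test_optimal_score_matches_exhaustive_enumeration(self, rng):
        alphabet = list("ACDEFGHIKL")
        for _ in range(15):
            p1 = "".join(rng.choice(alphabet, rng.integers(2, 8)))
            p2 = "".join(rng.choice(alphabet, rng.integers(2, 8)))
            _, _, score = align_proteins(p1, p2)
            assert score == brute_force_alignment_score(p1, p2)

    def test_mismatched_gene_names_raise(self):
        with pytest.raises(ValueError):
            codon_align(
                GeneSequence("a", "g1", "ATGTAA"), GeneSequence("b", "g2", "ATGTAA")
            )


def brute_force_pathways(c1, c2):
    """Independent pathway enumerator over orderings of differing sites."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, legal = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                legal = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if legal:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNG86:
    def test_identical_sequences_undefined_ratio(self):
        cds = "ATGGCTGCTTAA"
        aln = codon_align(
            GeneSequence("a", "g", cds), GeneSequence("b", "g", cds)
        )
        pair = ng86(aln)
        assert pair.ka == 0.0 and pair.ks == 0.0
        assert pair.ratio is None
        assert pair.selection == "undefined"

    def test_single_synonymous_difference_hand_derived(self):
        # 11 codons: ATG + 9x GCT + GCA vs ATG + 10x GCT.
        # Ala is fourfold (1 synonymous site per codon), ATG contributes
        # none: S = 10, Sd = 1, pS = 0.1, Ks = -(3/4) ln(1 - 0.4/3).
        a = GeneSequence("a", "g", "ATG" + "GCT" * 9 + "GCA")
        b = GeneSequence("b", "g", "ATG" + "GCT" * 10)
        pair = ng86(codon_align(a, b))
        assert pair.ka == 0.0
        assert pair.ks == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-12)
        assert pair.ratio == 0.0

    def test_pathway_averaging_matches_enumeration_oracle(self):
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                assert _pathway_counts(c1, c2) == brute_force_pathways(c1, c2)

    def test_site_counts_sum_to_three_per_codon(self, rng):
        codons = rng.choice(list(SENSE_CODONS), 40)
        aln = CodonAlignment(("a", "b"), "g", tuple(zip(codons, codons)))
        S = sum(SYN_SITES[c] for c in codons)
        assert S + (3 * len(codons) - S) == pytest.approx(3 * len(codons))
        for c in SENSE_CODONS:
            assert 0.0 <= SYN_SITES[c] <= 3.0

    def test_symmetry_in_sequence_order(self, rng):
        codons1 = rng.choice(list(SENSE_CODONS), 60)
        codons2 = [
            c if rng.random() < 0.8 else rng.choice(list(SENSE_CODONS))
            for c in codons1
        ]
        fwd = ng86(CodonAlignment(("a", "b"), "g", tuple(zip(codons1, codons2))))
        rev = ng86(CodonAlignment(("b", "a"), "g", tuple(zip(codons2, codons1))))
        assert fwd.ka == pytest.approx(rev.ka, abs=1e-14)
        assert fwd.ks == pytest.approx(rev.ks, abs=1e-14)


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.2, "strong purifying"),
            (0.5, "relaxed purifying"),
            (1.0, "relaxed purifying"),
            (1.5, "positive"),
            (None, "undefined"),
        ],
    )
    def test_threshold_boundaries(self, ratio, expected):
        assert classify_ratio(ratio) == expected


def _pair(gene, ratio, category, ka=0.01):
    ks = ka / ratio if ratio else 0.05
    return KaKsPair(
        gene_name=gene,
        species_pair=("a", "b"),
        ka=ka,
        ks=ks,
        ratio=ratio,
        selection=classify_ratio(ratio),
        category=category,
    )


class TestSelectionSummary:
    def test_constant_ratios_give_pure_class_and_zero_effect_size(self):
        pairs = [_pair(f"g{i}", 0.3, "photosystem I") for i in range(5)]
        pairs += [_pair(f"h{i}", 0.3, "photosystem II") for i in range(5)]
        summary = selection_summary(pairs)
        assert summary.class_fractions["strong purifying"] == 1.0
        assert summary.pairwise_tests.iloc[0]["cohens_d"] == 0.0

    def test_outliers_removed_before_statistics(self):
        pairs = [_pair(f"g{i}", 0.4, "other") for i in range(4)]
        pairs.append(_pair("g_out", 25.0, "other"))
        summary = selection_summary(pairs, max_ratio=10.0)
        assert summary.n_outliers_removed == 1
        assert summary.category_stats.loc["other", "mean_ratio"] == pytest.approx(0.4)

    def test_small_category_flagged_and_skipped(self):
        pairs = [_pair(f"g{i}", 0.3, "ATP synthase") for i in range(4)]
        pairs.append(_pair("solo", 0.8, "RNA polymerase"))
        summary = selection_summary(pairs)
        assert any("RNA polymerase" in f for f in summary.flags)
        assert (summary.category_tests["category"] == "ATP synthase").all()

    def test_bonferroni_never_exceeds_one(self, rng):
        cats = ["photosystem I", "photosystem II", "ATP synthase"]
        pairs = [
            _pair(f"g{i}", float(rng.uniform(0.1, 1.5)), cats[i % 3])
            for i in range(30)
        ]
        summary = selection_summary(pairs)
        assert (summary.category_tests["p_bonferroni"] <= 1.0).all()
        assert (summary.pairwise_tests["p_bonferroni"] <= 1.0).all()


class TestAllPairs:
    def test_all_unordered_pairs_per_gene(self):
        cds = "ATGGCTGCTAAACCTTAA"
        genes = {
            sp: [GeneSequence(sp, "g1", cds), GeneSequence(sp, "g2", cds)]
            for sp in ("s1", "s2", "s3")
        }
        pairs = all_pairs(genes)
        assert len(pairs) == 6  # 2 genes x C(3,2)
        assert {p.gene_name for p in pairs} == {"g1", "g2"}
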