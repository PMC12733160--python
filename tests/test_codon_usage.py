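"""RSCU, ENC, positional GC, PR2 and the neutrality regression."""

import numpy as np
import pytest

from plastevo.codon_usage import (
    CodonProfile,
    codon_counts,
    enc,
    expected_enc,
    merge_profiles,
    neutrality_fit,
    positional_gc,
    pr2_indices,
    preferred_codon_summary,
    rscu,
)
from plastevo.genetics import FAMILIES, FOURFOLD_CODONS, SENSE_CODONS


def one_codon_per_family_cds(copies=10):
    return "".join(codons[0] * copies for _, codons in sorted(FAMILIES.items()))


def uniform_usage_cds(copies=100):
    return "".join(c * copies for c in SENSE_CODONS)


class TestCounts:
    def test_two_codon_gene_counts_stop_apart(self):
        p = codon_counts("ATGTAA")
        assert p.counts == {"ATG": 1}
        assert p.stop_counts == {"TAA": 1}

    def test_repeated_codon(self):
        p = codon_counts("GCT" * 100)
        assert p.counts == {"GCT": 100}

    def test_counts_are_additive_over_genes(self, rng):
        genes = [
            "".join(rng.choice(list(SENSE_CODONS), rng.integers(5, 40)))
            for _ in range(6)
        ]
        merged = merge_profiles(codon_counts(g) for g in genes)
        assert merged.counts == codon_counts("".join(genes)).counts

    def test_ambiguous_codons_skipped(self):
        p = codon_counts("ATGNNNGCT")
        assert p.skipped_codons == 1
        assert p.counts == {"ATG": 1, "GCT": 1}


class TestRSCU:
    def test_uniform_usage_gives_all_ones(self):
        values = rscu(codon_counts(uniform_usage_cds()))
        assert len(values) == 59
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_sixfold_family_concentrated_on_one_codon(self):
        values = rscu(codon_counts("TTA" * 30))
        assert values["TTA"] == pytest.approx(6.0)
        for codon in ("TTG", "CTA", "CTC", "CTG", "CTT"):
            assert values[codon] == 0.0

    def test_family_means_equal_one(self, rng):
        counts = {c: int(rng.integers(0, 50)) for c in SENSE_CODONS}
        values = rscu(CodonProfile(counts=counts))
        for aa, codons in FAMILIES.items():
            if len(codons) == 1 or sum(counts[c] for c in codons) == 0:
                continue
            mean = np.mean([values[c] for c in codons])
            assert mean == pytest.approx(1.0, abs=1e-12)

    def test_preferred_codon_tally(self):
        # 29 preferred codons: 16 ending in T, 12 in A, 1 in G
        table = {}
        t_enders = [c for c in SENSE_CODONS if c[2] == "T"][:16]
        a_enders = [c for c in SENSE_CODONS if c[2] == "A"][:12]
        g_enders = [c for c in SENSE_CODONS if c[2] == "G"][:1]
        for c in t_enders + a_enders + g_enders:
            table[c] = 1.5
        for c in SENSE_CODONS:
            table.setdefault(c, 0.5)
        summary = preferred_codon_summary(table)
        assert summary["n_preferred"] == 29
        assert summary["at_share_percent"] == pytest.approx(96.55, abs=0.005)


def _wright_oracle(family_counts):
    """Independent spreadsheet-style evaluation of Wright's estimator."""
    from fractions import Fraction

    per_size = {2: [], 3: [], 4: [], 6: []}
    for counts in family_counts:
        n = sum(counts)
        f = (n * sum(Fraction(x, n) ** 2 for x in counts) - 1) / (n - 1)
        per_size[len(counts)].append(f)
    fbar = {k: sum(v) / len(v) for k, v in per_size.items() if v}
    return float(
        2 + Fraction(9) / fbar[2] + Fraction(1) / fbar[3]
        + Fraction(5) / fbar[4] + Fraction(3) / fbar[6]
    )


class TestENC:
    def test_maximum_bias_is_twenty(self):
        assert enc(codon_counts(one_codon_per_family_cds())) == 20.0

    def test_no_bias_caps_at_sixty_one(self):
        assert enc(codon_counts(uniform_usage_cds())) == 61.0

    def test_matches_hand_evaluation_on_fixed_family_counts(self):
        # one family of each size with hand-chosen counts, 60 codons total
        spec = {
            "K": [7, 3],        # 2-fold (Lys: AAA, AAG)
            "I": [6, 3, 1],     # 3-fold (Ile)
            "A": [8, 5, 4, 3],  # 4-fold (Ala)
            "L": [6, 5, 4, 3, 1, 1],  # 6-fold (Leu)
        }
        counts = {}
        for aa, ns in spec.items():
            for codon, x in zip(FAMILIES[aa], ns):
                counts[codon] = x
        value = enc(CodonProfile(counts=counts))
        assert value == pytest.approx(_wright_oracle(list(spec.values())), abs=1e-10)

    def test_bounds_and_scale_invariance(self, rng):
        counts = {c: int(rng.integers(1, 30)) for c in SENSE_CODONS}
        assert 20.0 <= enc(CodonProfile(counts=counts)) <= 61.0
        # invariance under count rescaling holds in the large-n limit
        big = enc(CodonProfile(counts={c: 100 * v for c, v in counts.items()}))
        bigger = enc(CodonProfile(counts={c: 1000 * v for c, v in counts.items()}))
        assert bigger == pytest.approx(big, abs=0.1)

    def test_undefined_when_families_unobserved(self):
        assert enc(codon_counts("ATGTAA")) is None


class TestExpectedENC:
    @pytest.mark.parametrize(
        "s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)]
    )
    def test_closed_form(self, s, expected):
        assert expected_enc(s) == pytest.approx(expected)

    def test_symmetry_about_half_after_removing_linear_term(self):
        for s in np.linspace(0, 1, 21):
            assert expected_enc(s) - s == pytest.approx(
                expected_enc(1 - s) - (1 - s), abs=1e-12
            )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


class TestPositionalGC:
    def test_all_gly_is_fully_gc(self):
        gc = positional_gc("GGGGGGGGG")
        assert gc["gc1"] == gc["gc2"] == gc["gc3"] == gc["gc3s"] == 1.0

    def test_met_only_gene_has_no_synonymous_third_positions(self):
        gc = positional_gc("ATGATGATG")
        assert gc["gc3s"] is None
        assert any("gc3s" in f for f in gc["flags"])
        # Met codons end in G, so the plain third-position GC is 1
        assert gc["gc3"] == 1.0

    def test_gc12_is_mean_of_first_two_positions(self, rng):
        cds = "".join(rng.choice(list(SENSE_CODONS), 50))
        gc = positional_gc(cds)
        assert gc["gc12"] == pytest.approx((gc["gc1"] + gc["gc2"]) / 2)


class TestPR2:
    def test_balanced_composition_is_centered(self):
        # equal use of all fourfold-family codons balances A3/T3 and G3/C3
        profile = codon_counts("".join(c * 5 for c in FOURFOLD_CODONS))
        assert pr2_indices(profile) == (0.5, 0.5)

    def test_direct_ratio(self):
        # Gly codons: A3=3, T3=1, G3=2, C3=2
        profile = codon_counts("GGA" * 3 + "GGT" + "GGG" * 2 + "GGC" * 2)
        a3, g3 = pr2_indices(profile)
        assert a3 == pytest.approx(0.75)
        assert g3 == pytest.approx(0.5)

    def test_swapping_complements_reflects_both_coordinates(self, rng):
        swap = {"A": "T", "T": "A", "G": "C", "C": "G"}
        counts = {c: int(rng.integers(0, 20)) for c in FOURFOLD_CODONS}
        swapped = {c[:2] + swap[c[2]]: v for c, v in counts.items()}
        a3, g3 = pr2_indices(CodonProfile(counts=counts))
        a3s, g3s = pr2_indices(CodonProfile(counts=swapped))
        assert a3s == pytest.approx(1 - a3, abs=1e-12)
        assert g3s == pytest.approx(1 - g3, abs=1e-12)

    def test_zero_denominator_flagged_as_none(self):
        a3, g3 = pr2_indices(codon_counts("GGG" * 4 + "GGC" * 2))
        assert a3 is None
        assert g3 == pytest.approx(2 / 3)


class TestNeutrality:
    def test_identity_line(self):
        fit = neutrality_fit([(x, x) for x in (0.1, 0.2, 0.3, 0.4)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_gc12_gives_zero_slope(self):
        fit = neutrality_fit([(0.4, x) for x in (0.1, 0.2, 0.3)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            x = rng.random(20)
            y = 0.3 * x + 0.1 + rng.normal(0, 0.02, 20)
            fit = neutrality_fit(list(zip(y, x)))
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)
            resid = y - X @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_zero_gc3_variance_flagged(self):
        fit = neutrality_fit([(0.1, 0.2), (0.3, 0.2), (0.5, 0.2)])
        assert fit.slope is None
        assert fit.flags
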