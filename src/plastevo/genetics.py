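"""Genetic-code tables and codon family structure shared across the package.

Translation uses the bacterial/plastid code (NCBI translation table 11).
Its 61 sense codons translate identically to the standard code; only the
set of permitted initiation codons differs, which is irrelevant here
because coding sequences are handled as already-delimited reading frames.
"""

from __future__ import annotations

from Bio.Data import CodonTable

TABLE_ID = 11
_table = CodonTable.unambiguous_dna_by_id[TABLE_ID]

#: codon -> one-letter amino acid, 61 sense codons (DNA alphabet, upper case)
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

STOP_CODONS = frozenset(_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(seq: str) -> str:
    """Base-wise complement (no reversal)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _build_families() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in CODON_TO_AA.items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in fams.items()}


#: amino acid -> synonymous codon family (sorted codons)
FAMILIES: dict[str, tuple[str, ...]] = _build_families()

#: amino acids encoded by a single codon (Met, Trp) -- excluded from the
#: 59-codon informative set used for RSCU, GC3s and PR2.
SINGLE_CODON_AAS = frozenset(
    aa for aa, codons in FAMILIES.items() if len(codons) == 1
)

#: the 59 synonymously variable sense codons
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: codons belonging to fourfold-degenerate families
FOURFOLD_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if len(FAMILIES[CODON_TO_AA[c]]) == 4
)

# Wright's family-size multiplicities for the standard/plastid code with
# Met and Trp set aside: nine 2-fold, one 3-fold (Ile), five 4-fold and
# three 6-fold (Leu, Ser, Arg) families.
FAMILY_MULTIPLICITY = {2: 9, 3: 1, 4: 5, 6: 3}


def translate(cds: str) -> str:
    """Translate an in-frame CDS; stop codons become '*'."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def has_internal_stop(cds: str) -> bool:
    """True if any codon before the final one is a stop codon."""
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3].upper() in STOP_CODONS:
            return True
    return False
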