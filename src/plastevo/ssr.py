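"""Perfect microsatellite (SSR) mining, context classification, motif
presence/absence matrices and species clustering.

Detection follows MISA-style semantics for perfect repeats: a locus is a
maximal run of a primitive repeat unit meeting a copy-number threshold
that depends on the unit length. Default thresholds are 10 copies for
mononucleotides, 6 for dinucleotides, 5 for tri- and tetranucleotides and
3 for penta- through decanucleotides. Runs are reported once, at their
primitive unit and leftmost phase; trailing partial copies are not
counted, so the reported interval length is exactly unit_len * copies.
Sequences are scanned linearly (a repeat spanning the circular origin is
not joined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .records import PlastomeRecord

__all__ = [
    "DEFAULT_THRESHOLDS",
    "SSRLocus",
    "find_ssrs",
    "classify_context",
    "motif_presence_matrix",
    "conserved_motifs",
    "cluster_species",
    "canonical_motif",
    "category_percentages",
]

UNIT_NAMES = {
    1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
    6: "hexa", 7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}

DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 3, 6: 3, 7: 3, 8: 3, 9: 3, 10: 3}


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation (strands are not collapsed:
    A- and T-homopolymers remain distinct motifs)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat locus (0-based half-open coordinates)."""

    species_id: str
    motif: str
    unit_len: int
    copies: int
    start: int
    end: int
    context: str = "unclassified"

    def __post_init__(self):
        if self.end - self.start != self.unit_len * self.copies:
            raise ValueError("interval length must equal unit_len * copies")

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)


def find_ssrs(
    sequence: str,
    thresholds: dict[int, int] | None = None,
    species_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the copy thresholds.

    For each unit length u the boolean array seq[x] == seq[x+u] is run-
    length scanned: a maximal run of m matches starting at i spans a
    repeat region of m+u bases whose leading u bases are the motif and
    whose whole-copy count is (m+u)//u. Non-primitive motifs (powers of a
    shorter unit) and motifs containing N are suppressed, so each
    physical run surfaces exactly once. Loci are returned sorted by
    (start, unit_len).
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    missing = set(range(1, 11)) - set(thresholds)
    if missing:
        raise ValueError(f"thresholds missing unit lengths {sorted(missing)}")
    seq = sequence.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    loci: list[SSRLocus] = []
    for u, min_copies in sorted(thresholds.items()):
        if n < u * min_copies:
            continue
        eq = arr[: n - u] == arr[u:]
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for i, j in zip(starts, ends):
            m = int(j - i)
            copies = (m + u) // u
            if copies < min_copies:
                continue
            motif = seq[i : i + u]
            if "N" in motif or not _is_primitive(motif):
                continue
            loci.append(
                SSRLocus(
                    species_id=species_id,
                    motif=motif,
                    unit_len=u,
                    copies=copies,
                    start=int(i),
                    end=int(i) + u * copies,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def classify_context(locus: SSRLocus, record: PlastomeRecord) -> str:
    """Genomic context of a locus by its start position.

    CDS exons take priority over introns, and both over intergenic
    spacers (IGS); tRNA/rRNA bodies are not coding sequence and count as
    IGS. A locus whose start lies outside the genome raises.
    """
    n = len(record.sequence)
    if not 0 <= locus.start < n:
        raise ValueError(f"locus start {locus.start} outside genome of {n} bp")
    pos = locus.start
    in_intron = False
    for gene in record.genes:
        if gene.feature_class == "CDS" and any(
            s <= pos < e for s, e in gene.exons
        ):
            return "CDS"
        if any(s <= pos < e for s, e in gene.introns):
            in_intron = True
    return "intron" if in_intron else "IGS"


def motif_presence_matrix(all_loci: dict[str, list[SSRLocus]]) -> pd.DataFrame:
    """Species x canonical-motif binary matrix (motifs sorted by unit
    length then lexicographically; species sorted by name)."""
    if len(all_loci) < 2:
        raise ValueError("need at least 2 species")
    motifs = sorted(
        {l.canonical for loci in all_loci.values() for l in loci},
        key=lambda m: (len(m), m),
    )
    species = sorted(all_loci)
    data = np.zeros((len(species), len(motifs)), dtype=int)
    motif_idx = {m: j for j, m in enumerate(motifs)}
    for i, sp in enumerate(species):
        for locus in all_loci[sp]:
            data[i, motif_idx[locus.canonical]] = 1
    return pd.DataFrame(data, index=species, columns=motifs)


def conserved_motifs(matrix: pd.DataFrame, min_fraction: float = 0.9) -> list[str]:
    """Motifs present in at least ``min_fraction`` of species."""
    frac = matrix.mean(axis=0)
    return [m for m in matrix.columns if frac[m] >= min_fraction]


def cluster_species(matrix: pd.DataFrame) -> str:
    """Average-linkage hierarchical clustering on Jaccard distances,
    returned as a Newick string with ultrametric branch lengths.

    Species are processed in name order so ties break deterministically;
    identical profiles merge at height 0.
    """
    if len(matrix) < 2 or matrix.shape[1] < 1:
        raise ValueError("need >= 2 species and >= 1 motif")
    matrix = matrix.sort_index()
    X = matrix.to_numpy(dtype=bool)
    dist = pdist(X, metric="jaccard")
    dist = np.nan_to_num(dist)  # all-zero profile pairs: distance 0
    Z = hierarchy.linkage(dist, method="average")
    return _linkage_to_newick(Z, list(matrix.index))


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def node(i: int):
        if i < n:
            return labels[i], 0.0
        left, right, dist, _ = Z[i - n]
        h = dist / 2.0
        parts = []
        for child in (int(left), int(right)):
            sub, child_h = node(child)
            parts.append(f"{sub}:{max(h - child_h, 0.0):.10g}")
        return "(" + ",".join(parts) + ")", h

    tree, _ = node(n + len(Z) - 1)
    return tree + ";"


def category_percentages(tallies: dict[str, int]) -> dict[str, float]:
    """Percent share of each category in a tally table (e.g. loci per
    unit-length class or per genomic context)."""
    total = sum(tallies.values())
    if total == 0:
        return {k: 0.0 for k in tallies}
    return {k: 100.0 * v / total for k, v in tallies.items()}
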