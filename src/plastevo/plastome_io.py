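"""Plastome I/O, quadripartite structure detection, CDS extraction,
structural statistics and gene-order synteny.

GenBank flat files are read and written through Biopython; coordinates are
converted between the 1-based inclusive source convention and the internal
0-based half-open convention at the I/O boundary. A lighter FASTA +
annotation-TSV pair is supported for synthetic data and round-tripping.

Inverted-repeat detection works on exact sequence identity: the maximal
pair of exact reverse-complement repeats is located on the doubled
sequence (to respect circularity) by k-mer seeding and greedy exact
extension, which is deterministic and independent of annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .categories import classify_with_map
from .genetics import complement, has_internal_stop, revcomp
from .records import (
    GeneAnnotation,
    GeneSequence,
    Interval,
    PlastomeRecord,
    RegionBoundaries,
)

logger = logging.getLogger("plastevo.plastome_io")

__all__ = [
    "ParseError",
    "NoQuadripartiteError",
    "AmbiguousRepeatError",
    "parse_plastome",
    "write_genbank",
    "write_fasta",
    "write_annotation_tsv",
    "detect_quadripartite",
    "extract_cds",
    "region_stats",
    "gene_order_synteny",
]

_FEATURE_CLASSES = ("CDS", "tRNA", "rRNA")
_SILENT_FEATURES = {"source", "gene", "exon", "intron", "misc_feature", "repeat_region"}


class ParseError(ValueError):
    pass


class NoQuadripartiteError(ValueError):
    """No exact inverted repeat of the requested minimum length exists."""


class AmbiguousRepeatError(ValueError):
    """Multiple non-equivalent maximal inverted-repeat pairs of equal length."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            f"{len(candidates)} maximal inverted-repeat pairs of equal length: "
            + "; ".join(f"({a},{b}, len={L})" for a, b, L in candidates)
        )


# ---------------------------------------------------------------------------
# parsing and writing
# ---------------------------------------------------------------------------


def parse_plastome(
    path, annotation=None, species_id: str | None = None
) -> PlastomeRecord:
    """Read a plastome from GenBank, or from FASTA plus an annotation TSV.

    Format is inferred from the file extension (.gb/.gbk/.gbff/.genbank
    vs .fa/.fasta/.fna). GenBank 1-based inclusive coordinates become
    0-based half-open; CDS, tRNA and rRNA features are captured with exon
    structure, other feature classes are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return _parse_genbank(path, species_id)
    if suffix in (".fa", ".fasta", ".fna"):
        return _parse_fasta(path, annotation, species_id)
    raise ParseError(f"unrecognized plastome file extension: {path.name}")


def _parse_genbank(path: Path, species_id: str | None) -> PlastomeRecord:
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # biopython raises bare ValueError subclasses
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    genes = []
    for feat in seqrec.features:
        if feat.type in _FEATURE_CLASSES:
            genes.append(_feature_to_annotation(feat, path))
        elif feat.type not in _SILENT_FEATURES:
            logger.warning("%s: ignoring feature of class %r", path.name, feat.type)
    return PlastomeRecord(
        species_id=species_id or seqrec.id or path.stem,
        sequence=str(seqrec.seq).upper(),
        genes=genes,
    )


def _feature_to_annotation(feat: SeqFeature, path: Path) -> GeneAnnotation:
    quals = feat.qualifiers
    name = (quals.get("gene") or quals.get("locus_tag") or [""])[0]
    if not name:
        raise ParseError(f"{path.name}: {feat.type} feature without gene/locus_tag")
    strand = "-" if feat.location.strand == -1 else "+"
    parts = sorted(
        ((int(p.start), int(p.end)) for p in feat.location.parts),
        key=lambda iv: iv[0],
        reverse=(strand == "-"),
    )
    return GeneAnnotation(
        name=name, feature_class=feat.type, strand=strand, exons=tuple(parts)
    )


def _parse_fasta(path: Path, annotation, species_id) -> PlastomeRecord:
    try:
        seqrec = SeqIO.read(str(path), "fasta")
    except Exception as exc:
        raise ParseError(f"malformed FASTA file {path}: {exc}") from exc
    genes = []
    if annotation is not None:
        genes = _read_annotation_tsv(annotation)
    return PlastomeRecord(
        species_id=species_id or seqrec.id or path.stem,
        sequence=str(seqrec.seq).upper(),
        genes=genes,
    )


def _read_annotation_tsv(path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
            name, fclass, strand, exon_str = fields
            try:
                exons = tuple(
                    (int(s), int(e))
                    for s, e in (part.split("-") for part in exon_str.split(";"))
                )
                genes.append(
                    GeneAnnotation(
                        name=name, feature_class=fclass, strand=strand, exons=exons
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_annotation_tsv(record: PlastomeRecord, path) -> None:
    """Write genes as a TSV: name, class, strand, exon intervals (0-based)."""
    with open(path, "w") as fh:
        fh.write("# gene\tclass\tstrand\texons (0-based half-open, transcription order)\n")
        for g in sorted(record.genes, key=lambda g: (g.start, g.name)):
            exon_str = ";".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.name}\t{g.feature_class}\t{g.strand}\t{exon_str}\n")


def write_fasta(record: PlastomeRecord, path) -> None:
    seqrec = SeqRecord(Seq(record.sequence), id=record.species_id, description="")
    SeqIO.write([seqrec], str(path), "fasta")


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a GenBank flat file (1-based inclusive coordinates on output)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.species_id,
        name=record.species_id[:16].replace(" ", "_"),
        description=f"{record.species_id} plastome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for g in sorted(record.genes, key=lambda g: (g.start, g.name)):
        strand = -1 if g.strand == "-" else 1
        parts = [
            SimpleLocation(s, e, strand)
            for s, e in sorted(g.exons, key=lambda iv: iv[0])
        ]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        seqrec.features.append(
            SeqFeature(loc, type=g.feature_class, qualifiers={"gene": [g.name]})
        )
    SeqIO.write([seqrec], str(path), "genbank")


# ---------------------------------------------------------------------------
# quadripartite structure
# ---------------------------------------------------------------------------


def detect_quadripartite(record: PlastomeRecord, min_ir: int = 1000) -> RegionBoundaries:
    """Locate the quadripartite structure of a circular plastome.

    Finds the maximal-length pair of exact reverse-complement repeats on
    the circle; the two single-copy gaps between them are labeled LSC
    (longer) and SSC (shorter), and the regions are reported in the
    orientation LSC -> IRb -> SSC -> IRa.

    Raises :class:`NoQuadripartiteError` when no inverted repeat of at
    least ``min_ir`` bp exists, and :class:`AmbiguousRepeatError` when two
    non-equivalent maximal pairs tie in length.
    """
    seq = record.sequence
    n = len(seq)
    if min_ir < 1:
        raise ValueError("min_ir must be positive")
    candidates = _maximal_revcomp_pairs(seq, min_ir)
    if not candidates:
        raise NoQuadripartiteError(
            f"{record.species_id}: no exact inverted repeat of >= {min_ir} bp"
        )
    best_len = max(L for _, _, L in candidates)
    best = sorted({(min(a, b), max(a, b), L) for a, b, L in candidates if L == best_len})
    if len(best) > 1:
        raise AmbiguousRepeatError(best)
    a, b, L = best[0]

    gap_ab = (b - (a + L)) % n  # gap following arc at a
    gap_ba = (a - (b + L)) % n  # gap following arc at b
    # LSC is the longer gap; ties resolved toward the gap after the
    # lower-coordinate arc so the result is deterministic.
    if gap_ab >= gap_ba:
        lsc = Interval((a + L) % n, b % n, n)
        irb = Interval(b % n, (b + L) % n, n)
        ssc = Interval((b + L) % n, a % n, n)
        ira = Interval(a % n, (a + L) % n, n)
    else:
        lsc = Interval((b + L) % n, a % n, n)
        irb = Interval(a % n, (a + L) % n, n)
        ssc = Interval((a + L) % n, b % n, n)
        ira = Interval(b % n, (b + L) % n, n)
    boundaries = RegionBoundaries(lsc=lsc, irb=irb, ssc=ssc, ira=ira)
    boundaries.validate(seq)
    return boundaries


def _maximal_revcomp_pairs(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal pairs (i, j, L) with seq[i:i+L] == revcomp(seq[j:j+L])
    circularly and the two arcs disjoint on the circle."""
    n = len(seq)
    k = min(31, min_len)
    ext = seq + seq[: k - 1]
    kmer_pos: dict[str, list[int]] = {}
    for i in range(n):
        kmer_pos.setdefault(ext[i : i + k], []).append(i)

    # seeds grouped by the extension-invariant anti-diagonal (i + m + L) mod n
    diag_seeds: dict[int, list[tuple[int, int]]] = {}
    for m in range(n):
        w = revcomp(ext[m : m + k])
        for i in kmer_pos.get(w, ()):
            diag_seeds.setdefault((i + m + k) % n, []).append((i, m))

    results: dict[frozenset, tuple[int, int, int]] = {}
    cap = n // 2
    for seeds in diag_seeds.values():
        covered: list[tuple[int, int]] = []  # (i_start, L) of extended pairs
        for i0, m0 in sorted(seeds):
            if any((i0 - s) % n < L for s, L in covered):
                continue
            i, m, L = _extend_pair(seq, n, i0, m0, k, cap)
            covered.append((i, L))
            if L < min_len:
                continue
            ai, am = i % n, m % n
            if ai == am or not _arcs_disjoint(ai, am, L, n):
                continue
            results[frozenset((ai, am))] = (ai, am, L)
    return list(results.values())


def _extend_pair(seq: str, n: int, i: int, m: int, L: int, cap: int):
    # invariant: seq[(i+t)%n] == complement(seq[(m+L-1-t)%n]) for t < L
    while L < cap and seq[(i - 1) % n] == complement(seq[(m + L) % n]):
        i -= 1
        L += 1
    while L < cap and seq[(i + L) % n] == complement(seq[(m - 1) % n]):
        m -= 1
        L += 1
    return i % n, m % n, L


def _arcs_disjoint(a: int, b: int, L: int, n: int) -> bool:
    if 2 * L > n:
        return False
    # distance from a to b going forward must be >= L, and likewise b to a
    return (b - a) % n >= L and (a - b) % n >= L


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rejection:
    gene_name: str
    reason: str


def splice_gene(record: PlastomeRecord, gene: GeneAnnotation) -> str:
    """Spliced, strand-corrected nucleotide sequence of a gene."""
    parts = []
    for s, e in gene.exons:
        sub = record.sequence[s:e]
        parts.append(revcomp(sub) if gene.strand == "-" else sub)
    return "".join(parts)


def extract_cds(
    record: PlastomeRecord, category_map: dict[str, str] | None = None
) -> tuple[list[GeneSequence], list[Rejection]]:
    """Spliced in-frame CDSs plus a report of genes failing the filters.

    Genes whose exon total is not a multiple of three, or whose spliced
    sequence contains an internal stop codon, are rejected with a reason
    rather than raising. Duplicated gene names (IR copies) keep the copy
    with the lower start coordinate.
    """
    kept: dict[str, GeneSequence] = {}
    rejections: list[Rejection] = []
    for gene in sorted(record.genes, key=lambda g: (g.start, g.name)):
        if gene.feature_class != "CDS":
            continue
        if gene.name in kept:
            continue  # IR duplicate: lower-start copy already retained
        cds = splice_gene(record, gene)
        if len(cds) % 3 != 0:
            rejections.append(Rejection(gene.name, "length not multiple of 3"))
            continue
        if has_internal_stop(cds):
            rejections.append(Rejection(gene.name, "internal stop"))
            continue
        kept[gene.name] = GeneSequence(
            species_id=record.species_id,
            gene_name=gene.name,
            cds=cds,
            category=classify_with_map(gene.name, category_map),
        )
    return list(kept.values()), rejections


# ---------------------------------------------------------------------------
# structural statistics
# ---------------------------------------------------------------------------


def region_stats(record: PlastomeRecord) -> dict:
    """Per-genome structural summary: lengths, composition, gene counts,
    GC by codon position over the concatenated retained CDSs."""
    seq = record.sequence
    n = len(seq)
    base_counts = {b: seq.count(b) for b in "ACGT"}
    gc = base_counts["G"] + base_counts["C"]
    stats: dict = {
        "species_id": record.species_id,
        "length": n,
        "gc_percent": 100.0 * gc / n,
        "base_percent": {b: 100.0 * c / n for b, c in base_counts.items()},
        "gene_counts": {
            fc: sum(1 for g in record.genes if g.feature_class == fc)
            for fc in ("CDS", "tRNA", "rRNA")
        },
        "n_genes": len(record.genes),
        "flags": [],
    }
    if record.boundaries is not None:
        lengths = record.boundaries.lengths()
        stats["lsc_len"] = lengths["lsc"]
        stats["ssc_len"] = lengths["ssc"]
        stats["ir_len"] = lengths["ira"]
    genes, _ = extract_cds(record)
    if genes:
        concat = "".join(g.cds for g in genes)
        for pos, key in enumerate(("gc1", "gc2", "gc3")):
            bases = concat[pos::3]
            stats[key] = 100.0 * sum(bases.count(b) for b in "GC") / len(bases)
    else:
        stats["flags"].append("no retained CDS: codon-position GC absent")
    return stats


# ---------------------------------------------------------------------------
# gene-order synteny
# ---------------------------------------------------------------------------


def gene_order_synteny(a: PlastomeRecord, b: PlastomeRecord) -> dict:
    """Collinearity of two annotated genomes from shared gene order.

    Genes shared by both genomes (names compared case-insensitively,
    duplicates collapsed to the lower-start copy) form a signed
    permutation of b's order relative to a's. Maximal collinear runs are
    the synteny blocks; a breakpoint is an adjacency of a's order not
    preserved, in either orientation, in b.
    """
    order_a = _signed_order(a)
    order_b = _signed_order(b)
    shared = sorted(set(order_a) & set(order_b))
    if len(shared) < 2:
        raise ValueError(
            f"insufficient shared annotation between {a.species_id} and "
            f"{b.species_id}: {len(shared)} shared gene(s)"
        )
    rank = {}
    sign_a = {}
    idx = 1
    for name in [g for g in _order_names(a) if g in shared]:
        rank[name] = idx
        sign_a[name] = order_a[name]
        idx += 1
    perm = [
        rank[name] * (1 if order_b[name] == sign_a[name] else -1)
        for name in _order_names(b)
        if name in shared
    ]
    blocks: list[list[int]] = [[perm[0]]]
    for prev, cur in zip(perm, perm[1:]):
        # adjacency preserved forward (.. 3 4 ..) or inside an inverted
        # run (.. -5 -4 ..)
        if cur == prev + 1 and (prev > 0) == (cur > 0):
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    m = len(perm)
    breakpoints = len(blocks) - 1
    inv_rank = {v: k for k, v in rank.items()}
    named_blocks = [[inv_rank[abs(x)] for x in blk] for blk in blocks]
    in_blocks = sum(len(blk) for blk in blocks if len(blk) >= 2)
    return {
        "shared_genes": m,
        "blocks": named_blocks,
        "n_blocks": len(blocks),
        "breakpoints": breakpoints,
        "collinear_fraction": in_blocks / m,
    }


def _dedup_genes(record: PlastomeRecord) -> list[GeneAnnotation]:
    seen: dict[str, GeneAnnotation] = {}
    for g in sorted(record.genes, key=lambda g: (g.start, g.name)):
        key = g.name.lower()
        if key not in seen:
            seen[key] = g
    return sorted(seen.values(), key=lambda g: g.start)


def _signed_order(record: PlastomeRecord) -> dict[str, str]:
    return {g.name.lower(): g.strand for g in _dedup_genes(record)}


def _order_names(record: PlastomeRecord) -> list[str]:
    return [g.name.lower() for g in _dedup_genes(record)]
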