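"""Concatenated alignments, Jukes-Cantor distances, neighbor joining and
branch-rate summaries.

This is a self-contained distance pipeline: genes are concatenated into a
supermatrix (gap-padded for missing species, sparse columns dropped),
pairwise distances use the Jukes-Cantor correction with pairwise deletion
of gapped columns, and trees come from Saitou-Nei neighbor joining with
deterministic tie-breaking. Trees are dendropy objects, so Newick I/O is
lossless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

logger = logging.getLogger("plastevo.phylo")

__all__ = [
    "DistanceMatrix",
    "concat_alignment",
    "jc_distance",
    "nj_tree",
    "branch_rate_summary",
    "tree_to_newick",
    "tree_from_newick",
]

GAP_CHARS = frozenset("-.?N")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal; nan marks a flagged entry

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")

    def flagged_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out


def concat_alignment(
    per_gene_alignments: dict[str, dict[str, str]],
    min_occupancy: float = 0.5,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-gene alignments into a supermatrix.

    Genes are taken in lexicographic order; species missing a gene are
    padded with gaps. Columns occupied (non-gap) in fewer than
    ``min_occupancy`` of all species are dropped per gene before
    concatenation, keeping the partition table consistent. Returns the
    supermatrix (species -> row) and a partition table of
    (gene, start, end) column ranges (0-based half-open).
    """
    if not per_gene_alignments:
        raise ValueError("no gene alignments supplied")
    species = sorted({sp for aln in per_gene_alignments.values() for sp in aln})
    rows = {sp: [] for sp in species}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for gene in sorted(per_gene_alignments):
        aln = per_gene_alignments[gene]
        widths = {len(s) for s in aln.values()}
        if len(widths) != 1:
            raise ValueError(f"unequal row lengths in alignment of {gene}")
        width = widths.pop()
        block = {
            sp: aln.get(sp, "-" * width).upper() for sp in species
        }
        keep_cols = [
            j
            for j in range(width)
            if sum(block[sp][j] not in GAP_CHARS for sp in species)
            >= min_occupancy * len(species)
        ]
        if len(keep_cols) < width:
            logger.info(
                "%s: dropped %d sparse column(s)", gene, width - len(keep_cols)
            )
        for sp in species:
            rows[sp].append("".join(block[sp][j] for j in keep_cols))
        partitions.append((gene, offset, offset + len(keep_cols)))
        offset += len(keep_cols)
    return {sp: "".join(parts) for sp, parts in rows.items()}, partitions


def jc_distance(supermatrix: dict[str, str]) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances with pairwise deletion.

    Columns where either row has a gap or ambiguity are excluded per
    pair; entries with p >= 3/4 or no shared columns are flagged (nan).
    """
    taxa = sorted(supermatrix)
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    seqs = {sp: np.frombuffer(supermatrix[sp].encode(), dtype="S1") for sp in taxa}
    valid = {
        sp: np.isin(seqs[sp], np.array(list("ACGT"), dtype="S1")) for sp in taxa
    }
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[taxa[i]] & valid[taxa[j]]
            sites = int(both.sum())
            if sites == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            p = float((seqs[taxa[i]][both] != seqs[taxa[j]][both]).mean())
            if p >= 0.75:
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(taxa=taxa, d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is chosen; ties go to the lowest
    (i, j) index pair. Negative branch lengths are clamped to zero with
    the deficit logged. The result is unrooted (trifurcating root).
    """
    flagged = dm.flagged_pairs()
    if flagged:
        raise ValueError(f"non-finite distance entries: {flagged}")
    if len(dm.taxa) < 3:
        raise ValueError("need >= 3 taxa")
    taxon_ns = dendropy.TaxonNamespace(dm.taxa)
    nodes = []
    for label in dm.taxa:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(node)
    d = dm.d.copy()
    active = list(range(len(dm.taxa)))
    next_nodes = {i: nodes[i] for i in active}
    deficit = 0.0

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, deficit = _clamp(li, deficit)
        lj, deficit = _clamp(lj, deficit)
        parent = dendropy.Node()
        parent.add_child(next_nodes[i])
        parent.add_child(next_nodes[j])
        next_nodes[i].edge.length = li
        next_nodes[j].edge.length = lj
        # reuse index i for the new node
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        next_nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        child = next_nodes[idx]
        root.add_child(child)
        child.edge.length = max(length, 0.0)
        if length < 0:
            logger.info("clamped negative branch length %.6g", length)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _clamp(x: float, deficit: float) -> tuple[float, float]:
    if x < 0:
        logger.info("clamped negative branch length %.6g", x)
        return 0.0, deficit - x
    return x, deficit


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def branch_rate_summary(
    tree: dendropy.Tree, genus_map: dict[str, str]
) -> dict[str, dict]:
    """Per-genus mean and SD of terminal branch lengths.

    Every leaf must be covered by ``genus_map``; singleton genera report
    the single terminal length with SD ``None``.
    """
    per_genus: dict[str, list[float]] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in genus_map:
            raise ValueError(f"leaf {label!r} missing from genus map")
        length = leaf.edge.length if leaf.edge.length is not None else 0.0
        per_genus.setdefault(genus_map[label], []).append(float(length))
    out = {}
    for genus in sorted(per_genus):
        lengths = np.array(per_genus[genus])
        out[genus] = {
            "n_species": len(lengths),
            "mean_terminal_branch": float(lengths.mean()),
            "sd_terminal_branch": float(lengths.std(ddof=1))
            if len(lengths) > 1
            else None,
        }
    return out
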