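"""Synthetic plastomes and ortholog sets with known ground truth.

The generator emulates the statistical structure of epidendroid
plastomes: a circular quadripartite genome (LSC + IRb + SSC + IRa, IRb
the exact reverse complement of IRa, SSC optionally contracted to a few
hundred bp), AT-biased protein-coding genes with a configurable GC3
target, AT-rich intergenic filler, and planted perfect SSRs with exact
recorded coordinates. Orthologs diverge by codon-wise rejection
sampling: proposed point mutations are rejected if they create a stop
codon, accepted with probability 1 when synonymous and with probability
omega when nonsynonymous. All randomness derives from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .genetics import BASES, CODON_TO_AA, FAMILIES, STOP_CODONS, complement, revcomp
from .records import (
    GeneAnnotation,
    GeneSequence,
    Interval,
    PlastomeRecord,
    RegionBoundaries,
)

__all__ = ["SimulationConfig", "simulate_plastome", "evolve_orthologs", "simulate_clade"]

_MIN_GAP = 12  # minimum intergenic filler between placed elements


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated plastome (or clade).

    Defaults mirror a strongly SSC-contracted epidendroid plastome:
    85,994 bp LSC, 608 bp SSC and 37,024 bp IRs (160,650 bp in total),
    ~63% AT filler and a GC3 target of 0.28 for coding sequence.
    """

    seed: int = 0
    lsc_len: int = 85994
    ssc_len: int = 608
    ir_len: int = 37024
    n_genes_lsc: int = 20
    n_genes_ir: int = 6
    n_genes_ssc: int = 0
    gene_len_codons: tuple[int, int] = (100, 300)  # incl. start and stop
    target_gc3: float = 0.28
    at_richness: float = 0.63
    #: planted repeats: (motif, copies, region in {lsc, ssc, ira})
    ssr_plan: tuple[tuple[str, int, str], ...] = ()
    tree: str | None = None  # Newick, branch lengths in subst/site
    omega: float = 0.2
    mutation_rate: float = 1.0

    def validate(self) -> None:
        if min(self.lsc_len, self.ir_len) <= 0 or self.ssc_len < 0:
            raise ValueError("region lengths must be positive")
        if self.lsc_len < self.ssc_len:
            raise ValueError("LSC must be at least as long as SSC")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0 < self.at_richness < 1:
            raise ValueError("at_richness must lie in (0, 1)")
        for motif, copies, region in self.ssr_plan:
            if region not in ("lsc", "ssc", "ira"):
                raise ValueError(f"unknown SSR region {region!r}")
            if not 1 <= len(motif) <= 10:
                raise ValueError("SSR unit length must be 1-10")
            if _power_of_shorter(motif):
                raise ValueError(f"SSR motif {motif!r} is not primitive")
            if copies < 2:
                raise ValueError("planted SSRs need >= 2 copies")


def _power_of_shorter(motif: str) -> bool:
    u = len(motif)
    return any(u % d == 0 and motif == motif[:d] * (u // d) for d in range(1, u))


def _filler(rng, length: int, at_richness: float) -> str:
    at = at_richness / 2.0
    gc = (1.0 - at_richness) / 2.0
    return "".join(
        rng.choice(list("ATGC"), size=length, p=[at, at, gc, gc])
    )


def _codon_sampler(rng, target_gc3: float):
    """Sampler of sense middle codons: uniform amino acid, third position
    weighted toward the GC3 target within each family.

    Met and Trp always end in G, so the within-family weight is deflated
    to keep the overall third-position GC near the target."""
    aas = sorted(FAMILIES)
    f_single = sum(1 for aa in aas if len(FAMILIES[aa]) == 1) / len(aas)
    g_eff = max((target_gc3 - f_single) / (1.0 - f_single), 0.02)
    tables = {}
    for aa in aas:
        codons = FAMILIES[aa]
        w = np.array([g_eff if c[2] in "GC" else 1.0 - g_eff for c in codons])
        tables[aa] = (list(codons), w / w.sum())

    def sample() -> str:
        aa = aas[rng.integers(len(aas))]
        codons, p = tables[aa]
        return codons[rng.choice(len(codons), p=p)]

    return sample


def random_cds(rng, n_codons: int, target_gc3: float) -> str:
    """A valid CDS: ATG, n_codons-2 biased sense codons, TAA."""
    if n_codons < 3:
        raise ValueError("need at least 3 codons")
    sample = _codon_sampler(rng, target_gc3)
    return "ATG" + "".join(sample() for _ in range(n_codons - 2)) + "TAA"


def _build_region(rng, name, target_len, n_genes, ssrs, cfg, gene_prefix):
    """Assemble one region: alternating filler and placed elements.

    Returns (sequence, gene placements, ssr placements) with local
    0-based coordinates. Raises before generation when the plan exceeds
    the region capacity.
    """
    genes = []
    lo, hi = cfg.gene_len_codons
    for g in range(n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        cds = random_cds(rng, n_codons, cfg.target_gc3)
        genes.append((f"{gene_prefix}{g + 1:02d}", cds, strand))
    items = [("gene",) + g for g in genes] + [
        ("ssr", motif, copies) for motif, copies in ssrs
    ]
    elem_len = sum(
        len(it[2]) if it[0] == "gene" else len(it[1]) * it[2] for it in items
    )
    need = elem_len + (len(items) + 1) * _MIN_GAP
    if need > target_len:
        raise ValueError(
            f"{name}: plan needs {need} bp but region is {target_len} bp"
        )
    order = rng.permutation(len(items))
    items = [items[k] for k in order]
    # distribute the slack across the len(items)+1 filler gaps
    slack = target_len - elem_len - (len(items) + 1) * _MIN_GAP
    cuts = np.sort(rng.integers(0, slack + 1, size=len(items))) if items else []
    gaps = []
    prev = 0
    for c in cuts:
        gaps.append(_MIN_GAP + int(c) - prev)
        prev = int(c)
    gaps.append(_MIN_GAP + slack - prev)

    parts = []
    gene_placements = []
    ssr_placements = []
    pos = 0
    for gap, item in zip(gaps, items):
        fill = _filler(rng, gap, cfg.at_richness)
        if item[0] == "ssr":
            motif = item[1]
            # flank bases must break the repeat so planted coordinates
            # are exactly what the detector reports
            fill = fill[:-1] + _base_not(rng, motif[-1])
        parts.append(fill)
        pos += gap
        if item[0] == "gene":
            gname, cds, strand = item[1], item[2], item[3]
            text = revcomp(cds) if strand == "-" else cds
            parts.append(text)
            gene_placements.append((gname, strand, pos, pos + len(cds)))
            pos += len(cds)
        else:
            motif, copies = item[1], item[2]
            parts.append(motif * copies)
            ssr_placements.append((motif, copies, pos, pos + len(motif) * copies))
            pos += len(motif) * copies
    tail = _filler(rng, gaps[-1], cfg.at_richness)
    # fix right flanks of planted SSRs inside the assembled string
    seq = "".join(parts) + tail
    seq_list = list(seq)
    for motif, copies, s, e in ssr_placements:
        if e < len(seq_list) and seq_list[e] == motif[0]:
            seq_list[e] = _base_not(rng, motif[0])
    seq = "".join(seq_list)
    assert len(seq) == target_len, (len(seq), target_len)
    return seq, gene_placements, ssr_placements


def _base_not(rng, banned: str) -> str:
    choices = [b for b in BASES if b != banned]
    return choices[int(rng.integers(len(choices)))]


def simulate_plastome(config: SimulationConfig):
    """Generate a quadripartite plastome plus ground-truth tables.

    Returns ``(record, truth)`` where ``record`` carries annotations and
    boundaries and ``truth`` maps ``boundaries``, ``genes`` and ``ssrs``
    to exact planted values (IR-mirrored gene and SSR copies included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ssrs_by_region = {"lsc": [], "ssc": [], "ira": []}
    for motif, copies, region in config.ssr_plan:
        ssrs_by_region[region].append((motif, copies))

    lsc_seq, lsc_genes, lsc_ssrs = _build_region(
        rng, "LSC", config.lsc_len, config.n_genes_lsc,
        ssrs_by_region["lsc"], config, "lscgene",
    )
    ssc_seq, ssc_genes, ssc_ssrs = _build_region(
        rng, "SSC", config.ssc_len, config.n_genes_ssc,
        ssrs_by_region["ssc"], config, "sscgene",
    )
    ira_seq, ira_genes, ira_ssrs = _build_region(
        rng, "IRa", config.ir_len, config.n_genes_ir,
        ssrs_by_region["ira"], config, "irgene",
    )
    irb_seq = revcomp(ira_seq)

    L, I, S = config.lsc_len, config.ir_len, config.ssc_len
    genome = lsc_seq + irb_seq + ssc_seq + ira_seq
    n = len(genome)
    off = {"lsc": 0, "irb": L, "ssc": L + I, "ira": L + I + S}

    # stop the IR palindrome from extending across region boundaries, so
    # detection recovers the planted lengths exactly
    glist = list(genome)
    if glist[L - 1] == complement(glist[0]):  # LSC-side junction
        glist[L - 1] = _base_not(rng, complement(glist[0]))
    if S > 0 and glist[L + I] == complement(glist[L + I + S - 1]):  # SSC side
        glist[L + I] = _base_not(rng, complement(glist[L + I + S - 1]))
    genome = "".join(glist)

    annotations: list[GeneAnnotation] = []
    truth_genes = []
    for region, placements in (("lsc", lsc_genes), ("ssc", ssc_genes), ("ira", ira_genes)):
        for gname, strand, s, e in placements:
            gs, ge = off[region] + s, off[region] + e
            annotations.append(
                GeneAnnotation(gname, "CDS", strand, ((gs, ge),))
            )
            truth_genes.append(
                {"name": gname, "region": region, "strand": strand, "start": gs, "end": ge}
            )
    # IRb mirrors of IRa genes (same names: true IR duplicates)
    for gname, strand, s, e in ira_genes:
        ms, me = off["irb"] + (I - e), off["irb"] + (I - s)
        mstrand = "-" if strand == "+" else "+"
        annotations.append(GeneAnnotation(gname, "CDS", mstrand, ((ms, me),)))
        truth_genes.append(
            {"name": gname, "region": "irb", "strand": mstrand, "start": ms, "end": me}
        )

    truth_ssrs = []
    for region, placements in (("lsc", lsc_ssrs), ("ssc", ssc_ssrs), ("ira", ira_ssrs)):
        for motif, copies, s, e in placements:
            truth_ssrs.append(
                {
                    "motif": motif,
                    "unit_len": len(motif),
                    "copies": copies,
                    "start": off[region] + s,
                    "end": off[region] + e,
                    "region": region,
                }
            )
    for motif, copies, s, e in ira_ssrs:  # IRb mirror copies
        truth_ssrs.append(
            {
                "motif": revcomp(motif),
                "unit_len": len(motif),
                "copies": copies,
                "start": off["irb"] + (I - e),
                "end": off["irb"] + (I - s),
                "region": "irb",
            }
        )

    boundaries = RegionBoundaries(
        lsc=Interval(0, L, n),
        irb=Interval(L, L + I, n),
        ssc=Interval(L + I, L + I + S, n),
        ira=Interval(L + I + S, n, n),
    )
    record = PlastomeRecord(
        species_id=f"sim{config.seed}",
        sequence=genome,
        genes=annotations,
        boundaries=boundaries,
    )
    boundaries.validate(record.sequence)
    truth = {
        "boundaries": {"lsc": L, "irb": I, "ssc": S, "ira": I},
        "genes": truth_genes,
        "ssrs": truth_ssrs,
    }
    return record, truth


# ---------------------------------------------------------------------------
# ortholog evolution
# ---------------------------------------------------------------------------


def _mutate_cds(rng, cds: str, expected_proposals: float, omega: float):
    """Codon-wise rejection sampling along one branch.

    Returns the mutated CDS and realized (synonymous, nonsynonymous)
    substitution counts. The terminal stop codon is left untouched; any
    proposal creating a stop codon is rejected.
    """
    seq = list(cds)
    coding_len = len(cds) - 3  # exclude terminal stop
    n_prop = int(rng.poisson(expected_proposals))
    syn = nonsyn = 0
    for _ in range(n_prop):
        pos = int(rng.integers(coding_len))
        old = seq[pos]
        alt = BASES[int(rng.integers(4))]
        while alt == old:
            alt = BASES[int(rng.integers(4))]
        ci = pos - pos % 3
        codon = "".join(seq[ci : ci + 3])
        new_codon = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
        if new_codon in STOP_CODONS:
            continue
        if CODON_TO_AA[new_codon] == CODON_TO_AA[codon]:
            seq[pos] = alt
            syn += 1
        elif rng.random() < omega:
            seq[pos] = alt
            nonsyn += 1
    return "".join(seq), syn, nonsyn


def evolve_orthologs(
    ancestor_genes: list[GeneSequence],
    tree: str | dendropy.Tree,
    omega: float,
    mutation_rate: float = 1.0,
    seed: int = 0,
):
    """Evolve CDSs along a tree under a synonymous/nonsynonymous
    acceptance model.

    Branch lengths are in expected proposed substitutions per site,
    scaled by ``mutation_rate``. Returns ``(leaf_genes, branch_truth)``:
    per-leaf lists of :class:`GeneSequence` and realized substitution
    counts per branch.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", preserve_underscores=True)
    rng = np.random.default_rng(seed)
    leaf_genes: dict[str, list[GeneSequence]] = {}
    branch_truth: list[dict] = []

    for gene in ancestor_genes:
        seqs = {id(tree.seed_node): gene.cds}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_seq = seqs[id(node.parent_node)]
            blen = node.edge.length or 0.0
            expected = mutation_rate * blen * len(parent_seq)
            mutated, syn, nonsyn = _mutate_cds(rng, parent_seq, expected, omega)
            seqs[id(node)] = mutated
            branch_truth.append(
                {
                    "gene": gene.gene_name,
                    "node": node.taxon.label if node.taxon else "internal",
                    "branch_length": blen,
                    "synonymous": syn,
                    "nonsynonymous": nonsyn,
                }
            )
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            leaf_genes.setdefault(label, []).append(
                GeneSequence(
                    species_id=label,
                    gene_name=gene.gene_name,
                    cds=seqs[id(leaf)],
                    category=gene.category,
                )
            )
    return leaf_genes, branch_truth


def simulate_clade(config: SimulationConfig):
    """Simulate a clade: one ancestral plastome evolved to every leaf of
    ``config.tree``.

    Gene sequences evolve under the omega model; intergenic filler
    receives independent substitutions at the root-to-leaf rate (planted
    SSR loci and their flanks are held fixed so truth tables stay
    exact); the IRb segment is re-mirrored from IRa per species.

    Returns ``(records, truth)`` with one annotated record per leaf.
    """
    if config.tree is None:
        raise ValueError("config.tree is required for clade simulation")
    ancestor, truth = simulate_plastome(config)
    tree = dendropy.Tree.get(data=config.tree, schema="newick", preserve_underscores=True)
    ancestor_genes = _primary_gene_sequences(ancestor, truth)
    leaf_genes, branch_truth = evolve_orthologs(
        ancestor_genes, tree, config.omega, config.mutation_rate, seed=config.seed + 1
    )
    truth = dict(truth, branches=branch_truth)

    L, I, S = config.lsc_len, config.ir_len, config.ssc_len
    n = len(ancestor.sequence)
    protected = np.zeros(n, dtype=bool)
    for entry in truth["ssrs"]:
        protected[max(entry["start"] - 1, 0) : entry["end"] + 1] = True
    gene_spans = {
        g["name"]: g for g in truth["genes"] if g["region"] != "irb"
    }
    for g in truth["genes"]:
        protected[g["start"] : g["end"]] = True
    # junction-adjacent bases keep the IR palindrome from extending
    for pos in (0, L - 1, L + I, L + I + S - 1):
        protected[pos] = True

    records: dict[str, PlastomeRecord] = {}
    leaf_depths = _leaf_depths(tree)
    for idx, label in enumerate(sorted(leaf_genes)):
        rng = np.random.default_rng([config.seed + 2, idx])
        seq = list(ancestor.sequence)
        # filler divergence outside genes, planted SSRs and IRb
        p_sub = min(config.mutation_rate * leaf_depths[label], 0.5)
        if p_sub > 0:
            for a, b in ((0, L), (L + I, n)):
                hits = a + np.flatnonzero(rng.random(b - a) < p_sub)
                for pos in hits:
                    if not protected[pos]:
                        seq[pos] = _base_not(rng, seq[pos])
        # write evolved primary gene copies
        for gene in leaf_genes[label]:
            span = gene_spans[gene.gene_name]
            text = revcomp(gene.cds) if span["strand"] == "-" else gene.cds
            seq[span["start"] : span["end"]] = text
        # re-mirror IRb from IRa
        ira_seq = "".join(seq[L + I + S :])
        seq[L : L + I] = revcomp(ira_seq)
        records[label] = PlastomeRecord(
            species_id=label,
            sequence="".join(seq),
            genes=list(ancestor.genes),
            boundaries=ancestor.boundaries,
        )
    return records, truth


def _primary_gene_sequences(record: PlastomeRecord, truth) -> list[GeneSequence]:
    from .plastome_io import splice_gene

    out = []
    seen = set()
    spans = {(g["start"], g["end"]): g for g in truth["genes"] if g["region"] != "irb"}
    for gene in record.genes:
        key = (gene.start, gene.end)
        if key in spans and gene.name not in seen:
            seen.add(gene.name)
            out.append(
                GeneSequence(
                    species_id=record.species_id,
                    gene_name=gene.name,
                    cds=splice_gene(record, gene),
                )
            )
    return out


def _leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths
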