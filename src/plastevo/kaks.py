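"""Pairwise Ka/Ks estimation by the Nei-Gojobori counting method.

Orthologous CDSs are aligned at the protein level (global affine-gap
alignment with deterministic traceback), back-translated to codons, and
gap columns removed. Synonymous and nonsynonymous sites and differences
are then counted codon-wise:

* the synonymous site fraction of a codon is, summed over its three
  positions, (number of one-step synonymous changes at that position)/3;
  changes creating stop codons are never synonymous, so S + N = 3L
  exactly;
* observed differences between a codon pair are averaged over all
  mutational pathways (orderings of the differing positions) that avoid
  stop-codon intermediates;
* proportions are corrected for multiple hits with the Jukes-Cantor
  formula d = -(3/4) ln(1 - 4p/3).

Pairs are classified as strong purifying (Ka/Ks < 0.5), relaxed
purifying (0.5 <= Ka/Ks <= 1) or positive (Ka/Ks > 1); the ratio is
undefined when dS = 0 or a proportion reaches the correction's domain
boundary.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .genetics import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, translate
from .records import GeneSequence

logger = logging.getLogger("plastevo.kaks")

__all__ = [
    "CodonAlignment",
    "KaKsPair",
    "SelectionSummary",
    "codon_align",
    "ng86",
    "selection_summary",
    "all_pairs",
    "classify_ratio",
]

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -1, -5, -1
# a gap of length g scores GAP_OPEN + g * GAP_EXTEND


@dataclass(frozen=True)
class CodonAlignment:
    species_pair: tuple[str, str]
    gene_name: str
    codon_columns: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.codon_columns)


@dataclass(frozen=True)
class KaKsPair:
    gene_name: str
    species_pair: tuple[str, str]
    ka: float | None
    ks: float | None
    ratio: float | None
    selection: str  # strong purifying | relaxed purifying | positive | undefined
    category: str = "other"
    flags: tuple[str, ...] = ()


def classify_ratio(ratio: float | None) -> str:
    if ratio is None:
        return "undefined"
    if ratio < 0.5:
        return "strong purifying"
    if ratio <= 1.0:
        return "relaxed purifying"
    return "positive"


# ---------------------------------------------------------------------------
# protein-guided codon alignment
# ---------------------------------------------------------------------------


def align_proteins(p1: str, p2: str) -> tuple[str, str, int]:
    """Global affine-gap alignment (Gotoh) of two protein strings.

    Scoring: match +1, mismatch -1, a gap of length g costs -5 - g.
    Traceback is deterministic, preferring diagonal over up over left at
    every tie. Returns the two gapped strings and the optimal score.
    """
    n, m = len(p1), len(p2)
    NEG = -(10**9)
    # state 0 = M (diagonal), 1 = X (gap in p2, consumes p1), 2 = Y (left)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + i * GAP_EXTEND
        ptr[1, i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + j * GAP_EXTEND
        ptr[2, 0, j] = 2
    for i in range(1, n + 1):
        ci = p1[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ci == p2[j - 1] else MISMATCH
            # M: best predecessor, diagonal preference M > X > Y
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cand))
            M[i, j] = cand[k] + s
            ptr[0, i, j] = k
            # X (up): open from M/Y or extend X
            cand = (
                M[i - 1, j] + GAP_OPEN + GAP_EXTEND,
                X[i - 1, j] + GAP_EXTEND,
                Y[i - 1, j] + GAP_OPEN + GAP_EXTEND,
            )
            k = int(np.argmax(cand))
            X[i, j] = cand[k]
            ptr[1, i, j] = k
            # Y (left)
            cand = (
                M[i, j - 1] + GAP_OPEN + GAP_EXTEND,
                X[i, j - 1] + GAP_OPEN + GAP_EXTEND,
                Y[i, j - 1] + GAP_EXTEND,
            )
            k = int(np.argmax(cand))
            Y[i, j] = cand[k]
            ptr[2, i, j] = k

    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    score = int(finals[state])
    a1: list[str] = []
    a2: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == 0:
            a1.append(p1[i - 1])
            a2.append(p2[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            a1.append(p1[i - 1])
            a2.append("-")
            i -= 1
        else:
            a1.append("-")
            a2.append(p2[j - 1])
            j -= 1
        state = prev
    return "".join(reversed(a1)), "".join(reversed(a2)), score


def codon_align(a: GeneSequence, b: GeneSequence) -> CodonAlignment:
    """Align two orthologous CDSs via their translations and return the
    gap-free codon columns (complete deletion of gapped columns).

    Terminal stop codons are stripped before translation. Raises when no
    alignable codon columns remain.
    """
    if a.gene_name != b.gene_name:
        raise ValueError(f"gene names differ: {a.gene_name} vs {b.gene_name}")
    cds_a = _strip_terminal_stop(a.cds)
    cds_b = _strip_terminal_stop(b.cds)
    aln1, aln2, _ = align_proteins(translate(cds_a), translate(cds_b))
    columns: list[tuple[str, str]] = []
    ia = ib = 0
    for x, y in zip(aln1, aln2):
        ca = cb = None
        if x != "-":
            ca = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if y != "-":
            cb = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        if ca is not None and cb is not None:
            columns.append((ca, cb))
    if not columns:
        raise ValueError(
            f"no alignable codons for {a.gene_name} "
            f"({a.species_id} vs {b.species_id})"
        )
    return CodonAlignment(
        species_pair=(a.species_id, b.species_id),
        gene_name=a.gene_name,
        codon_columns=tuple(columns),
    )


def _strip_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------


def _syn_site_fraction(codon: str) -> float:
    s = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


#: codon -> synonymous site count in [0, 3]
SYN_SITES: dict[str, float] = {c: _syn_site_fraction(c) for c in SENSE_CODONS}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float] | None:
    """Mean (synonymous, nonsynonymous) difference counts over all legal
    mutational pathways from c1 to c2. ``None`` if every pathway passes
    through a stop codon."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment, category: str = "other") -> KaKsPair:
    """Nei-Gojobori Ka/Ks for one pairwise codon alignment."""
    if len(aln) < 1:
        raise ValueError("empty alignment")
    S1 = S2 = 0.0
    Sd = Nd = 0.0
    flags: list[str] = []
    skipped = 0
    for c1, c2 in aln.codon_columns:
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError("stop codon inside aligned columns")
        S1 += SYN_SITES[c1]
        S2 += SYN_SITES[c2]
        counts = _pathway_counts(c1, c2)
        if counts is None:
            skipped += 1
            continue
        Sd += counts[0]
        Nd += counts[1]
    if skipped:
        flags.append(f"{skipped} codon pair(s) with stop-only pathways skipped")
        logger.info("%s: %s", aln.gene_name, flags[-1])
    L = len(aln)
    S = (S1 + S2) / 2.0
    N = 3.0 * L - S
    ka = ks = ratio = None
    if S > 0 and N > 0:
        ps, pn = Sd / S, Nd / N
        ks = _jukes_cantor(ps)
        ka = _jukes_cantor(pn)
        if ks is None:
            flags.append("pS at Jukes-Cantor domain boundary")
        if ka is None:
            flags.append("pN at Jukes-Cantor domain boundary")
        if ka is not None and ks is not None:
            if ks > 0:
                ratio = ka / ks
            elif ka is not None and ka > 0:
                flags.append("dS = 0 with dN > 0: ratio infinite/undefined")
    else:
        flags.append("degenerate site counts")
    return KaKsPair(
        gene_name=aln.gene_name,
        species_pair=aln.species_pair,
        ka=ka,
        ks=ks,
        ratio=ratio,
        selection=classify_ratio(ratio),
        category=category,
        flags=tuple(flags),
    )


def all_pairs(
    genes_by_species: dict[str, list[GeneSequence]],
) -> list[KaKsPair]:
    """NG86 over all unordered species pairs for every shared gene name."""
    by_gene: dict[str, dict[str, GeneSequence]] = {}
    for sp in sorted(genes_by_species):
        for gene in genes_by_species[sp]:
            by_gene.setdefault(gene.gene_name, {})[sp] = gene
    pairs: list[KaKsPair] = []
    for gene_name in sorted(by_gene):
        species = sorted(by_gene[gene_name])
        for sp1, sp2 in itertools.combinations(species, 2):
            g1, g2 = by_gene[gene_name][sp1], by_gene[gene_name][sp2]
            try:
                aln = codon_align(g1, g2)
            except ValueError as exc:
                logger.warning("skipping %s %s/%s: %s", gene_name, sp1, sp2, exc)
                continue
            pairs.append(ng86(aln, category=g1.category))
    return pairs


# ---------------------------------------------------------------------------
# selection-pressure summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SelectionSummary:
    n_pairs_total: int  # before the outlier filter, defined ratios only
    n_pairs: int  # after removing ratio > max_ratio
    n_outliers_removed: int
    n_undefined: int
    class_fractions: dict[str, float]
    category_stats: pd.DataFrame  # per functional category
    category_tests: pd.DataFrame  # one-sample t vs 1, Bonferroni over categories
    pairwise_tests: pd.DataFrame  # Wilcoxon rank-sum + Cohen's d, Bonferroni
    flags: list[str] = field(default_factory=list)


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    pooled = math.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def selection_summary(
    pairs: list[KaKsPair], max_ratio: float = 10.0
) -> SelectionSummary:
    """Category-level selection statistics over a set of Ka/Ks pairs.

    Outlier pairs (ratio > ``max_ratio``) are removed first. Per
    functional category: mean and median ratio, one-sample t-test against
    the neutral expectation 1 (Bonferroni over categories), all pairwise
    Wilcoxon rank-sum tests (Bonferroni over category pairs) with pooled-
    SD Cohen's d (sign: first minus second category in report order), and
    the Pearson correlation of Ka with Ks. Categories with fewer than
    two pairs are flagged and excluded from tests.
    """
    defined = [p for p in pairs if p.ratio is not None]
    if not defined:
        raise ValueError("no pairs with defined Ka/Ks ratio")
    kept = [p for p in defined if p.ratio <= max_ratio]
    n_outliers = len(defined) - len(kept)
    flags: list[str] = []

    classes = ("strong purifying", "relaxed purifying", "positive")
    fractions = {
        cls: sum(1 for p in kept if p.selection == cls) / len(kept)
        for cls in classes
    }

    by_cat: dict[str, list[KaKsPair]] = {}
    for p in kept:
        by_cat.setdefault(p.category, []).append(p)
    categories = sorted(by_cat)

    rows = []
    for cat in categories:
        ratios = np.array([p.ratio for p in by_cat[cat]])
        kas = np.array([p.ka for p in by_cat[cat]])
        kss = np.array([p.ks for p in by_cat[cat]])
        if len(ratios) >= 2 and np.ptp(kas) > 0 and np.ptp(kss) > 0:
            r = float(sstats.pearsonr(kas, kss)[0])
        else:
            r = float("nan")
        rows.append(
            {
                "category": cat,
                "n_pairs": len(ratios),
                "mean_ratio": float(ratios.mean()),
                "median_ratio": float(np.median(ratios)),
                "sd_ratio": float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan"),
                "positive_fraction": float(np.mean(ratios > 1.0)),
                "pearson_r_ka_ks": r,
            }
        )
    category_stats = pd.DataFrame(rows).set_index("category")

    testable = [c for c in categories if len(by_cat[c]) >= 2]
    for cat in categories:
        if cat not in testable:
            flags.append(f"category {cat!r} has < 2 pairs: tests skipped")

    t_rows = []
    for cat in testable:
        ratios = np.array([p.ratio for p in by_cat[cat]])
        if ratios.std(ddof=1) == 0:
            t, pval = float("nan"), float("nan")
        else:
            t, pval = sstats.ttest_1samp(ratios, popmean=1.0)
        t_rows.append(
            {
                "category": cat,
                "t_statistic": float(t),
                "p_value": float(pval),
                "p_bonferroni": min(float(pval) * len(testable), 1.0)
                if not math.isnan(pval)
                else float("nan"),
            }
        )
    category_tests = pd.DataFrame(t_rows)

    pair_rows = []
    combos = list(itertools.combinations(testable, 2))
    for cat1, cat2 in combos:
        x = np.array([p.ratio for p in by_cat[cat1]])
        y = np.array([p.ratio for p in by_cat[cat2]])
        stat, pval = sstats.ranksums(x, y)
        pair_rows.append(
            {
                "category_1": cat1,
                "category_2": cat2,
                "mean_difference": float(x.mean() - y.mean()),
                "statistic": float(stat),
                "p_value": float(pval),
                "p_bonferroni": min(float(pval) * len(combos), 1.0),
                "cohens_d": _cohens_d(x, y),
            }
        )
    pairwise_tests = pd.DataFrame(pair_rows)

    return SelectionSummary(
        n_pairs_total=len(defined),
        n_pairs=len(kept),
        n_outliers_removed=n_outliers,
        n_undefined=len(pairs) - len(defined),
        class_fractions=fractions,
        category_stats=category_stats,
        category_tests=category_tests,
        pairwise_tests=pairwise_tests,
        flags=flags,
    )
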