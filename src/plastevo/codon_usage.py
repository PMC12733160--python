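"""Codon-usage-bias battery: RSCU, ENC, expected ENC, positional GC,
PR2 indices and the neutrality (GC12 ~ GC3) regression.

Conventions
-----------
* Statistics use the 59-codon informative set: the 61 sense codons minus
  ATG (Met) and TGG (Trp), whose amino acids admit no synonymous choice.
  Stop codons are tallied separately and excluded everywhere.
* ENC is Wright's estimator with the unbiased within-family homozygosity
  F = (n * sum(p^2) - 1) / (n - 1); families with fewer than two codons
  observed, or with F <= 0, are dropped from their family-size average,
  and a missing threefold class is imputed as the mean of the two- and
  fourfold averages. The estimate is capped at 61.
* GC3s and the PR2 indices are computed over third positions of the
  informative codons; GC1/GC2/GC3 cover all non-stop codons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .genetics import (
    CODON_TO_AA,
    FAMILIES,
    FAMILY_MULTIPLICITY,
    FOURFOLD_CODONS,
    INFORMATIVE_CODONS,
    STOP_CODONS,
)
from .records import GeneSequence

logger = logging.getLogger("plastevo.codon_usage")

__all__ = [
    "CodonProfile",
    "NeutralityFit",
    "codon_counts",
    "merge_profiles",
    "rscu",
    "enc",
    "expected_enc",
    "positional_gc",
    "pr2_indices",
    "neutrality_fit",
    "preferred_codon_summary",
    "profile_gene",
]

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class CodonProfile:
    """Codon counts for one gene (or pooled genes) plus derived statistics."""

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    skipped_codons: int = 0  # codons containing ambiguous bases

    def total(self) -> int:
        return sum(self.counts.values())

    def third_position_counts(self, fourfold_only: bool = False) -> dict[str, int]:
        """Third-position base tally over the informative codon set."""
        codons = FOURFOLD_CODONS if fourfold_only else INFORMATIVE_CODONS
        out = {b: 0 for b in "ACGT"}
        for codon in codons:
            out[codon[2]] += self.counts.get(codon, 0)
        return out


def codon_counts(gene: GeneSequence | str) -> CodonProfile:
    """Exact codon tally of an in-frame CDS.

    Stop codons (terminal or otherwise) are tallied apart from the sense
    counts; codons containing ambiguous bases are skipped and logged.
    """
    cds = gene.cds if isinstance(gene, GeneSequence) else gene
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    skipped = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in CODON_TO_AA:
            counts[codon] = counts.get(codon, 0) + 1
        elif codon in STOP_CODONS:
            stops[codon] = stops.get(codon, 0) + 1
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d codon(s) with ambiguous bases", skipped)
    return CodonProfile(counts=counts, stop_counts=stops, skipped_codons=skipped)


def merge_profiles(profiles) -> CodonProfile:
    """Sum counts over profiles (equals counting the concatenated genes)."""
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    skipped = 0
    for p in profiles:
        for codon, c in p.counts.items():
            counts[codon] = counts.get(codon, 0) + c
        for codon, c in p.stop_counts.items():
            stops[codon] = stops.get(codon, 0) + c
        skipped += p.skipped_codons
    return CodonProfile(counts=counts, stop_counts=stops, skipped_codons=skipped)


def rscu(profile: CodonProfile) -> dict[str, float]:
    """Relative synonymous codon usage over the 59 informative codons.

    For codon j in a family of n_i synonymous codons with family total
    X_i, RSCU = x_j * n_i / X_i. Unobserved families are omitted; Met,
    Trp and stop codons are excluded.
    """
    out: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if len(codons) == 1:
            continue
        total = sum(profile.counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c] = profile.counts.get(c, 0) * k / total
    return out


def enc(profile: CodonProfile, unbiased: bool = True) -> float | None:
    """Wright's effective number of codons, in [20, 61].

    Returns ``None`` (undefined, to be flagged by callers) when too few
    family-size classes are observed to evaluate the estimator.
    """
    f_by_size: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        ns = [profile.counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        f = (n * sum_p2 - 1) / (n - 1) if unbiased else sum_p2
        if f <= 0:
            continue
        f_by_size[k].append(f)
    fbar = {k: sum(v) / len(v) for k, v in f_by_size.items() if v}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2  # Wright's fallback for Ile
    if set(fbar) != {2, 3, 4, 6}:
        return None
    value = 2.0 + sum(FAMILY_MULTIPLICITY[k] / fbar[k] for k in (2, 3, 4, 6))
    return min(value, ENC_MAX)


def expected_enc(gc3s: float) -> float:
    """Expected ENC under a purely GC3-driven mutation model:
    ENC* = 2 + s + 29 / (s^2 + (1 - s)^2)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must lie in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def positional_gc(gene: GeneSequence | str | CodonProfile) -> dict:
    """GC fractions by codon position: gc1, gc2, gc3, gc3s, gc12.

    gc1/gc2/gc3 run over all non-stop codons; gc3s over third positions
    of the informative (synonymously variable) codons only. Undefined
    fields are ``None`` with an entry in ``flags``.
    """
    profile = gene if isinstance(gene, CodonProfile) else codon_counts(gene)
    out: dict = {"flags": []}
    total = profile.total()
    if total == 0:
        out.update(gc1=None, gc2=None, gc3=None, gc3s=None, gc12=None)
        out["flags"].append("no informative codons")
        return out
    for pos, key in enumerate(("gc1", "gc2", "gc3")):
        gc = sum(
            c for codon, c in profile.counts.items() if codon[pos] in "GC"
        )
        out[key] = gc / total
    out["gc12"] = (out["gc1"] + out["gc2"]) / 2
    third = profile.third_position_counts()
    informative = sum(third.values())
    if informative == 0:
        out["gc3s"] = None
        out["flags"].append("gc3s undefined: no synonymously variable codons")
    else:
        out["gc3s"] = (third["G"] + third["C"]) / informative
    return out


def pr2_indices(
    profile: CodonProfile, fourfold_only: bool = False
) -> tuple[float | None, float | None]:
    """Parity-rule-2 coordinates (A3/(A3+T3), G3/(G3+C3)).

    Computed at third positions of the informative codons by default; a
    fourfold-family restriction is available. A zero denominator leaves
    that coordinate ``None``.
    """
    third = profile.third_position_counts(fourfold_only=fourfold_only)
    at = third["A"] + third["T"]
    gc = third["G"] + third["C"]
    a3_ratio = third["A"] / at if at else None
    g3_ratio = third["G"] / gc if gc else None
    return a3_ratio, g3_ratio


def preferred_codon_summary(rscu_values: dict[str, float]) -> dict:
    """Tally preferred codons (RSCU > 1) by their third base and the
    percent share ending in A or T."""
    preferred = sorted(c for c, v in rscu_values.items() if v > 1.0)
    ending = {b: sum(1 for c in preferred if c[2] == b) for b in "ACGT"}
    n = len(preferred)
    at = ending["A"] + ending["T"]
    return {
        "n_preferred": n,
        "ending": ending,
        "at_share_percent": 100.0 * at / n if n else None,
    }


@dataclass(frozen=True)
class NeutralityFit:
    """OLS regression of GC12 on GC3 across genes of one species."""

    slope: float | None
    intercept: float | None
    r_squared: float | None
    n_genes: int
    mean_gc12: float
    sd_gc12: float
    mean_gc3: float
    sd_gc3: float
    flags: tuple[str, ...] = ()


def neutrality_fit(points) -> NeutralityFit:
    """Fit GC12 ~ GC3 by ordinary least squares.

    ``points`` is an iterable of (gc12, gc3) pairs; pairs containing
    ``None`` are dropped. With zero variance in GC3 the slope is
    undefined and flagged.
    """
    clean = [(y, x) for y, x in points if y is not None and x is not None]
    if len(clean) < 2:
        raise ValueError(f"need at least 2 genes, got {len(clean)}")
    y = np.array([p[0] for p in clean])
    x = np.array([p[1] for p in clean])
    stats_common = dict(
        n_genes=len(clean),
        mean_gc12=float(y.mean()),
        sd_gc12=float(y.std(ddof=1)),
        mean_gc3=float(x.mean()),
        sd_gc3=float(x.std(ddof=1)),
    )
    if np.ptp(x) == 0:
        return NeutralityFit(
            slope=None,
            intercept=None,
            r_squared=None,
            flags=("zero variance in GC3: slope undefined",),
            **stats_common,
        )
    res = sstats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if math.isnan(r2):  # constant GC12: slope 0, no variance explained
        r2 = 0.0
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        **stats_common,
    )


def profile_gene(gene: GeneSequence, unbiased_enc: bool = True) -> dict:
    """Full per-gene record: counts, RSCU, ENC, positional GC, PR2."""
    profile = codon_counts(gene)
    gc = positional_gc(profile)
    a3_ratio, g3_ratio = pr2_indices(profile)
    return {
        "species_id": gene.species_id,
        "gene_name": gene.gene_name,
        "category": gene.category,
        "n_codons": profile.total(),
        "profile": profile,
        "rscu": rscu(profile),
        "enc": enc(profile, unbiased=unbiased_enc),
        "gc1": gc["gc1"],
        "gc2": gc["gc2"],
        "gc3": gc["gc3"],
        "gc3s": gc["gc3s"],
        "gc12": gc["gc12"],
        "a3_ratio": a3_ratio,
        "g3_ratio": g3_ratio,
        "flags": gc["flags"],
    }
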