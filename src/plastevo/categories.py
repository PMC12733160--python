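"""Functional categorization of plastid genes.

Standard plastid gene nomenclature maps onto eleven functional groups
(photosystems, ATP synthase, cytochrome b6/f, NADH dehydrogenase, RubisCO,
RNA polymerase, the two ribosomal protein classes, hypothetical reading
frames, and a catch-all). Classification is prefix-based on the gene name
and case-insensitive, so IR-duplicated or suffixed copies ("ycf1_2",
"rps12-3end") resolve to the same category as their parent gene.
"""

from __future__ import annotations

CATEGORIES = (
    "photosystem I",
    "photosystem II",
    "cytochrome b6/f",
    "ATP synthase",
    "NADH dehydrogenase",
    "RubisCO large subunit",
    "RNA polymerase",
    "small ribosomal protein",
    "large ribosomal protein",
    "hypothetical reading frame (ycf)",
    "other",
)

_PREFIX_MAP = [
    ("psa", "photosystem I"),
    ("psb", "photosystem II"),
    ("pet", "cytochrome b6/f"),
    ("atp", "ATP synthase"),
    ("ndh", "NADH dehydrogenase"),
    ("rbcl", "RubisCO large subunit"),
    ("rpo", "RNA polymerase"),
    ("rps", "small ribosomal protein"),
    ("rpl", "large ribosomal protein"),
    ("ycf", "hypothetical reading frame (ycf)"),
]


def classify_gene(name: str) -> str:
    """Map a plastid gene name to its functional category."""
    key = name.strip().lower()
    for prefix, category in _PREFIX_MAP:
        if key.startswith(prefix):
            return category
    return "other"


def load_category_map(path) -> dict[str, str]:
    """Read a user TSV (gene<TAB>category) overriding the built-in scheme."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, _, category = line.partition("\t")
            if not category:
                raise ValueError(f"malformed category line: {line!r}")
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r} for {gene}")
            mapping[gene.strip().lower()] = category
    return mapping


def classify_with_map(name: str, mapping: dict[str, str] | None) -> str:
    if mapping:
        hit = mapping.get(name.strip().lower())
        if hit:
            return hit
    return classify_gene(name)
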