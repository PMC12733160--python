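"""End-to-end orchestration over a directory of plastomes.

Runs regions -> CDS extraction -> codon battery -> COA -> SSR -> Ka/Ks ->
synteny -> tree, writing one table per analysis plus a JSON manifest with
parameters, per-stage timings, file checksums and failures. Stages are
independent where possible: a failing stage is recorded and its
dependents skipped, while unrelated stages continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_usage as cu
from . import kaks as kk
from . import multivariate, phylo, plastome_io, ssr
from .categories import load_category_map
from .genetics import INFORMATIVE_CODONS
from .records import PlastomeRecord

logger = logging.getLogger("plastevo.pipeline")

__all__ = ["RunConfig", "run_all", "category_summary"]


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    min_ir: int = 1000
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(ssr.DEFAULT_THRESHOLDS)
    )
    max_kaks_ratio: float = 10.0
    category_map_file: str | None = None
    stages: tuple[str, ...] = (
        "regions", "codon", "coa", "ssr", "kaks", "synteny", "tree",
    )
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise ValueError(f"input directory does not exist: {self.input_dir}")
        if self.min_ir <= 0 or self.max_kaks_ratio <= 0:
            raise ValueError("thresholds must be positive")
        for u, t in self.ssr_thresholds.items():
            if t <= 0:
                raise ValueError(f"SSR threshold for unit {u} must be positive")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns the manifest dictionary."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    category_map = (
        load_category_map(config.category_map_file)
        if config.category_map_file
        else None
    )

    paths = sorted(
        p
        for p in Path(config.input_dir).iterdir()
        if p.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank", ".fa", ".fasta", ".fna")
    )
    if not paths:
        raise ValueError(f"no plastome files in {config.input_dir}")

    manifest: dict = {
        "parameters": {
            "min_ir": config.min_ir,
            "ssr_thresholds": {str(k): v for k, v in config.ssr_thresholds.items()},
            "max_kaks_ratio": config.max_kaks_ratio,
            "seed": config.seed,
            "n_genomes": len(paths),
        },
        "stages": {},
        "files": {},
        "failures": [],
    }

    records: dict[str, PlastomeRecord] = {}
    for p in paths:
        rec = plastome_io.parse_plastome(p)
        records[rec.species_id] = rec
    species = sorted(records)

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except Exception as exc:  # a stage failure must not kill the run
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {
                "status": "failed",
                "error": str(exc),
                "seconds": round(time.perf_counter() - t0, 3),
            }
            manifest["failures"].append(name)

    # --- regions -----------------------------------------------------------
    def stage_regions():
        rows = []
        for sp in species:
            rec = records[sp]
            try:
                boundaries = plastome_io.detect_quadripartite(rec, config.min_ir)
                records[sp] = rec.with_boundaries(boundaries)
            except plastome_io.NoQuadripartiteError:
                logger.warning("%s: treated as IR-lacking", sp)
            rows.append(plastome_io.region_stats(records[sp]))
        df = pd.json_normalize(rows)
        df.to_csv(out / "structure_summary.tsv", sep="\t", index=False)
        (out / "structure_summary.json").write_text(
            json.dumps(rows, indent=1, default=str)
        )

    run_stage("regions", stage_regions)

    # --- CDS extraction + codon battery -----------------------------------
    genes_by_species: dict[str, list] = {}
    profiles: list[dict] = []

    def stage_codon():
        rej_rows = []
        for sp in species:
            genes, rejections = plastome_io.extract_cds(records[sp], category_map)
            genes_by_species[sp] = genes
            rej_rows += [
                {"species_id": sp, "gene": r.gene_name, "reason": r.reason}
                for r in rejections
            ]
            profiles.extend(cu.profile_gene(g) for g in genes)
        pd.DataFrame(
            rej_rows, columns=["species_id", "gene", "reason"]
        ).to_csv(out / "cds_rejections.tsv", sep="\t", index=False)

        rows = []
        for pr in profiles:
            row = {
                k: pr[k]
                for k in (
                    "species_id", "gene_name", "category", "n_codons",
                    "enc", "gc1", "gc2", "gc3", "gc3s", "gc12",
                    "a3_ratio", "g3_ratio",
                )
            }
            row.update({c: pr["rscu"].get(c, 0.0) for c in INFORMATIVE_CODONS})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "gene_profiles.tsv", sep="\t", index=False)

        sp_rows = []
        for sp in species:
            mine = [p for p in profiles if p["species_id"] == sp]
            encs = [p["enc"] for p in mine if p["enc"] is not None]
            gc3s = [p["gc3s"] for p in mine if p["gc3s"] is not None]
            fit_points = [(p["gc12"], p["gc3"]) for p in mine]
            row = {
                "species_id": sp,
                "n_genes": len(mine),
                "mean_enc": float(np.mean(encs)) if encs else None,
                "mean_gc3s": float(np.mean(gc3s)) if gc3s else None,
            }
            if len(fit_points) >= 2:
                fit = cu.neutrality_fit(fit_points)
                row.update(
                    slope=fit.slope,
                    intercept=fit.intercept,
                    r_squared=fit.r_squared,
                    mean_gc12=fit.mean_gc12,
                    mean_gc3=fit.mean_gc3,
                )
            sp_rows.append(row)
        pd.DataFrame(sp_rows).to_csv(
            out / "species_summary.tsv", sep="\t", index=False
        )

    run_stage("codon", stage_codon)

    # --- correspondence analysis (per species, genes x 59 codons) ---------
    def stage_coa():
        if not profiles:
            raise RuntimeError("codon stage did not run")
        summary = []
        coord_frames = []
        for sp in species:
            mine = {p["gene_name"]: p["rscu"] for p in profiles if p["species_id"] == sp}
            if len(mine) < 2:
                continue
            result = multivariate.coa(multivariate.rscu_matrix(mine))
            row = {"species_id": sp, "total_inertia": result.total_inertia}
            for k in range(min(2, result.n_axes)):
                row[f"axis{k + 1}_pct"] = float(result.axis_pct[k])
            summary.append(row)
            rc = result.row_coords.iloc[:, :2].copy()
            rc.insert(0, "species_id", sp)
            coord_frames.append(rc)
        pd.DataFrame(summary).to_csv(out / "coa_summary.tsv", sep="\t", index=False)
        if coord_frames:
            pd.concat(coord_frames).to_csv(out / "coa_coords.tsv", sep="\t")

    run_stage("coa", stage_coa)

    # --- SSRs --------------------------------------------------------------
    def stage_ssr():
        all_loci = {}
        rows = []
        for sp in species:
            loci = ssr.find_ssrs(
                records[sp].sequence, config.ssr_thresholds, species_id=sp
            )
            loci = [
                ssr.SSRLocus(
                    species_id=l.species_id,
                    motif=l.motif,
                    unit_len=l.unit_len,
                    copies=l.copies,
                    start=l.start,
                    end=l.end,
                    context=ssr.classify_context(l, records[sp]),
                )
                for l in loci
            ]
            all_loci[sp] = loci
            rows += [
                {
                    "species_id": sp,
                    "motif": l.motif,
                    "canonical_motif": l.canonical,
                    "unit_len": l.unit_len,
                    "copies": l.copies,
                    "start": l.start,
                    "end": l.end,
                    "context": l.context,
                }
                for l in loci
            ]
        pd.DataFrame(rows).to_csv(out / "ssr_loci.tsv", sep="\t", index=False)
        if len(all_loci) >= 2:
            matrix = ssr.motif_presence_matrix(all_loci)
            matrix.to_csv(out / "ssr_presence.tsv", sep="\t")
            (out / "ssr_dendrogram.nwk").write_text(
                ssr.cluster_species(matrix) + "\n"
            )

    run_stage("ssr", stage_ssr)

    # --- Ka/Ks -------------------------------------------------------------
    kaks_pairs: list = []

    def stage_kaks():
        if not genes_by_species:
            raise RuntimeError("codon stage did not run")
        kaks_pairs.extend(kk.all_pairs(genes_by_species))
        pd.DataFrame(
            [
                {
                    "gene": p.gene_name,
                    "species_1": p.species_pair[0],
                    "species_2": p.species_pair[1],
                    "ka": p.ka,
                    "ks": p.ks,
                    "ratio": p.ratio,
                    "selection": p.selection,
                    "category": p.category,
                }
                for p in kaks_pairs
            ]
        ).to_csv(out / "kaks_pairs.tsv", sep="\t", index=False)
        if any(p.ratio is not None for p in kaks_pairs):
            summary = kk.selection_summary(kaks_pairs, config.max_kaks_ratio)
            summary.category_stats.to_csv(out / "kaks_categories.tsv", sep="\t")
            summary.pairwise_tests.to_csv(
                out / "kaks_category_tests.tsv", sep="\t", index=False
            )
            (out / "kaks_summary.json").write_text(
                json.dumps(
                    {
                        "n_pairs_total": summary.n_pairs_total,
                        "n_pairs": summary.n_pairs,
                        "n_outliers_removed": summary.n_outliers_removed,
                        "class_fractions": summary.class_fractions,
                    },
                    indent=1,
                )
            )

    run_stage("kaks", stage_kaks)

    # --- synteny -----------------------------------------------------------
    def stage_synteny():
        rows = []
        for i, sp1 in enumerate(species):
            for sp2 in species[i + 1 :]:
                try:
                    rep = plastome_io.gene_order_synteny(records[sp1], records[sp2])
                except ValueError as exc:
                    logger.warning("synteny %s/%s: %s", sp1, sp2, exc)
                    continue
                rows.append(
                    {
                        "species_1": sp1,
                        "species_2": sp2,
                        "shared_genes": rep["shared_genes"],
                        "n_blocks": rep["n_blocks"],
                        "breakpoints": rep["breakpoints"],
                        "collinear_fraction": rep["collinear_fraction"],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "synteny.tsv", sep="\t", index=False)

    run_stage("synteny", stage_synteny)

    # --- tree --------------------------------------------------------------
    def stage_tree():
        if not genes_by_species:
            raise RuntimeError("codon stage did not run")
        per_gene: dict[str, dict[str, str]] = {}
        by_gene: dict[str, dict] = {}
        for sp, genes in genes_by_species.items():
            for g in genes:
                by_gene.setdefault(g.gene_name, {})[sp] = g
        for gene_name, members in by_gene.items():
            if len(members) < 2:
                continue
            sps = sorted(members)
            ref = members[sps[0]]
            ref_row = kk._strip_terminal_stop(ref.cds)
            aln: dict[str, str] = {sps[0]: ref_row}
            ok = True
            for sp in sps[1:]:
                try:
                    pair = kk.codon_align(ref, members[sp])
                except ValueError:
                    ok = False
                    break
                if len(pair) * 3 != len(ref_row):
                    ok = False  # indels against the reference: skip gene
                    break
                aln[sp] = "".join(c2 for _, c2 in pair.codon_columns)
            if ok and len({len(s) for s in aln.values()}) == 1:
                per_gene[gene_name] = aln
        if not per_gene:
            raise RuntimeError("no alignable shared genes for tree building")
        supermatrix, partitions = phylo.concat_alignment(per_gene)
        pd.DataFrame(
            partitions, columns=["gene", "start", "end"]
        ).to_csv(out / "partitions.tsv", sep="\t", index=False)
        dm = phylo.jc_distance(supermatrix)
        if len(dm.taxa) >= 3 and not dm.flagged_pairs():
            tree = phylo.nj_tree(dm)
            (out / "nj_tree.nwk").write_text(phylo.tree_to_newick(tree) + "\n")
            genus_map = {sp: sp.split("_")[0] for sp in dm.taxa}
            (out / "branch_rates.json").write_text(
                json.dumps(phylo.branch_rate_summary(tree, genus_map), indent=1)
            )

    run_stage("tree", stage_tree)

    # --- category summary joins codon + kaks -------------------------------
    if profiles:
        category_summary(profiles, kaks_pairs).to_csv(
            out / "category_summary.tsv", sep="\t"
        )

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def category_summary(profiles: list[dict], pairs: list | None = None) -> pd.DataFrame:
    """Per-functional-category means/SDs of ENC, GC3, GC12, GC3s, joined
    with mean Ka/Ks and the positive-selection fraction when pairs are
    supplied. Every retained gene contributes to exactly one row."""
    rows: dict[str, dict[str, list]] = {}
    for p in profiles:
        bucket = rows.setdefault(
            p["category"], {"enc": [], "gc3": [], "gc12": [], "gc3s": []}
        )
        for key in ("enc", "gc3", "gc12", "gc3s"):
            if p[key] is not None:
                bucket[key].append(p[key])
    out_rows = []
    for cat in sorted(rows):
        row: dict = {"category": cat, "n_genes": len([
            p for p in profiles if p["category"] == cat
        ])}
        for key, values in rows[cat].items():
            row[f"mean_{key}"] = float(np.mean(values)) if values else None
            row[f"sd_{key}"] = (
                float(np.std(values, ddof=1)) if len(values) > 1 else None
            )
        out_rows.append(row)
    df = pd.DataFrame(out_rows).set_index("category")
    if pairs:
        defined = [p for p in pairs if p.ratio is not None]
        if defined:
            kdf = pd.DataFrame(
                {"category": [p.category for p in defined],
                 "ratio": [p.ratio for p in defined]}
            )
            agg = kdf.groupby("category")["ratio"].agg(
                mean_kaks="mean",
                positive_fraction=lambda s: float((s > 1).mean()),
            )
            df = df.join(agg, how="left")
    return df
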