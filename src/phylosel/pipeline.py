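"""End-to-end orchestration: QC -> selection tests -> FDR -> robustness ->
enrichment -> genome statistics, driven by a single YAML-able config.

Every stochastic stage takes a seed from the config, so a config plus
seed reproduces byte-identical TSV outputs.  Inputs are either simulated
in place (the default smoke path) or read from directories of
FASTA/newick/TSV files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import CodonAlignment
from .alignment_robustness import make_ensemble, robust_test
from .codon_engine import branch_ds, fit_parameters
from .enrichment import AnnotationMap, enrichment_scan
from .genome_stats import (
    filter_sites,
    het_per_kb,
    make_psmcfa,
    write_psmcfa,
    write_sites_tsv,
)
from .ortholog_qc import beta_outlier_filter, min_patristic_ds
from .selection_tests import (
    branch_site_test,
    branch_test,
    correct_records,
    records_to_frame,
    summaries_to_frame,
    summarize_tests,
)
from .synthetic_data import (
    default_species_tree,
    simulate_annotation_set,
    simulate_orthogroup_set,
    simulate_variant_sites,
)
from .trees import PhyloTree

logger = logging.getLogger("phylosel.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_starts": 1,
    "fdr": 0.05,
    "bh_mode": "step_up",
    "species_tree": None,  # newick string/path; default five-taxon tree
    "foregrounds": {
        "BAMBUSICOLA": "Bambusicola",
        "GALLUS": "Gallus",
        "MRCA": ["Bambusicola", "Gallus"],
    },
    "tests": ["branch"],
    "qc": {"enabled": True, "beta_percentile": 0.99},
    "simulate": {
        "n_genes": 20,
        "n_codons": 120,
        "contamination_rate": 0.1,
        "ds_shift": 0.8,
        "omega": 0.2,
        "kappa": 2.0,
    },
    "inputs": None,  # {"alignments": dir, "trees": dir, "annotations": tsv, "sites": tsv}
    "robustness": {"enabled": False, "n_alignments": 10},
    "enrichment": {"n_categories": 25, "planted_category": "CAT:0000", "odds": 5.0},
    "het": {
        "chrom_lengths": {"chr1": 400_000, "chr2": 250_000, "chrZ": 150_000},
        "het_rate": 0.0038,
        "depth_mean": 25.0,
        "error_rate": 0.0002,
        "min_depth": 20,
        "min_qual": 20,
        "min_maf": 0.1,
        "psmc_min_depth": 10,
        "psmc_max_depth": 50,
    },
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default config, an optional YAML file, and overrides."""

    def deep_merge(base: dict, extra: dict) -> dict:
        out = dict(base)
        for key, val in extra.items():
            if isinstance(val, dict) and isinstance(out.get(key), dict):
                out[key] = deep_merge(out[key], val)
            else:
                out[key] = val
        return out

    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            config = deep_merge(config, loaded)
    if overrides:
        config = deep_merge(config, overrides)
    return config


def _species_tree(config: dict) -> PhyloTree:
    if config.get("species_tree"):
        return PhyloTree.from_newick(config["species_tree"])
    return default_species_tree()


def _load_inputs(config: dict) -> tuple[dict[str, CodonAlignment], dict[str, PhyloTree]]:
    inputs = config["inputs"]
    aln_dir = Path(inputs["alignments"])
    if not aln_dir.is_dir():
        raise FileNotFoundError(f"alignment directory {aln_dir} does not exist")
    alignments = {}
    for path in sorted(aln_dir.glob("*.fasta")):
        alignments[path.stem] = CodonAlignment.from_fasta(path)
    if not alignments:
        raise FileNotFoundError(f"no *.fasta alignments under {aln_dir}")
    trees = {}
    tree_dir = inputs.get("trees")
    if tree_dir:
        for path in sorted(Path(tree_dir).glob("*.nwk")):
            trees[path.stem] = PhyloTree.from_newick(path)
    return alignments, trees


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns a manifest dict.

    Stage order: (simulate|load) -> ortholog QC -> branch/branch-site
    tests -> BH correction -> robustness -> enrichment -> genome stats.
    All outputs are TSV (plus one psmcfa and a JSON manifest) under
    ``outdir``.
    """
    t_start = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    n_starts = int(config["n_starts"])
    species_tree = _species_tree(config)
    manifest: dict = {"version": __version__, "seed": seed, "stages": {}, "config": config}
    float_fmt = "%.6g"

    # ---------------------------------------------------------------- input
    if config.get("inputs"):
        alignments, _gene_trees = _load_inputs(config)
        truth_contaminated = {}
    else:
        sim = config["simulate"]
        groups, ds_trees, truth = simulate_orthogroup_set(
            n_genes=int(sim["n_genes"]),
            species=tuple(species_tree.leaf_names),
            contamination_rate=float(sim["contamination_rate"]),
            ds_shift=float(sim["ds_shift"]),
            seed=seed,
            n_codons=int(sim["n_codons"]),
            kappa=float(sim["kappa"]),
            omega=float(sim["omega"]),
        )
        truth_contaminated = truth.params["contaminated"]
        alignments = {}
        for group in groups:
            taxa, rows = [], []
            for sp in species_tree.leaf_names:
                seq_id = group.members[sp][0]
                taxa.append(sp)
                rows.append(group.cds[seq_id])
            alignments[group.group_id] = CodonAlignment(taxa, rows)
    genes = sorted(alignments)
    logger.info("input: %d genes", len(genes))
    manifest["stages"]["input"] = {"n_genes": len(genes), "seconds": round(time.time() - t_start, 2)}

    # ------------------------------------------------------------------- qc
    t0 = time.time()
    excluded: set[str] = set()
    if config["qc"]["enabled"]:
        min_ds_pooled: dict[str, float] = {}
        owner: dict[str, str] = {}
        for gene in genes:
            fit = fit_parameters(
                alignments[gene], species_tree, "free_ratio",
                n_starts=n_starts, seed=seed,
            )
            ds_map = branch_ds(fit)
            ds_tree = PhyloTree.from_newick(species_tree.to_newick())
            ds_tree.set_branch_lengths(ds_map)
            for leaf, value in min_patristic_ds(ds_tree).items():
                key = f"{gene}:{leaf}"
                min_ds_pooled[key] = value
                owner[key] = gene
        report = beta_outlier_filter(
            min_ds_pooled, percentile=float(config["qc"]["beta_percentile"])
        )
        excluded = {owner[k] for k in report.removed}
        qc_frame = pd.DataFrame(
            {
                "sequence": sorted(min_ds_pooled),
                "min_ds": [min_ds_pooled[k] for k in sorted(min_ds_pooled)],
                "removed": [k in report.removed for k in sorted(min_ds_pooled)],
            }
        )
        qc_frame.to_csv(outdir / "qc_min_ds.tsv", sep="\t", index=False, float_format=float_fmt)
        (outdir / "excluded_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(excluded))
        )
        manifest["stages"]["qc"] = {
            "n_sequences": len(min_ds_pooled),
            "beta_alpha": None if np.isnan(report.beta_alpha) else round(report.beta_alpha, 4),
            "beta_cutoff": None if np.isnan(report.cutoff) else round(report.cutoff, 4),
            "n_removed_sequences": len(report.removed),
            "n_excluded_genes": len(excluded),
            "truth_contaminated_genes": sorted(
                g for g, v in truth_contaminated.items() if v
            ),
            "seconds": round(time.time() - t0, 2),
        }
    retained = [g for g in genes if g not in excluded]

    # ---------------------------------------------------------------- tests
    t0 = time.time()
    records = []
    for fg_name, fg_spec in config["foregrounds"].items():
        fg_branch = species_tree.resolve_branch(fg_spec)
        for gene in retained:
            if "branch" in config["tests"]:
                rec = branch_test(
                    alignments[gene], species_tree, fg_branch, gene_id=gene,
                    n_starts=n_starts, seed=seed,
                )
                records.append(rec)
            if "branch_site" in config["tests"]:
                rec = branch_site_test(
                    alignments[gene], species_tree, fg_branch, gene_id=gene,
                    n_starts=n_starts, seed=seed,
                )
                records.append(rec)
    records = correct_records(records, fdr=float(config["fdr"]), mode=config["bh_mode"])
    frame = records_to_frame(records)
    frame.to_csv(outdir / "tests.tsv", sep="\t", index=False, float_format=float_fmt)
    summaries = summarize_tests(records)
    summaries_to_frame(summaries).to_csv(
        outdir / "summary.tsv", sep="\t", index=False, float_format=float_fmt
    )
    manifest["stages"]["tests"] = {
        "n_records": len(records),
        "n_significant": int(sum(r.significant for r in records)),
        "seconds": round(time.time() - t0, 2),
    }

    # ----------------------------------------------------------- robustness
    t0 = time.time()
    if config["robustness"]["enabled"]:
        verdicts = []
        n_ens = int(config["robustness"]["n_alignments"])
        for rec in records:
            if not rec.significant:
                continue
            ensemble = make_ensemble(
                alignments[rec.gene_id], rec.gene_id, n=n_ens, seed=seed + 17
            )
            verdict, _ = robust_test(
                ensemble, species_tree, rec.foreground, rec.test_type,
                original_q=rec.q, n_starts=n_starts, seed=seed,
            )
            verdicts.append(vars(verdict))
        pd.DataFrame(verdicts).to_csv(
            outdir / "robustness.tsv", sep="\t", index=False, float_format=float_fmt
        )
        manifest["stages"]["robustness"] = {
            "n_reexamined": len(verdicts),
            "n_passing_95pct": int(sum(v["passes_95pct"] for v in verdicts)),
            "seconds": round(time.time() - t0, 2),
        }

    # ----------------------------------------------------------- enrichment
    t0 = time.time()
    enrich_cfg = config["enrichment"]
    if config.get("inputs") and config["inputs"].get("annotations"):
        annotations = AnnotationMap.from_tsv(config["inputs"]["annotations"])
    else:
        gene_sets, names, _, _ = simulate_annotation_set(
            n_genes=len(genes),
            n_categories=int(enrich_cfg["n_categories"]),
            planted_category=enrich_cfg.get("planted_category"),
            odds=float(enrich_cfg["odds"]),
            seed=seed + 23,
        )
        remap = dict(zip(sorted(gene_sets), genes))
        annotations = AnnotationMap(
            gene_to_categories={remap[g]: cats for g, cats in gene_sets.items()},
            names=names,
        )
    scans = []
    for fg_name, fg_spec in config["foregrounds"].items():
        fg_branch = species_tree.resolve_branch(fg_spec)
        fg_records = [r for r in records if r.foreground == fg_branch]
        scan = enrichment_scan(
            annotations.categories(), fg_records, annotations, fdr=float(config["fdr"])
        )
        scan.insert(0, "foreground", fg_name)
        scans.append(scan)
    enrich_frame = pd.concat(scans, ignore_index=True) if scans else pd.DataFrame()
    enrich_frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format=float_fmt)
    manifest["stages"]["enrichment"] = {
        "n_rows": len(enrich_frame),
        "n_significant": int(enrich_frame["significant"].sum()) if len(enrich_frame) else 0,
        "seconds": round(time.time() - t0, 2),
    }

    # ---------------------------------------------------------- genome stats
    t0 = time.time()
    het_cfg = config["het"]
    chrom_lengths = {str(k): int(v) for k, v in het_cfg["chrom_lengths"].items()}
    sites, truth_payload, _ = simulate_variant_sites(
        chrom_lengths,
        het_rate=float(het_cfg["het_rate"]),
        depth_mean=float(het_cfg["depth_mean"]),
        error_rate=float(het_cfg["error_rate"]),
        seed=seed + 31,
    )
    write_sites_tsv(sites, outdir / "sites.tsv")
    autosome_map = {c: ("Z" if c.endswith("Z") else c) for c in chrom_lengths}
    kept, _report = filter_sites(
        sites,
        min_depth=int(het_cfg["min_depth"]),
        min_qual=int(het_cfg["min_qual"]),
        min_maf=float(het_cfg["min_maf"]),
        chrom_map=autosome_map,
        autosomes_only=True,
    )
    autosomes = {
        c: truth_payload["callable_lengths"][c]
        for c in chrom_lengths
        if autosome_map[c] not in ("Z", "W")
    }
    per_chrom, total = het_per_kb(kept, autosomes)
    het_frame = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "callable_bases": s.callable_bases,
                "het_bases": s.het_bases,
                "het_per_kb": round(s.het_per_kb, 4),
            }
            for s in per_chrom + [total]
        ]
    )
    het_frame.to_csv(outdir / "het.tsv", sep="\t", index=False, float_format=float_fmt)

    psmc_kept, _ = filter_sites(
        sites,
        min_depth=int(het_cfg["psmc_min_depth"]),
        max_depth=int(het_cfg["psmc_max_depth"]),
        min_qual=int(het_cfg["min_qual"]),
        min_maf=float(het_cfg["min_maf"]),
        chrom_map=autosome_map,
        autosomes_only=True,
    )
    psmc_records = make_psmcfa(
        psmc_kept, {c: L for c, L in chrom_lengths.items() if c in autosomes}
    )
    write_psmcfa(psmc_records, outdir / "psmc.psmcfa")
    manifest["stages"]["genome_stats"] = {
        "n_sites": len(sites),
        "n_het_retained": len(kept),
        "het_per_kb": round(total.het_per_kb, 4),
        "n_psmcfa_records": len(psmc_records),
        "seconds": round(time.time() - t0, 2),
    }

    manifest["seconds_total"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
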