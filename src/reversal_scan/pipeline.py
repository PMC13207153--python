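"""Stage orchestration: classify -> genes -> enrich, per platform.

Each stage reads its inputs from the configured paths, writes tab-delimited
result tables under ``out_dir``, and reconciles counts in the log. All
randomness (the gene-stage Monte Carlo fallback) derives from the single
config seed, so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from reversal_scan import io as rio
from reversal_scan.classify import classify_all
from reversal_scan.config import PipelineConfig
from reversal_scan.enrich import (
    assign_categories,
    cross_platform_shared,
    enrich,
    read_category_map,
)
from reversal_scan.genes import run_gene_analysis
from reversal_scan.harmonize import apply_qc, harmonize_alleles
from reversal_scan.simulate import write_fixture_bundle

logger = logging.getLogger(__name__)

PLATFORMS = ("platform1", "platform2")
CLASSES = ("reversal", "stable")


def _platform_inputs(cfg: PipelineConfig, platform: str) -> tuple[str, str]:
    pre = getattr(cfg.inputs, f"{platform}_pre")
    post = getattr(cfg.inputs, f"{platform}_post")
    return pre, post


def _configured_platforms(cfg: PipelineConfig) -> list[str]:
    return [p for p in PLATFORMS if all(_platform_inputs(cfg, p))]


def run_simulate(cfg: PipelineConfig, fixture_dir: str | Path | None = None) -> dict[str, Path]:
    out = Path(fixture_dir) if fixture_dir else Path(cfg.out_dir) / "fixture"
    return write_fixture_bundle(cfg.simulate, out)


def run_classify(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """QC, harmonization, and heterogeneity classification per platform."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}
    for platform in _configured_platforms(cfg):
        pre_path, post_path = _platform_inputs(cfg, platform)
        ds_pre = rio.read_sumstats(pre_path, "pre", platform)
        ds_post = rio.read_sumstats(post_path, "post", platform)
        n_in = len(ds_pre) + len(ds_post)
        ds_pre, ds_post, qc_report = apply_qc(ds_pre, ds_post, cfg.qc)
        pairs, harm_report = harmonize_alleles(ds_pre, ds_post, ambiguous_policy=cfg.ambiguous_policy)
        classified, counts = classify_all(pairs, cfg.classify)
        logger.info(
            "%s: %d input rows -> %d harmonized pairs -> %s",
            platform,
            n_in,
            len(pairs),
            counts,
        )
        qc = pd.concat([qc_report.to_frame().assign(stage="qc"), harm_report.to_frame().assign(stage="harmonize")])
        qc.to_csv(out / f"qc_report_{platform}.tsv", sep="\t", index=False)
        classified.to_csv(out / f"classified_{platform}.tsv", sep="\t", index=False)
        for label in CLASSES:
            rio.write_magma_input(
                classified,
                label,
                out / f"magma_{platform}_{label}.snploc.tsv",
                out / f"magma_{platform}_{label}.pval.tsv",
            )
        results[platform] = classified
    if not results:
        raise ValueError("no platform has both pre and post summary-statistics paths configured")
    return results


def run_genes(cfg: PipelineConfig, classified: dict[str, pd.DataFrame] | None = None) -> dict[tuple[str, str], pd.DataFrame]:
    """LD-aware gene-level analysis per platform and variant class."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_locs = rio.read_gene_locations(cfg.inputs.gene_locations)
    panel = rio.read_reference_genotypes(cfg.inputs.reference_panel)
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for platform in _configured_platforms(cfg):
        if classified is not None and platform in classified:
            table = classified[platform]
        else:
            path = out / f"classified_{platform}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"classified table {path} not found; run the classify stage first")
            table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for i, label in enumerate(CLASSES):
            res = run_gene_analysis(
                table,
                gene_locs,
                panel,
                label,
                window_bp=cfg.genes.window_bp,
                mc_draws=cfg.genes.mc_draws,
                seed=cfg.seed * 10 + i,
                retain_alpha=cfg.genes.retain_alpha,
            )
            res.to_csv(out / f"genes_{platform}_{label}.tsv", sep="\t", index=False)
            results[(platform, label)] = res
    return results


def run_enrich(
    cfg: PipelineConfig,
    gene_results: dict[tuple[str, str], pd.DataFrame] | None = None,
) -> dict[str, pd.DataFrame]:
    """Gene-set enrichment per platform/class plus cross-platform shared pathways."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets = rio.read_gmt(cfg.inputs.gene_sets)
    category_map = read_category_map(cfg.inputs.category_map) if cfg.inputs.category_map else None

    def _load(platform: str, label: str) -> pd.DataFrame:
        if gene_results is not None and (platform, label) in gene_results:
            return gene_results[(platform, label)]
        path = out / f"genes_{platform}_{label}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"gene table {path} not found; run the genes stage first")
        return pd.read_csv(path, sep="\t", dtype={"GENE": str})

    enrichments: dict[tuple[str, str], pd.DataFrame] = {}
    for platform in _configured_platforms(cfg):
        tables = {label: _load(platform, label) for label in CLASSES}
        # platform-aware universe: every gene with at least one mapped SNP
        universe = sorted(set().union(*(set(t["GENE"].astype(str)) for t in tables.values() if len(t))))
        for label in CLASSES:
            t = tables[label]
            query = t.loc[t["retained"], "GENE"].astype(str).tolist() if len(t) else []
            rows = enrich(query, universe, sets, min_set=cfg.enrich.min_set, max_set=cfg.enrich.max_set)
            serial = rows.copy()
            if len(serial):
                serial["genes_overlap"] = serial["genes_overlap"].map(lambda g: ",".join(g))
            serial.to_csv(out / f"enrichment_{platform}_{label}.tsv", sep="\t", index=False)
            enrichments[(platform, label)] = rows
            if category_map is not None:
                counts = assign_categories(query, category_map)
                pd.DataFrame(sorted(counts.items()), columns=["category", "count"]).to_csv(
                    out / f"categories_{platform}_{label}.tsv", sep="\t", index=False
                )

    shared: dict[str, pd.DataFrame] = {}
    platforms = _configured_platforms(cfg)
    if len(platforms) == 2:
        for label in CLASSES:
            sp = cross_platform_shared(
                enrichments[(platforms[0], label)],
                enrichments[(platforms[1], label)],
                criterion=cfg.enrich.criterion,
                alpha=cfg.enrich.alpha,
            )
            serial = sp.copy()
            for col in ("genes_platform1", "genes_platform2"):
                if len(serial):
                    serial[col] = serial[col].map(lambda g: ",".join(g))
            serial.to_csv(out / f"shared_pathways_{label}.tsv", sep="\t", index=False)
            shared[label] = sp
    return shared


def run_all(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    classified = run_classify(cfg)
    gene_results = run_genes(cfg, classified)
    return run_enrich(cfg, gene_results)
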