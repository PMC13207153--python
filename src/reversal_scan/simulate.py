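"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the statistical structure the pipeline assumes: two
strata (pre/post) of Wald summary statistics over genes with AR(1)
within-gene LD, containing planted reversal variants (opposite-sign true
effects), stable variants (shared true effect), nulls, and one-sided
signals; a fraction of post-stratum records carries swapped allele coding
(which harmonization must undo) and a fraction of variants is assigned
palindromic A/T or C/G allele pairs. A matching 0/1/2 reference panel is
drawn from the same latent-Gaussian LD model, and the fixture bundle adds a
second platform as a partially overlapping variant subset with re-sampled
noise, so SNP-level overlap is limited while pathway-level signal is shared.

Estimates are internally consistent: beta-hat = true beta + N(0, SE) noise,
SE = se_scale / sqrt(2 * maf * (1 - maf) * N), and p is the two-sided Wald
p-value of beta-hat / SE. Fixed seed implies byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from reversal_scan.io import write_reference_genotypes, write_sumstats
from reversal_scan.models import ReferencePanel, SummaryDataset

logger = logging.getLogger(__name__)

TRUE_CLASSES = ("reversal", "stable", "null", "one_sided")

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("C", "A"), ("G", "A"), ("T", "C"), ("T", "G")]
_PALINDROMIC = [("A", "T"), ("C", "G"), ("T", "A"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic paired-summary-statistics draw.

    Cohort sizes default to 1,500 premenopausal and 2,200 postmenopausal
    samples; with MAFs in [0.05, 0.5] this puts per-variant SEs near 0.05.
    Planted effect sizes of 0.5 give essentially complete single-variant
    power at those SEs. Class fractions leave a 10% remainder of one-sided
    signals (nominally associated in a single stratum only).
    """

    seed: int = 13
    n_pre: int = 1500
    n_post: int = 2200
    n_genes: int = 400
    snps_per_gene: tuple[int, int] = (3, 7)
    ld_rho: float = 0.5
    frac_reversal: float = 0.15
    frac_stable: float = 0.15
    frac_null: float = 0.60
    beta_reversal: float = 0.5
    beta_stable: float = 0.5
    se_scale: float = 1.0
    frac_allele_swap: float = 0.30
    frac_palindromic: float = 0.10
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_ref_samples: int = 500
    platform2_overlap: float = 0.70

    def __post_init__(self) -> None:
        fracs = (self.frac_reversal, self.frac_stable, self.frac_null, self.frac_allele_swap, self.frac_palindromic)
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_reversal + self.frac_stable + self.frac_null > 1 + 1e-12:
            raise ValueError("class fractions must sum to at most 1")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValueError("snps_per_gene range invalid")

    @property
    def frac_one_sided(self) -> float:
        return max(0.0, 1.0 - self.frac_reversal - self.frac_stable - self.frac_null)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def _variant_frame(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic layout shared by the panel and both platforms: gene
    placement, variant positions, MAFs, allele pairs, true classes/effects."""
    rng = _rng(cfg, 0)
    lo, hi = cfg.snps_per_gene
    m_per_gene = rng.integers(lo, hi + 1, size=cfg.n_genes)
    rows = []
    snp_counter = 0
    for g in range(cfg.n_genes):
        gene_id = str(10001 + g)
        chrom = str((g % 22) + 1)
        start = 1_000_000 + (g // 22) * 500_000
        m = int(m_per_gene[g])
        for j in range(m):
            rows.append(
                {
                    "snp_id": f"rs{snp_counter + 1:07d}",
                    "gene_id": gene_id,
                    "symbol": f"SIMG{g + 1:04d}",
                    "gene_idx": g,
                    "chrom": chrom,
                    "gene_start": start,
                    "gene_end": start + 1000 * (m + 1),
                    "pos": start + 1000 * (j + 1),
                }
            )
            snp_counter += 1
    df = pd.DataFrame(rows)
    n = len(df)

    df["maf"] = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    probs = [cfg.frac_reversal, cfg.frac_stable, cfg.frac_null, cfg.frac_one_sided]
    df["true_class"] = rng.choice(TRUE_CLASSES, size=n, p=probs)
    sign = rng.choice([-1.0, 1.0], size=n)
    one_sided_pre = rng.random(n) < 0.5

    beta_pre = np.zeros(n)
    beta_post = np.zeros(n)
    is_rev = (df["true_class"] == "reversal").to_numpy()
    is_stab = (df["true_class"] == "stable").to_numpy()
    is_one = (df["true_class"] == "one_sided").to_numpy()
    beta_pre[is_rev] = sign[is_rev] * cfg.beta_reversal
    beta_post[is_rev] = -sign[is_rev] * cfg.beta_reversal
    beta_pre[is_stab] = sign[is_stab] * cfg.beta_stable
    beta_post[is_stab] = sign[is_stab] * cfg.beta_stable
    beta_pre[is_one & one_sided_pre] = sign[is_one & one_sided_pre] * cfg.beta_stable
    beta_post[is_one & ~one_sided_pre] = sign[is_one & ~one_sided_pre] * cfg.beta_stable
    df["true_beta_pre"] = beta_pre
    df["true_beta_post"] = beta_post

    df["is_palindromic"] = rng.random(n) < cfg.frac_palindromic
    pal_idx = rng.integers(0, len(_PALINDROMIC), size=n)
    non_idx = rng.integers(0, len(_NONPALINDROMIC), size=n)
    alleles = [
        _PALINDROMIC[pal_idx[i]] if df["is_palindromic"].iat[i] else _NONPALINDROMIC[non_idx[i]]
        for i in range(n)
    ]
    df["effect_allele"] = [a for a, _ in alleles]
    df["other_allele"] = [b for _, b in alleles]
    df["was_allele_swapped"] = rng.random(n) < cfg.frac_allele_swap
    return df


def _draw_stratum(
    variants: pd.DataFrame,
    n_samples: int,
    true_beta: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    stratum: str,
    platform: str,
) -> SummaryDataset:
    n = len(variants)
    maf = variants["maf"].to_numpy()
    se = cfg.se_scale / np.sqrt(2.0 * maf * (1.0 - maf) * n_samples)
    beta_hat = true_beta + rng.normal(0.0, se)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(beta_hat / se)), 1e-300)
    df = pd.DataFrame(
        {
            "snp_id": variants["snp_id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "effect_allele": variants["effect_allele"].to_numpy(),
            "other_allele": variants["other_allele"].to_numpy(),
            "beta": beta_hat,
            "se": se,
            "maf": maf,
            "n": np.full(n, n_samples, dtype=np.int64),
            "p": p,
            "hwe_p": rng.uniform(0.01, 1.0, size=n),
        }
    )
    if stratum == "post":
        swap = variants["was_allele_swapped"].to_numpy()
        ea = df["effect_allele"].to_numpy().copy()
        oa = df["other_allele"].to_numpy().copy()
        df.loc[swap, "effect_allele"] = oa[swap]
        df.loc[swap, "other_allele"] = ea[swap]
        df.loc[swap, "beta"] = -df.loc[swap, "beta"]
        # the maf column is a minor-allele frequency, invariant to coding
    return SummaryDataset(stratum=stratum, platform=platform, records=df)


def simulate_paired_sumstats(
    cfg: SimulationConfig,
    platform: str = "platform1",
    noise_stream: int = 1,
) -> tuple[SummaryDataset, SummaryDataset, pd.DataFrame]:
    """Draw one platform's pre/post summary statistics plus the truth table.

    ``noise_stream`` selects an independent noise substream so a second
    platform re-samples estimation noise over the same true effects.
    """
    variants = _variant_frame(cfg)
    rng = _rng(cfg, noise_stream)
    ds_pre = _draw_stratum(variants, cfg.n_pre, variants["true_beta_pre"].to_numpy(), cfg, rng, "pre", platform)
    ds_post = _draw_stratum(variants, cfg.n_post, variants["true_beta_post"].to_numpy(), cfg, rng, "post", platform)
    truth = variants[
        [
            "snp_id",
            "true_class",
            "true_beta_pre",
            "true_beta_post",
            "gene_id",
            "symbol",
            "is_palindromic",
            "was_allele_swapped",
        ]
    ].copy()
    return ds_pre, ds_post, truth


def simulate_reference_panel(cfg: SimulationConfig, n_samples: int) -> ReferencePanel:
    """Draw a 0/1/2 dosage panel matching the simulated variants' LD.

    Per gene, a latent Gaussian vector with AR(1) correlation ``ld_rho`` is
    thresholded at each variant's Hardy-Weinberg genotype-frequency quantiles
    (counted allele = the simulated effect allele). On the genotype scale
    adjacent-variant correlation attenuates toward roughly ld_rho^2.
    """
    if n_samples < 2:
        raise ValueError("reference panel needs at least 2 samples")
    variants = _variant_frame(cfg)
    rng = _rng(cfg, 9)
    genos = np.empty((n_samples, len(variants)), dtype=float)
    col = 0
    for _, gene in variants.groupby("gene_idx", sort=True):
        m = len(gene)
        eps = rng.standard_normal((n_samples, m))
        z = np.empty((n_samples, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            z[:, j] = cfg.ld_rho * z[:, j - 1] + np.sqrt(1.0 - cfg.ld_rho**2) * eps[:, j]
        f = gene["maf"].to_numpy()
        q0 = stats.norm.ppf((1.0 - f) ** 2)
        q1 = stats.norm.ppf((1.0 - f) ** 2 + 2.0 * f * (1.0 - f))
        g = np.zeros((n_samples, m))
        g[z >= q0] = 1.0
        g[z >= q1] = 2.0
        genos[:, col : col + m] = g
        col += m
    return ReferencePanel(variant_ids=variants["snp_id"].tolist(), genotypes=genos)


def _gene_sets_for(cfg: SimulationConfig, variants: pd.DataFrame, rng: np.random.Generator) -> list[tuple[str, str, list[str]]]:
    """Random gene sets plus one set loaded with reversal-hosting genes."""
    gene_ids = variants.drop_duplicates("gene_id")["gene_id"].tolist()
    reversal_genes = variants.loc[variants["true_class"] == "reversal", "gene_id"].drop_duplicates().tolist()
    other_genes = [g for g in gene_ids if g not in set(reversal_genes)]
    planted = reversal_genes[: max(5, len(reversal_genes))]
    if other_genes:
        planted = planted + list(rng.choice(other_genes, size=min(2, len(other_genes)), replace=False))
    sets = [("SIM:REV01", "planted_reversal_pathway", planted)]
    for s in range(10):
        size = int(rng.integers(5, 31))
        members = list(rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False))
        sets.append((f"SIM:RAND{s + 1:02d}", f"random_set_{s + 1}", members))
    return sets


def write_fixture_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete synthetic bundle to ``out_dir``.

    Emits two platforms x two strata of summary statistics (platform 2 is a
    partially overlapping variant subset with independent noise), the
    gene-location file, a GMT file including one set enriched for
    reversal-hosting genes, the reference panel, the truth table, and the
    configuration used. Deterministic given the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants = _variant_frame(cfg)

    paths: dict[str, Path] = {}
    p1_pre, p1_post, truth = simulate_paired_sumstats(cfg, platform="platform1", noise_stream=1)
    p2_pre_full, p2_post_full, _ = simulate_paired_sumstats(cfg, platform="platform2", noise_stream=2)
    keep_rng = _rng(cfg, 3)
    keep = keep_rng.random(len(variants)) < cfg.platform2_overlap
    p2_pre = SummaryDataset("pre", "platform2", p2_pre_full.records.loc[keep].reset_index(drop=True))
    p2_post = SummaryDataset("post", "platform2", p2_post_full.records.loc[keep].reset_index(drop=True))

    for name, ds in [
        ("platform1_pre", p1_pre),
        ("platform1_post", p1_post),
        ("platform2_pre", p2_pre),
        ("platform2_post", p2_post),
    ]:
        paths[name] = out / f"{name}.tsv"
        write_sumstats(ds, paths[name])

    genes = variants.drop_duplicates("gene_id")[["gene_id", "chrom", "gene_start", "gene_end", "symbol"]]
    paths["gene_locations"] = out / "gene_locations.tsv"
    with open(paths["gene_locations"], "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{g.gene_id} {g.chrom} {g.gene_start} {g.gene_end} + {g.symbol}\n")

    paths["gene_sets"] = out / "gene_sets.gmt"
    set_rng = _rng(cfg, 4)
    with open(paths["gene_sets"], "w") as fh:
        for set_id, name, members in _gene_sets_for(cfg, variants, set_rng):
            fh.write("\t".join([set_id, name] + list(members)) + "\n")

    panel = simulate_reference_panel(cfg, cfg.n_ref_samples)
    paths["reference_panel"] = out / "reference_panel.tsv"
    write_reference_genotypes(panel, paths["reference_panel"])

    paths["truth_table"] = out / "truth_table.tsv"
    truth.to_csv(paths["truth_table"], sep="\t", index=False)

    paths["config"] = out / "simulation_config.yaml"
    cfg_dict = asdict(cfg)
    cfg_dict["snps_per_gene"] = list(cfg.snps_per_gene)
    cfg_dict["maf_range"] = list(cfg.maf_range)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    logger.info("fixture bundle written to %s (%d variants, %d genes)", out, len(variants), cfg.n_genes)
    return paths
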