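"""File readers and writers for every format the pipeline touches.

Summary statistics are tab-delimited with a header naming at least the ten
required columns (SNP, CHR, BP, A1, A2, BETA, SE, MAF, N, P; HWE_P optional).
Gene locations follow the NCBI gene-location convention (whitespace table,
1-based inclusive coordinates). Gene sets arrive as GMT. The LD reference
panel is a tab-delimited 0/1/2 dosage matrix with variant ids in the header.
Gene-stage exports mirror the SNP-location and p-value file layout consumed
by gene-based association tools.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from reversal_scan.models import (
    DEFAULT_HEADER_MAP,
    SUMSTATS_COLUMNS,
    VALID_ALLELES,
    GeneSet,
    GeneSetCollection,
    ReferencePanel,
    SummaryDataset,
)

logger = logging.getLogger(__name__)

_REQUIRED = [c for c in SUMSTATS_COLUMNS if c != "hwe_p"]
_NUMERIC = ["pos", "beta", "se", "maf", "n", "p"]


def read_sumstats(
    path: str | Path,
    stratum: str,
    platform: str = "",
    column_map: dict[str, str] | None = None,
) -> SummaryDataset:
    """Read one stratum's summary-statistics table.

    Rows with unparsable numerics, missing required fields, out-of-range
    values, or non-single-nucleotide alleles are dropped with a logged count.
    A missing required column or a duplicate SNP id is fatal.

    Parameters
    ----------
    column_map:
        Optional mapping from file header names to the internal field names
        (``snp_id``, ``chrom``, ``pos``, ``effect_allele``, ``other_allele``,
        ``beta``, ``se``, ``maf``, ``n``, ``p``, ``hwe_p``); defaults to the
        conventional SNP/CHR/BP/A1/A2/BETA/SE/MAF/N/P/HWE_P headers.
    """
    header_map = dict(DEFAULT_HEADER_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    renamed = raw.rename(columns=header_map)
    for col in _REQUIRED:
        if col not in renamed.columns:
            file_name = next((k for k, v in header_map.items() if v == col), col)
            raise ValueError(f"{path}: missing required column {file_name!r}")
    df = renamed[[c for c in SUMSTATS_COLUMNS if c in renamed.columns]].copy()
    if "hwe_p" not in df.columns:
        df["hwe_p"] = np.nan

    n_in = len(df)
    for col in _NUMERIC + ["hwe_p"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].str.upper()

    ok = df[_NUMERIC].notna().all(axis=1)
    ok &= df["snp_id"].str.len() > 0
    ok &= df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    ok &= (df["se"] > 0) & df["maf"].between(0, 0.5) & (df["p"] > 0) & (df["p"] <= 1)
    ok &= (df["n"] > 0) & (df["pos"] > 0)
    ok &= df["hwe_p"].isna() | ((df["hwe_p"] > 0) & (df["hwe_p"] <= 1))

    dropped = int((~ok).sum())
    if dropped:
        logger.warning("%s: dropped %d unparsable/invalid rows", path, dropped)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)

    dup = df["snp_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate snp_id {df.loc[dup, 'snp_id'].iloc[0]!r}")
    return SummaryDataset(stratum=stratum, platform=platform, records=df)


def write_sumstats(ds: SummaryDataset, path: str | Path) -> None:
    """Write a dataset back to the tab-delimited contract (round-trip safe)."""
    inv = {v: k for k, v in DEFAULT_HEADER_MAP.items()}
    out = ds.records[SUMSTATS_COLUMNS].rename(columns=inv)
    if out["HWE_P"].isna().all():
        out = out.drop(columns=["HWE_P"])
    # repr-based float formatting keeps tiny p-values (1e-300) intact
    out.to_csv(path, sep="\t", index=False, float_format=None)


def read_gene_locations(path: str | Path) -> pd.DataFrame:
    """Read a gene-location table: gene_id chrom start end [strand] [symbol].

    Coordinates are 1-based inclusive. Rows with end < start are rejected
    with a warning. Returns columns gene_id, chrom, start, end, strand,
    symbol (symbol falls back to gene_id when absent).
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 4:
                n_bad += 1
                continue
            gene_id, chrom, start_s, end_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                n_bad += 1
                continue
            if start > end:
                n_bad += 1
                continue
            strand = fields[4] if len(fields) > 4 else "."
            symbol = fields[5] if len(fields) > 5 else gene_id
            rows.append((gene_id, chrom, start, end, strand, symbol))
    if n_bad:
        logger.warning("%s: rejected %d malformed gene-location rows", path, n_bad)
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "symbol"])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (set_id TAB description TAB genes...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: GMT line with <3 fields rejected", path, lineno)
                continue
            set_id, name = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("%s:%d: duplicate gene ids in set %s deduplicated", path, lineno, set_id)
            if not deduped:
                logger.warning("%s:%d: empty gene set %s rejected", path, lineno, set_id)
                continue
            coll.sets[set_id] = GeneSet(set_id=set_id, name=name, genes=tuple(deduped))
    return coll


def read_reference_genotypes(path: str | Path) -> ReferencePanel:
    """Read a samples-by-variants 0/1/2 dosage matrix (header = variant ids).

    Missing entries may be coded NA, NaN, "." or empty; anything else outside
    {0, 1, 2} is fatal. All-missing or monomorphic columns are retained but
    flagged via :attr:`ReferencePanel.monomorphic`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    variant_ids = list(df.columns)
    cleaned = df.where(~df.isin(["NA", "NaN", "nan", ".", ""]))
    mat = cleaned.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(mat) & cleaned.notna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-genotype entry {df.iat[r, c]!r} at row {r + 1}, variant {variant_ids[c]}")
    valid = np.isnan(mat) | np.isin(mat, (0.0, 1.0, 2.0))
    if not valid.all():
        r, c = np.argwhere(~valid)[0]
        raise ValueError(f"{path}: genotype entry {mat[r, c]!r} outside {{0,1,2,NA}} at row {r + 1}, variant {variant_ids[c]}")
    panel = ReferencePanel(variant_ids=variant_ids, genotypes=mat)
    n_mono = int(panel.monomorphic.sum())
    if n_mono:
        logger.warning("%s: %d monomorphic/unusable variant columns", path, n_mono)
    return panel


def write_reference_genotypes(panel: ReferencePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.genotypes, columns=panel.variant_ids)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def write_magma_input(
    classified: pd.DataFrame,
    class_filter: str,
    snp_loc_path: str | Path,
    pval_path: str | Path,
) -> int:
    """Export one class of variants for gene-stage analysis.

    Writes a SNP-location file (SNP, CHR, BP) and a p-value file (SNP, P, N)
    where P is the smaller of the two stratum p-values and N is the sample
    size of the stratum contributing that minimum (ties resolved toward the
    pre stratum, the harmonization reference). Returns the row count.
    """
    if class_filter not in ("reversal", "stable"):
        raise ValueError(f"class_filter must be 'reversal' or 'stable', got {class_filter!r}")
    sel = classified.loc[classified["label"] == class_filter]
    take_pre = sel["p_pre"] <= sel["p_post"]
    out = pd.DataFrame(
        {
            "SNP": sel["snp_id"],
            "P": sel["p_pre"].where(take_pre, sel["p_post"]),
            "N": sel["n_pre"].where(take_pre, sel["n_post"]).astype(np.int64),
        }
    )
    loc = pd.DataFrame({"SNP": sel["snp_id"], "CHR": sel["chrom"], "BP": sel["pos"]})
    if sel.empty:
        logger.warning("no variants with label %s; writing header-only files", class_filter)
    loc.to_csv(snp_loc_path, sep="\t", index=False)
    out.to_csv(pval_path, sep="\t", index=False)
    return len(sel)
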