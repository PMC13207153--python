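"""Gene-set over-representation, BH correction, functional categories, and
cross-platform shared-pathway intersection.

Enrichment is the one-sided hypergeometric upper tail of the overlap between
a query gene list and each set within a stated universe (equivalently a
one-sided Fisher exact test), with Benjamini-Hochberg adjustment across the
tested sets. The cross-platform step intersects the pathways significant on
both genotyping platforms, carrying both p-values and overlap gene lists.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from reversal_scan.models import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_id", "set_name", "k", "K", "n", "N", "genes_overlap", "p_raw", "p_adj"]


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided upper-tail hypergeometric p: P(overlap >= k) when drawing
    n genes from a universe of N containing K set members."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_genes,
    universe_genes,
    sets: GeneSetCollection,
    min_set: int = 3,
    max_set: int = 500,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each gene set.

    Query genes outside the universe are dropped with a warning; duplicates
    are removed; sets are restricted to the universe and kept only when
    their restricted size lies in [min_set, max_set]. BH adjustment runs
    across the surviving sets only. Rows are sorted by raw p (ties by
    set_id), so output is invariant to input gene order.
    """
    universe = list(dict.fromkeys(str(g) for g in universe_genes))
    uni = set(universe)
    query = list(dict.fromkeys(str(g) for g in query_genes))
    outside = [g for g in query if g not in uni]
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
    query = [g for g in query if g in uni]
    if not query:
        logger.warning("empty query gene list; no enrichment computed")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    qset = set(query)
    N, n = len(uni), len(query)
    rows = []
    for gs in sets:
        members = [g for g in gs.genes if g in uni]
        K = len(members)
        if not (min_set <= K <= max_set):
            continue
        overlap = [g for g in members if g in qset]
        k = len(overlap)
        rows.append(
            {
                "set_id": gs.set_id,
                "set_name": gs.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "genes_overlap": tuple(overlap),
                "p_raw": hypergeom_p(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out = out.sort_values(["p_raw", "set_id"], kind="mergesort").reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS]


def cross_platform_shared(
    rows_p1: pd.DataFrame,
    rows_p2: pd.DataFrame,
    criterion: str = "raw_p",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathways significant on both platforms under the chosen criterion.

    ``criterion`` selects raw (exploratory, the default) or BH-adjusted
    p-values; output carries both platforms' p-values and overlap gene
    lists, sorted by the worse of the two p-values.
    """
    if criterion not in ("raw_p", "adjusted_p"):
        raise ValueError(f"unknown criterion {criterion!r}")
    col = "p_raw" if criterion == "raw_p" else "p_adj"
    cols = ["set_id", "set_name", col, "genes_overlap"]
    empty = pd.DataFrame(
        columns=["set_id", "set_name", "p_platform1", "p_platform2", "genes_platform1", "genes_platform2"]
    )
    if rows_p1.empty or rows_p2.empty:
        return empty
    if not set(rows_p1["set_id"]) & set(rows_p2["set_id"]):
        logger.warning("platforms share no gene-set ids; empty shared-pathway output")
        return empty
    sig1 = rows_p1.loc[rows_p1[col] < alpha, cols]
    sig2 = rows_p2.loc[rows_p2[col] < alpha, cols]
    merged = sig1.merge(sig2, on="set_id", suffixes=("_1", "_2"))
    out = pd.DataFrame(
        {
            "set_id": merged["set_id"],
            "set_name": merged["set_name_1"],
            "p_platform1": merged[f"{col}_1"],
            "p_platform2": merged[f"{col}_2"],
            "genes_platform1": merged["genes_overlap_1"],
            "genes_platform2": merged["genes_overlap_2"],
        }
    )
    order = np.maximum(out["p_platform1"].to_numpy(), out["p_platform2"].to_numpy())
    out = out.iloc[np.argsort(order, kind="stable")].reset_index(drop=True)
    return out


def read_category_map(path: str | Path) -> dict[str, str]:
    """Read a gene-to-functional-category mapping (gene TAB category).

    A gene mapped more than once keeps its first category, with a warning.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            gene, category = fields[0], fields[1]
            if gene in mapping:
                logger.warning("gene %s mapped to multiple categories; keeping %r", gene, mapping[gene])
                continue
            mapping[gene] = category
    return mapping


def assign_categories(genes, category_map: dict[str, str]) -> dict[str, int]:
    """Count genes per functional category; unmapped genes fall to 'Other'."""
    counts: dict[str, int] = {}
    for g in dict.fromkeys(str(x) for x in genes):
        cat = category_map.get(g, "Other")
        counts[cat] = counts.get(cat, 0) + 1
    return counts
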