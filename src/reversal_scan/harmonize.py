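"""Variant QC and cross-stratum allele harmonization.

Per-stratum filters (MAF >= 0.01, Hardy-Weinberg p >= 1e-6, SE <= 1,
|beta| <= 2) remove unstable association estimates; the joint filter drops
shared variants with no evidence of association in either stratum
(p >= 0.05 in both). Harmonization then aligns the postmenopausal effect
coding onto the premenopausal reference: swapped allele coding inverts the
sign of beta (keeping SE and p) and re-orients the effect-allele frequency,
strand-ambiguous A/T and C/G pairs are dropped by default, and only variants
present in both strata are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from reversal_scan.models import VALID_ALLELES, QCReport, SummaryDataset

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta_pre",
    "se_pre",
    "p_pre",
    "n_pre",
    "maf_pre",
    "beta_post",
    "se_post",
    "p_post",
    "n_post",
    "maf_post",
    "flipped",
]


@dataclass
class QCThresholds:
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    max_se: float = 1.0
    max_abs_beta: float = 2.0
    nominal_alpha: float = 0.05


def _stratum_filter(df: pd.DataFrame, thr: QCThresholds, report: QCReport) -> pd.DataFrame:
    """Apply the per-stratum rules in fixed order; first failing rule wins."""
    fail_maf = df["maf"] < thr.min_maf
    fail_hwe = df["hwe_p"].notna() & (df["hwe_p"] < thr.min_hwe_p) & ~fail_maf
    fail_se = (df["se"] > thr.max_se) & ~fail_maf & ~fail_hwe
    fail_beta = (df["beta"].abs() > thr.max_abs_beta) & ~fail_maf & ~fail_hwe & ~fail_se
    report.add("maf", int(fail_maf.sum()))
    report.add("hwe", int(fail_hwe.sum()))
    report.add("se_gt_1", int(fail_se.sum()))
    report.add("abs_beta_gt_2", int(fail_beta.sum()))
    return df.loc[~(fail_maf | fail_hwe | fail_se | fail_beta)]


def apply_qc(
    ds_pre: SummaryDataset,
    ds_post: SummaryDataset,
    thresholds: QCThresholds | None = None,
) -> tuple[SummaryDataset, SummaryDataset, QCReport]:
    """Apply variant QC to both strata.

    Per-stratum rules run within each dataset (rule counts are summed over
    the two strata). The no-association rule (p >= nominal_alpha in both
    strata) is evaluated once on the shared-id set and removes the variant
    from both datasets, counted once.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(n_input=len(ds_pre) + len(ds_post))
    pre = _stratum_filter(ds_pre.records, thr, report)
    post = _stratum_filter(ds_post.records, thr, report)

    shared = pre.merge(post[["snp_id", "p"]], on="snp_id", suffixes=("", "_post"))
    dull = shared.loc[(shared["p"] >= thr.nominal_alpha) & (shared["p_post"] >= thr.nominal_alpha), "snp_id"]
    report.add("p_ge_0.05_both", len(dull))
    drop = set(dull)
    pre = pre.loc[~pre["snp_id"].isin(drop)].reset_index(drop=True)
    post = post.loc[~post["snp_id"].isin(drop)].reset_index(drop=True)
    # joint removals hit both strata but are counted once
    report.n_retained = report.n_input - report.n_removed - len(drop)
    if pre.empty or post.empty:
        logger.warning("QC left an empty dataset (pre=%d, post=%d survivors)", len(pre), len(post))
    return (
        SummaryDataset(ds_pre.stratum, ds_pre.platform, pre),
        SummaryDataset(ds_post.stratum, ds_post.platform, post),
        report,
    )


def is_strand_ambiguous(effect_allele: str, other_allele: str) -> bool:
    """True iff the pair is palindromic (A/T or C/G), hence strand-ambiguous."""
    a, b = effect_allele.upper(), other_allele.upper()
    if a not in VALID_ALLELES or b not in VALID_ALLELES:
        raise ValueError(f"non-ACGT allele in pair ({effect_allele!r}, {other_allele!r})")
    return _COMPLEMENT[a] == b


def harmonize_alleles(
    ds_pre: SummaryDataset,
    ds_post: SummaryDataset,
    ambiguous_policy: str = "drop",
    maf_rescue_threshold: float = 0.4,
) -> tuple[pd.DataFrame, QCReport]:
    """Align post-stratum effect coding onto the pre-stratum reference.

    For each variant present in both strata: matching allele coding is copied
    through; swapped coding inverts the post beta sign and re-orients the
    post effect-allele frequency (maf := 1 - maf), keeping SE and p; under
    ``maf_rescue`` strand complements are mapped before the comparison and
    palindromic pairs are kept when both strata report MAF below the rescue
    threshold (orientation then inferable from frequency); anything else is
    an allele mismatch. Palindromic pairs are dropped under the default
    ``drop`` policy. Returns the harmonized table plus a report whose counts,
    together with the emitted pairs, partition the shared-id set.
    """
    if ambiguous_policy not in ("drop", "maf_rescue"):
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    pre, post = ds_pre.records, ds_post.records
    merged = pre.merge(post, on="snp_id", suffixes=("_pre", "_post"), how="outer", indicator=True)
    report = QCReport(n_input=merged["snp_id"].nunique())
    report.add("not_shared", int((merged["_merge"] != "both").sum()))
    both = merged.loc[merged["_merge"] == "both"].reset_index(drop=True)

    rows = []
    n_ambig = n_mismatch = 0
    for rec in both.itertuples(index=False):
        ea_pre, oa_pre = rec.effect_allele_pre, rec.other_allele_pre
        ea_post, oa_post = rec.effect_allele_post, rec.other_allele_post
        ambiguous = is_strand_ambiguous(ea_pre, oa_pre)

        if ambiguous and ambiguous_policy == "drop":
            n_ambig += 1
            continue

        flipped = None
        if (ea_post, oa_post) == (ea_pre, oa_pre):
            flipped = False
        elif (ea_post, oa_post) == (oa_pre, ea_pre):
            flipped = True
        elif ambiguous_policy == "maf_rescue" and not ambiguous:
            comp = (_COMPLEMENT[ea_post], _COMPLEMENT[oa_post])
            if comp == (ea_pre, oa_pre):
                flipped = False
            elif comp == (oa_pre, ea_pre):
                flipped = True

        if flipped is None:
            n_mismatch += 1
            continue
        if ambiguous:
            # rescue only when frequency clearly identifies the minor allele
            # in both strata, i.e. orientation is determined
            if not (rec.maf_pre < maf_rescue_threshold and rec.maf_post < maf_rescue_threshold):
                n_ambig += 1
                continue

        beta_post = -rec.beta_post if flipped else rec.beta_post
        maf_post = 1.0 - rec.maf_post if flipped else rec.maf_post
        rows.append(
            (
                rec.snp_id,
                rec.chrom_pre,
                rec.pos_pre,
                ea_pre,
                oa_pre,
                rec.beta_pre,
                rec.se_pre,
                rec.p_pre,
                rec.n_pre,
                rec.maf_pre,
                beta_post,
                rec.se_post,
                rec.p_post,
                rec.n_post,
                maf_post,
                flipped,
            )
        )

    report.add("strand_ambiguous", n_ambig)
    report.add("allele_mismatch", n_mismatch)
    pairs = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    if not pairs.empty:
        pairs["pos"] = pairs["pos"].astype(np.int64)
        pairs["n_pre"] = pairs["n_pre"].astype(np.int64)
        pairs["n_post"] = pairs["n_post"].astype(np.int64)
    report.n_retained = len(pairs)
    logger.info(
        "harmonized %d shared variants (%d ambiguous dropped, %d mismatched, %d not shared)",
        len(pairs),
        n_ambig,
        n_mismatch,
        report.removed["not_shared"],
    )
    return pairs, report
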