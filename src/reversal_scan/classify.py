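"""Heterogeneity testing and reversal/stable variant classification.

For each harmonized variant the difference of the two stratum effects is
tested with

    Z = (beta_pre - beta_post) / sqrt(SE_pre^2 + SE_post^2)
    P_het = 2 * (1 - Phi(|Z|))

Variants with nominal association in at least one stratum are then labeled:

* reversal — significant heterogeneity (P_het < alpha_het), opposite effect
  directions (beta_pre * beta_post < 0), and at least one |beta| at or above
  the minimal magnitude;
* stable — nominally associated in both strata (p < alpha_nominal in both)
  without significant heterogeneity (P_het >= alpha_het);
* excluded otherwise, with an auditable reason code.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from reversal_scan.models import ClassThresholds

logger = logging.getLogger(__name__)

LABELS = ("reversal", "stable", "excluded")

EXCLUSION_REASONS = (
    "no_nominal_assoc",
    "het_but_same_sign",
    "negligible_beta",
    "discordant_no_het",
    "concordant_one_nominal",
)


def het_z(beta_pre: float, se_pre: float, beta_post: float, se_post: float) -> float:
    """Signed heterogeneity Z for the difference of two independent effects."""
    if se_pre <= 0 or se_post <= 0:
        raise ValueError("standard errors must be positive")
    return (beta_pre - beta_post) / math.hypot(se_pre, se_post)

def het_p(z: float) -> float:
    """Two-sided normal p for a heterogeneity Z, precise in the far tail."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def _label_one(
    p_pre: float,
    p_post: float,
    beta_pre: float,
    beta_post: float,
    p_het_val: float,
    thr: ClassThresholds,
) -> tuple[str, str]:
    if p_pre >= thr.alpha_nominal and p_post >= thr.alpha_nominal:
        return "excluded", "no_nominal_assoc"
    opposite = beta_pre * beta_post < 0
    het = p_het_val < thr.alpha_het
    if het and opposite and max(abs(beta_pre), abs(beta_post)) >= thr.min_abs_beta:
        return "reversal", ""
    if p_pre < thr.alpha_nominal and p_post < thr.alpha_nominal and not het:
        return "stable", ""
    if het and opposite:
        return "excluded", "negligible_beta"
    if het:
        return "excluded", "het_but_same_sign"
    if opposite:
        return "excluded", "discordant_no_het"
    return "excluded", "concordant_one_nominal"


def classify(pair: pd.Series | dict, thresholds: ClassThresholds | None = None) -> dict:
    """Classify a single harmonized variant; returns its fields plus
    ``z_het``, ``p_het``, ``label`` and ``exclusion_reason``."""
    thr = thresholds or ClassThresholds()
    rec = dict(pair)
    z = het_z(rec["beta_pre"], rec["se_pre"], rec["beta_post"], rec["se_post"])
    p = het_p(z)
    label, reason = _label_one(rec["p_pre"], rec["p_post"], rec["beta_pre"], rec["beta_post"], p, thr)
    rec.update(z_het=z, p_het=p, label=label, exclusion_reason=reason)
    return rec


def classify_all(
    pairs: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every harmonized variant (vectorized); every row receives
    exactly one label. Returns the table plus per-label counts."""
    thr = thresholds or ClassThresholds()
    out = pairs.copy()
    if out.empty:
        out["z_het"] = pd.Series(dtype=float)
        out["p_het"] = pd.Series(dtype=float)
        out["label"] = pd.Series(dtype=str)
        out["exclusion_reason"] = pd.Series(dtype=str)
        return out, {lab: 0 for lab in LABELS}

    if (out["se_pre"] <= 0).any() or (out["se_post"] <= 0).any():
        raise ValueError("standard errors must be positive")
    z = (out["beta_pre"] - out["beta_post"]) / np.hypot(out["se_pre"], out["se_post"])
    p_het_vals = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    out["z_het"] = z
    out["p_het"] = p_het_vals

    labeled = [
        _label_one(r.p_pre, r.p_post, r.beta_pre, r.beta_post, r.p_het, thr)
        for r in out.itertuples(index=False)
    ]
    out["label"] = [lab for lab, _ in labeled]
    out["exclusion_reason"] = [reason for _, reason in labeled]
    counts = {lab: int((out["label"] == lab).sum()) for lab in LABELS}
    logger.info(
        "classified %d variants: %d reversal, %d stable, %d excluded",
        len(out),
        counts["reversal"],
        counts["stable"],
        counts["excluded"],
    )
    return out, counts


def min_p_for_gene_stage(variant: pd.Series | dict) -> tuple[float, int]:
    """Gene-stage (p, n) for a classified variant: the smaller of the two
    stratum p-values and the sample size of the contributing stratum (ties
    resolved toward the pre stratum, the harmonization reference)."""
    rec = dict(variant)
    if rec.get("label") not in ("reversal", "stable"):
        raise ValueError("min_p_for_gene_stage requires a reversal or stable variant")
    if rec["p_pre"] <= rec["p_post"]:
        return float(rec["p_pre"]), int(rec["n_pre"])
    return float(rec["p_post"]), int(rec["n_post"])
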