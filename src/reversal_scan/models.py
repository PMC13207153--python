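"""In-memory containers shared across pipeline stages.

Tabular data (summary statistics, harmonized pairs, classified variants, gene
results, enrichment rows) travels as pandas DataFrames with documented column
sets; the small dataclasses here carry the non-tabular state alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical internal column order for a summary-statistics table.
SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "maf",
    "n",
    "p",
    "hwe_p",
]

#: Default file header names, mapped onto the internal columns above.
DEFAULT_HEADER_MAP = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "BETA": "beta",
    "SE": "se",
    "MAF": "maf",
    "N": "n",
    "P": "p",
    "HWE_P": "hwe_p",
}

VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryDataset:
    """One stratum's GWAS summary statistics on one platform.

    ``records`` holds one row per variant with the ``SUMSTATS_COLUMNS``
    schema; ``hwe_p`` is NaN when the input carried no Hardy-Weinberg column
    (absent values are treated as passing the HWE filter).
    """

    stratum: str
    platform: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.stratum not in ("pre", "post"):
            raise ValueError(f"stratum must be 'pre' or 'post', got {self.stratum!r}")
        dup = self.records["snp_id"].duplicated()
        if dup.any():
            first = self.records.loc[dup, "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in {self.stratum} dataset: {first!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSet:
    set_id: str
    name: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content) keyed by set id."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


@dataclass
class ReferencePanel:
    """Genotype dosage matrix (samples x variants) for LD estimation.

    Dosages are 0/1/2 copies of the counted allele; missing entries are NaN.
    ``monomorphic`` flags columns with no observed variation (including
    all-missing columns), which are unusable for correlation estimation.
    """

    variant_ids: list[str]
    genotypes: np.ndarray  # float matrix, NaN = missing

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        if self.genotypes.shape[0] < 2:
            raise ValueError("reference panel needs at least 2 samples")
        if self.genotypes.shape[1] != len(self.variant_ids):
            raise ValueError("variant id count does not match matrix width")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant ids in reference panel")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def monomorphic(self) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            sd = np.nanstd(self.genotypes, axis=0)
        return ~(sd > 0)

    def column(self, variant_id: str) -> np.ndarray | None:
        i = self._index.get(variant_id)
        return None if i is None else self.genotypes[:, i]


# Fixed evaluation order of the variant-level QC rules; the first failing
# rule claims the removal so the report is deterministic.
QC_RULES = [
    "maf",
    "hwe",
    "se_gt_1",
    "abs_beta_gt_2",
    "p_ge_0.05_both",
    "strand_ambiguous",
    "allele_mismatch",
    "not_shared",
]


@dataclass
class QCReport:
    """Audit trail of variant removals, one count per rule."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in QC_RULES})

    def add(self, rule: str, count: int = 1) -> None:
        if rule not in self.removed:
            raise KeyError(f"unknown QC rule {rule!r}")
        self.removed[rule] += count

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": c} for r, c in self.removed.items()]
        rows.append({"rule": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


@dataclass
class ClassThresholds:
    """Cutoffs for the reversal/stable variant classification.

    alpha_het:    heterogeneity significance level (P_het below it is
                  significant effect-size heterogeneity).
    alpha_nominal: nominal association level applied to each stratum's p.
    min_abs_beta: minimal effect magnitude; a reversal call needs at least
                  one stratum with |beta| at or above it.
    """

    alpha_het: float = 0.05
    alpha_nominal: float = 0.05
    min_abs_beta: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.alpha_het < 1 and 0 < self.alpha_nominal < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if self.min_abs_beta < 0:
            raise ValueError("min_abs_beta must be non-negative")


@dataclass
class LDMatrix:
    """Pairwise genotype correlations for one gene's mapped SNPs.

    ``R`` is symmetric with unit diagonal, regularized to positive
    semidefinite by clipping negative eigenvalues at zero; ``eigenvalues``
    are the clipped spectrum used as weights in the gene-level null.
    """

    gene_id: str
    snp_ids: list[str]
    R: np.ndarray
    eigenvalues: np.ndarray

    @property
    def m(self) -> int:
        return len(self.snp_ids)
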