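import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from reversal_scan.models import SummaryDataset
from reversal_scan.simulate import SimulationConfig, write_fixture_bundle

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_sumstats(rows, stratum="pre", platform="p1"):
    """Build a SummaryDataset from (snp, chrom, pos, a1, a2, beta, se, maf, n, p[, hwe_p]) tuples."""
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "maf", "n", "p", "hwe_p"]
    padded = [tuple(r) + (np.nan,) * (11 - len(r)) for r in rows]
    df = pd.DataFrame(padded, columns=cols)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return SummaryDataset(stratum=stratum, platform=platform, records=df)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=13, n_genes=60, snps_per_gene=(2, 5), n_ref_samples=300)


@pytest.fixture(scope="session")
def fixture_bundle(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(small_cfg, out)
    return paths
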