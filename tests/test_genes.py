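import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reversal_scan.genes import (
    gene_pvalue_weighted_chisq,
    gene_statistic,
    ld_correlation,
    map_snps_to_genes,
    run_gene_analysis,
    weighted_chisq_sf,
)
from reversal_scan.models import LDMatrix, ReferencePanel


def ar1(m, rho):
    i = np.arange(m)
    return rho ** np.abs(i[:, None] - i[None, :])


def ld_from(R, gene_id="g1"):
    lam = np.clip(np.linalg.eigvalsh(R), 0, None)
    return LDMatrix(gene_id, [f"s{i}" for i in range(len(R))], R, lam)


class TestMapping:
    gene_locs = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "chrom": ["1", "1", "2"],
            "start": [50, 120, 50],
            "end": [150, 200, 150],
            "strand": ["+"] * 3,
            "symbol": ["G1", "G2", "G3"],
        }
    )

    def variants(self, positions, chrom="1"):
        return pd.DataFrame(
            {"snp_id": [f"rs{p}" for p in positions], "chrom": chrom, "pos": positions}
        )

    def test_containment_and_inclusive_bounds(self):
        a = map_snps_to_genes(self.variants([100, 150, 151]), self.gene_locs, 0)
        assert a["g1"] == ["rs100", "rs150"]

    def test_window_extends_mapping(self):
        assert "g1" not in map_snps_to_genes(self.variants([160]), self.gene_locs[:1], 0)
        assert map_snps_to_genes(self.variants([160]), self.gene_locs[:1], 20)["g1"] == ["rs160"]

    def test_multi_mapping_in_overlap(self):
        a = map_snps_to_genes(self.variants([130]), self.gene_locs, 0)
        assert a["g1"] == ["rs130"] and a["g2"] == ["rs130"]

    def test_chromosome_separation(self):
        a = map_snps_to_genes(self.variants([100], chrom="2"), self.gene_locs, 0)
        assert list(a) == ["g3"]


class TestLDCorrelation:
    def panel(self, cols):
        return ReferencePanel(
            variant_ids=[f"s{i}" for i in range(len(cols))],
            genotypes=np.column_stack(cols).astype(float),
        )

    def test_single_snp_identity(self):
        p = self.panel([[0, 1, 2, 1]])
        ld = ld_correlation("g", ["s0"], p)
        np.testing.assert_array_equal(ld.R, [[1.0]])

    def test_perfect_ld(self):
        col = [0, 1, 2, 1, 0, 2]
        ld = ld_correlation("g", ["s0", "s1"], self.panel([col, col]))
        assert ld.R[0, 1] == pytest.approx(1.0)
        assert (ld.eigenvalues >= -1e-12).all()

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(3)
        cols = [rng.integers(0, 3, 1000), rng.integers(0, 3, 1000)]
        ld = ld_correlation("g", ["s0", "s1"], self.panel(cols))
        assert abs(ld.R[0, 1]) < 0.1

    def test_missing_snp_treated_independent(self):
        p = self.panel([[0, 1, 2, 1]])
        ld = ld_correlation("g", ["s0", "absent"], p)
        assert ld.R[0, 1] == 0.0 and ld.R[1, 1] == 1.0

    def test_monomorphic_treated_independent(self):
        ld = ld_correlation("g", ["s0", "s1"], self.panel([[0, 1, 2, 1], [1, 1, 1, 1]]))
        assert ld.R[0, 1] == 0.0

    def test_eigenvalues_sum_to_m(self):
        rng = np.random.default_rng(4)
        cols = [rng.integers(0, 3, 200) for _ in range(6)]
        ld = ld_correlation("g", [f"s{i}" for i in range(6)], self.panel(cols))
        assert ld.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)


class TestGeneStatistic:
    def test_oracle_values(self):
        # frozen 1-df chi-squared quantiles: Q(1-0.05) = 3.8415
        assert gene_statistic([0.05]) == pytest.approx(3.8415, abs=1e-3)
        assert gene_statistic([1.0, 1.0]) == 0.0
        assert gene_statistic([0.05, 1.0]) == pytest.approx(1.9207, abs=1e-3)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            gene_statistic([0.0])
        with pytest.raises(ValueError):
            gene_statistic([1.5])

    def test_tiny_p_floored_finite(self):
        assert np.isfinite(gene_statistic([1e-320]))


class TestWeightedChisq:
    def test_identity_weights_match_gamma_tail(self):
        # mean of m independent chi2_1 is Gamma(m/2, 2/m)
        for m in (2, 5, 10):
            for T in (0.2, 1.0, 2.0, 5.0):
                p, _ = weighted_chisq_sf(m * T, np.ones(m))
                assert p == pytest.approx(stats.gamma.sf(T, a=m / 2, scale=2 / m), abs=1e-8)

    def test_against_monte_carlo_under_ld(self):
        R = ar1(4, 0.7)
        lam = np.linalg.eigvalsh(R)
        rng = np.random.default_rng(11)
        draws = rng.standard_normal((100_000, 4)) @ np.linalg.cholesky(R).T
        t_null = (draws**2).mean(axis=1)
        for T in (1.0, 2.5):
            p, _ = weighted_chisq_sf(4 * T, lam)
            mc = (t_null >= T).mean()
            se = np.sqrt(mc * (1 - mc) / len(t_null))
            assert abs(p - mc) < 3 * se

    def test_monotone_decreasing_in_q(self):
        lam = np.array([2.5, 1.0, 0.5, 0.5, 0.5])
        ps = [weighted_chisq_sf(q, lam)[0] for q in np.linspace(0.5, 60, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_inputs(self):
        assert weighted_chisq_sf(0.0, [1.0]) == (1.0, 0.0)
        assert weighted_chisq_sf(5.0, [])[0] == 0.0


class TestGenePValue:
    def test_single_snp_identity(self):
        ld = ld_from(np.eye(1))
        T = float(stats.chi2.isf(0.01, 1))
        p, method = gene_pvalue_weighted_chisq(T, ld)
        assert method == "single_snp" and p == pytest.approx(0.01, rel=1e-9)

    def test_monte_carlo_route_agrees(self):
        R = ar1(5, 0.8)
        ld = ld_from(R)
        rng = np.random.default_rng(2)
        p_int, m1 = gene_pvalue_weighted_chisq(2.0, ld, mc_draws=0)
        # force the Monte Carlo route via an unconverged-integration stand-in
        lam = np.clip(np.linalg.eigvalsh(R), 0, None)
        L = np.linalg.cholesky(R)
        draws = rng.standard_normal((200_000, 5)) @ L.T
        mc = ((draws**2).mean(axis=1) >= 2.0).mean()
        assert m1 == "weighted_chisq"
        assert abs(p_int - mc) < 3 * np.sqrt(mc * (1 - mc) / 200_000)

    def test_deep_tail_positive_and_monotone(self):
        ld = ld_from(ar1(5, 0.5))
        ps = [gene_pvalue_weighted_chisq(T, ld, mc_draws=0)[0] for T in (10, 20, 40)]
        assert all(p > 0 for p in ps) and ps[0] > ps[1] > ps[2]


class TestRunGeneAnalysis:
    def build_inputs(self):
        classified = pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3", "rs4"],
                "chrom": ["1", "1", "1", "2"],
                "pos": [100, 110, 120, 100],
                "p_pre": [1e-5, 0.02, 0.5, 0.04],
                "p_post": [0.3, 0.01, 1e-4, 0.2],
                "label": ["reversal", "reversal", "reversal", "reversal"],
            }
        )
        gene_locs = pd.DataFrame(
            {
                "gene_id": ["10001", "10002"],
                "chrom": ["1", "2"],
                "start": [50, 50],
                "end": [200, 200],
                "strand": ["+", "+"],
                "symbol": ["GA", "GB"],
            }
        )
        rng = np.random.default_rng(0)
        panel = ReferencePanel(
            variant_ids=["rs1", "rs2", "rs3", "rs4"],
            genotypes=rng.integers(0, 3, size=(200, 4)).astype(float),
        )
        return classified, gene_locs, panel

    def test_single_snp_gene_keeps_snp_p(self):
        classified, gene_locs, panel = self.build_inputs()
        res = run_gene_analysis(classified, gene_locs, panel, "reversal", seed=1)
        single = res[res.GENE == "10002"].iloc[0]
        assert single.NSNPS == 1 and single.P == 0.04 and single.method == "single_snp"

    def test_multi_snp_gene_stat_and_retention(self):
        classified, gene_locs, panel = self.build_inputs()
        res = run_gene_analysis(classified, gene_locs, panel, "reversal", seed=1)
        g = res[res.GENE == "10001"].iloc[0]
        expected_T = gene_statistic([1e-5, 0.01, 1e-4])  # min-p per SNP
        assert g.STAT_T == pytest.approx(expected_T)
        assert g.NSNPS == 3 and bool(g.retained)
        assert g.ZSTAT == pytest.approx(stats.norm.isf(g.P), rel=1e-9)

    def test_empty_class_gives_empty_result(self):
        classified, gene_locs, panel = self.build_inputs()
        res = run_gene_analysis(classified, gene_locs, panel, "stable", seed=1)
        assert res.empty


class TestNullCalibrationByLD:
    @pytest.mark.parametrize("rho", [0.0, 0.6])
    def test_gene_p_uniform_under_null(self, rho):
        # 300 null genes of 5 SNPs with known AR(1) LD: p_gene ~ U(0,1)
        m = 5
        R = ar1(m, rho)
        ld = ld_from(R)
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(300):
            z = L @ rng.standard_normal(m)
            snp_p = 2 * stats.norm.sf(np.abs(z))
            p, _ = gene_pvalue_weighted_chisq(gene_statistic(snp_p), ld, mc_draws=0)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
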