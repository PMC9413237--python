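"""Association mapping: MAF filter, PCs, OLS scan, inflation, GRM, MLMA,
meta-analysis and regional views."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitropop import gwas as gw
from vitropop.synthetic import (GenotypeMatrix, GenotypeSimSpec,
                                PopulationSpec, simulate_genotypes,
                                simulate_population)


def make_gm(genos, chrom=None, pos=None, sex=None, groups=None):
    genos = np.asarray(genos, dtype=float)
    n, m = genos.shape
    snp_ids = [f"s{j}" for j in range(m)]
    sample_ids = [f"i{j}" for j in range(n)]
    freq = np.nanmean(genos, axis=0) / 2
    return GenotypeMatrix(
        genotypes=pd.DataFrame(genos, index=sample_ids, columns=snp_ids),
        snps=pd.DataFrame({
            "snp_id": snp_ids,
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else np.arange(m) * 1000,
            "maf": np.minimum(freq, 1 - freq),
        }).set_index("snp_id"),
        samples=pd.DataFrame({
            "sample_id": sample_ids,
            "sex": sex if sex is not None else ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            "ancestry_group": groups if groups is not None else ["group1"] * n,
        }).set_index("sample_id"),
    )


@pytest.fixture(scope="module")
def structured_panel():
    params = simulate_population(PopulationSpec(n_individuals=146, seed=1))
    gm, params = simulate_genotypes(
        GenotypeSimSpec(n_snps=1200, n_ancestry_groups=2,
                        group_divergence=0.08, seed=2), params)
    return gw.filter_maf(gm), params


class TestMafFilter:
    def test_monomorphic_snp_removed(self):
        gm = make_gm(np.column_stack([np.zeros(10), np.ones(10)]))
        out = gw.filter_maf(gm, 0.05)
        assert list(out.genotypes.columns) == ["s1"]

    def test_just_below_threshold_removed(self):
        # 146 samples, 14 minor alleles of 292 -> MAF 0.0479 < 0.05
        g = np.zeros((146, 2))
        g[:14, 0] = 1
        g[:20, 1] = 1
        out = gw.filter_maf(make_gm(g), 0.05)
        assert list(out.genotypes.columns) == ["s1"]

    def test_exactly_at_threshold_retained(self):
        g = np.zeros((100, 1))
        g[:10, 0] = 1  # MAF = 10/200 = 0.05
        out = gw.filter_maf(make_gm(g), 0.05)
        assert out.n_snps == 1

    def test_major_allele_coding_flipped_to_minor(self):
        g = np.full((10, 1), 2.0)
        g[:3, 0] = 1.0  # mean/2 = 0.85 -> recode
        out = gw.filter_maf(make_gm(g), 0.05)
        assert out.genotypes.iloc[:, 0].mean() / 2 <= 0.5

    def test_all_removed_errors(self):
        gm = make_gm(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            gw.filter_maf(gm, 0.05)


class TestPCs:
    def test_structure_on_leading_pc(self, structured_panel):
        gm, _ = structured_panel
        pcs = gw.genotype_pcs(gm, 3)
        grp = (gm.samples["ancestry_group"] == "group2").astype(float)
        assert abs(np.corrcoef(pcs["PC1"], grp)[0, 1]) > 0.9

    def test_permutation_equivariance(self, structured_panel):
        gm, _ = structured_panel
        perm = np.random.default_rng(3).permutation(gm.n_samples)
        gm_perm = GenotypeMatrix(genotypes=gm.genotypes.iloc[perm],
                                 snps=gm.snps, samples=gm.samples.iloc[perm])
        a = gw.genotype_pcs(gm, 2)
        b = gw.genotype_pcs(gm_perm, 2)
        assert np.allclose(a.iloc[perm].to_numpy(), b.to_numpy(), atol=1e-8)

    def test_k_zero_gives_empty_block_and_scan_runs(self, structured_panel):
        gm, params = structured_panel
        pcs = gw.genotype_pcs(gm, 0)
        assert pcs.shape[1] == 0
        pheno = pd.Series(np.log10(params["ec50"].to_numpy()),
                          index=gm.genotypes.index)
        tbl = gw.snp_association(pheno, gm, pcs)
        assert len(tbl) == gm.n_snps

    def test_zero_variance_snp_rejected(self):
        gm = make_gm(np.column_stack([np.zeros(12), np.ones(12)]))
        with pytest.raises(ValueError, match="zero-variance"):
            gw.genotype_pcs(gm, 1)


class TestAssociation:
    def test_null_pvalues_uniform_and_calibrated(self, rng):
        params = simulate_population(PopulationSpec(n_individuals=146, seed=4))
        gm, _ = simulate_genotypes(GenotypeSimSpec(n_snps=2000, seed=5), params)
        gm = gw.filter_maf(gm)
        pcs = gw.genotype_pcs(gm, 3)
        pheno = pd.Series(rng.standard_normal(146), index=gm.genotypes.index)
        tbl = gw.snp_association(pheno, gm, pcs)
        assert stats.kstest(tbl["p"], "uniform").pvalue > 0.01
        # type-I error at alpha = 1e-3 within 3 binomial SEs of nominal
        alpha = 1e-3
        m = len(tbl)
        se = np.sqrt(alpha * (1 - alpha) / m)
        assert abs((tbl["p"] < alpha).mean() - alpha) < 3 * se

    def test_planted_strong_snp_found(self, rng):
        params = simulate_population(PopulationSpec(n_individuals=146, seed=6))
        gm, _ = simulate_genotypes(GenotypeSimSpec(n_snps=500, seed=7), params)
        gm = gw.filter_maf(gm)
        g = gm.genotypes.iloc[:, 42].to_numpy(dtype=float)
        gz = (g - g.mean()) / g.std()
        y = np.sqrt(0.3) * gz + np.sqrt(0.7) * rng.standard_normal(146)
        pheno = pd.Series(y, index=gm.genotypes.index)
        tbl = gw.snp_association(pheno, gm, gw.genotype_pcs(gm, 3))
        hit = tbl.iloc[42]
        assert hit["p"] < 1e-5
        assert tbl["p"].idxmin() == 42

    def test_constant_genotype_flagged_untestable(self, rng):
        g = np.column_stack([np.ones(30),
                             rng.integers(0, 3, 30).astype(float)])
        gm = make_gm(g)
        pheno = pd.Series(rng.standard_normal(30), index=gm.genotypes.index)
        tbl = gw.snp_association(pheno, gm)
        assert tbl.loc[0, "hit_class"] == "untestable"
        assert np.isnan(tbl.loc[0, "p"])

    def test_phenotype_affine_equivariance(self, structured_panel, rng):
        gm, _ = structured_panel
        pcs = gw.genotype_pcs(gm, 3)
        y = pd.Series(rng.standard_normal(gm.n_samples),
                      index=gm.genotypes.index)
        t1 = gw.snp_association(y, gm, pcs)
        t2 = gw.snp_association(3.0 * y + 5.0, gm, pcs)
        assert np.allclose(t2["beta"], 3.0 * t1["beta"])
        assert np.allclose(t2["t"], t1["t"], atol=1e-10)
        assert np.allclose(t2["p"], t1["p"], atol=1e-12)

    def test_hit_classes_are_threshold_functions(self):
        p = np.array([0.5, 9e-6, 4e-8, 1e-5, 5e-8])
        cls = gw._classify(p)
        # boundaries are strict: p = 1e-5 is not suggestive, p = 5e-8 is
        # not genome-wide significant but still suggestive
        assert list(cls) == ["none", "suggestive", "significant",
                             "none", "suggestive"]


class TestInflation:
    def test_uniform_null_lambda_near_one(self, rng):
        rep = gw.genomic_lambda(rng.uniform(size=10_000))
        assert 0.95 <= rep.lam <= 1.05
        assert rep.acceptable

    def test_doubled_chisquare_lambda_two(self, rng):
        chi = stats.chi2.rvs(1, size=20_000, random_state=123)
        p = stats.chi2.sf(2 * chi, 1)
        rep = gw.genomic_lambda(p)
        assert rep.lam == pytest.approx(2.0, rel=0.05)
        assert not rep.acceptable

    def test_all_half_gives_exactly_one(self):
        rep = gw.genomic_lambda(np.full(500, 0.5))
        assert rep.lam == pytest.approx(1.0, abs=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            gw.genomic_lambda(np.linspace(0, 1, 200))  # contains 0

    def test_null_lambda_in_band_for_large_panels(self):
        # with no structure and 10,000 SNPs the lambda band [0.9, 1.1]
        # is ~4 sigma wide, so nearly every null replicate falls inside
        params = simulate_population(PopulationSpec(n_individuals=146,
                                                    seed=30))
        ok = 0
        for rep in range(40):
            gm, _ = simulate_genotypes(
                GenotypeSimSpec(n_snps=10_000, seed=700 + rep), params)
            gm = gw.filter_maf(gm)
            rng = np.random.default_rng(800 + rep)
            y = pd.Series(rng.standard_normal(146),
                          index=gm.genotypes.index)
            tbl = gw.snp_association(y, gm, None)
            ok += int(0.9 <= gw.genomic_lambda(tbl["p"]).lam <= 1.1)
        assert ok >= 38  # >= 95%


class TestGRM:
    def test_duplicate_sample_matches_diagonal(self, structured_panel):
        gm, _ = structured_panel
        dup = GenotypeMatrix(
            genotypes=pd.concat([gm.genotypes,
                                 gm.genotypes.iloc[[0]].rename(
                                     index={gm.genotypes.index[0]: "dup"})]),
            snps=gm.snps,
            samples=pd.concat([gm.samples,
                               gm.samples.iloc[[0]].rename(
                                   index={gm.samples.index[0]: "dup"})]))
        k = gw.grm(dup)
        assert k[0, -1] == pytest.approx(k[0, 0], rel=1e-10)

    def test_unrelated_samples_offdiagonal_shrinks_with_snps(self):
        params = simulate_population(PopulationSpec(n_individuals=60, seed=8))
        means = []
        for m in (200, 2000):
            gm, _ = simulate_genotypes(GenotypeSimSpec(n_snps=m, seed=9),
                                       params)
            k = gw.grm(gw.filter_maf(gm))
            off = k[np.triu_indices_from(k, 1)]
            means.append(np.mean(np.abs(off)))
            assert abs(np.mean(off)) < 0.05
        assert means[1] < means[0]

    def test_diagonal_averages_one_under_hardy_weinberg(self, structured_panel):
        gm, _ = structured_panel
        k = gw.grm(gm)
        assert np.diag(k).mean() == pytest.approx(1.0, abs=0.1)
        assert np.allclose(k, k.T)

    def test_fixed_snp_rejected(self):
        gm = make_gm(np.column_stack([np.zeros(10), np.ones(10)]))
        with pytest.raises(ValueError, match="filter"):
            gw.grm(gm)


class TestMLMA:
    def test_identity_grm_equals_ols(self, structured_panel, rng):
        gm, params = structured_panel
        pcs = gw.genotype_pcs(gm, 3)
        pheno = pd.Series(np.log10(params["ec50"].to_numpy()),
                          index=gm.genotypes.index)
        ols = gw.snp_association(pheno, gm, pcs)
        mm = gw.mlma_association(pheno, gm, np.eye(gm.n_samples), pcs)
        ok = np.isfinite(ols["t"])
        assert np.max(np.abs(mm.loc[ok, "t"] - ols.loc[ok, "t"])) < 1e-8

    def test_polygenic_background_inflation_reduced(self, rng):
        params = simulate_population(PopulationSpec(n_individuals=146, seed=10))
        gm, _ = simulate_genotypes(
            GenotypeSimSpec(n_snps=1500, n_ancestry_groups=2,
                            group_divergence=0.1, seed=11), params)
        gm = gw.filter_maf(gm)
        z = gm.genotypes.to_numpy()
        z = (z - z.mean(axis=0))
        poly = z @ rng.normal(0, 1, gm.n_snps)
        poly /= poly.std()
        y = pd.Series(poly + 0.3 * rng.standard_normal(gm.n_samples),
                      index=gm.genotypes.index)
        # no PC correction: polygenic structure inflates the naive scan
        ols = gw.snp_association(y, gm, None)
        mm = gw.mlma_association(y, gm, gw.grm(gm), None)
        lam_ols = gw.genomic_lambda(ols["p"]).lam
        lam_mm = gw.genomic_lambda(mm["p"]).lam
        assert lam_ols > lam_mm

    def test_small_group_refused(self, structured_panel):
        gm, params = structured_panel
        tiny = GenotypeMatrix(genotypes=gm.genotypes.iloc[:5],
                              snps=gm.snps, samples=gm.samples.iloc[:5])
        pheno = pd.Series(np.zeros(5), index=tiny.genotypes.index)
        with pytest.raises(ValueError, match="refused"):
            gw.mlma_association(pheno, tiny, np.eye(5))


class TestMeta:
    @staticmethod
    def _table(z, n=3):
        t = z  # treat z as t for construction
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(z))],
                             "chrom": 1, "pos": np.arange(len(z)),
                             "maf": 0.2, "t": t, "p": p})

    def test_single_group_identity(self):
        tbl = self._table(np.array([1.5, -2.0, 0.0001]))
        out = gw.meta_z({"a": tbl}, {"a": 50})
        assert np.allclose(out["z"], [1.5, -2.0, 0.0001], atol=1e-6)

    def test_equal_groups_equal_z_scales_by_sqrt2(self):
        tbl = self._table(np.array([2.0, -1.0]))
        out = gw.meta_z({"a": tbl, "b": tbl}, {"a": 40, "b": 40})
        assert np.allclose(out["z"], np.sqrt(2) * np.array([2.0, -1.0]),
                           atol=1e-6)

    def test_opposite_z_cancels(self):
        ta = self._table(np.array([2.0]))
        tb = self._table(np.array([-2.0]))
        out = gw.meta_z({"a": ta, "b": tb}, {"a": 40, "b": 40})
        assert out["z"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_snps_rejected(self):
        ta = self._table(np.array([1.0, 2.0]))
        tb = self._table(np.array([1.0, 2.0]))
        tb.loc[1, "snp_id"] = "other"
        with pytest.raises(ValueError, match="mismatched"):
            gw.meta_z({"a": ta, "b": tb}, {"a": 10, "b": 10})


class TestRegional:
    def _table(self):
        return pd.DataFrame({
            "snp_id": ["a", "b", "c", "d"],
            "chrom": [1, 1, 1, 2],
            "pos": [100, 500, 900, 500],
            "maf": 0.3,
            "p": [1e-3, 1e-7, 0.5, 1e-6],
        })

    def test_window_subsets_and_orders(self):
        out = gw.regional_view(self._table(), 1, 500, 400)
        assert list(out["snp_id"]) == ["a", "b", "c"]
        assert "neglog10_p" in out

    def test_empty_window_is_empty_not_error(self):
        out = gw.regional_view(self._table(), 9, 500, 100)
        assert out.empty

    def test_zero_width_matches_center_only(self):
        out = gw.regional_view(self._table(), 1, 500, 0)
        assert list(out["snp_id"]) == ["b"]

    def test_shared_hits_reported_across_phenotypes(self):
        t = self._table()
        tables = {"x": t, "y": t, "z": t.assign(p=[0.5, 0.5, 0.5, 1e-6])}
        out = gw.overlap_loci(tables, p_threshold=1e-5, min_substances=2)
        assert set(out["snp_id"]) == {"b", "d"}
        assert out.set_index("snp_id").loc["d", "n_substances"] == 3
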