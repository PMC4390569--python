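import numpy as np
import pandas as pd
import pytest

from ethoscan import (
    GenotypeMatrix,
    LineMeansScan,
    filter_variants,
    qq_points,
    read_genotypes,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=3R>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\tL3\tL4
3R\t100\tv1\tA\tT\t.\t.\t.\tGT\t0/0\t0/0\t1/1\t1/1
3R\t200\tv2\tC\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.
3R\t300\tv3\tG\tA\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0
"""


@pytest.fixture()
def tiny_vcf(tmp_path):
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture()
def tiny_tsv(tmp_path):
    df = pd.DataFrame({
        "id": ["v1", "v2", "v3"],
        "chrom": ["3R"] * 3,
        "pos": [100, 200, 300],
        "ref": ["A", "C", "G"],
        "alt": ["T", "G", "A"],
        "L1": [0.0, 0.0, 0.0],
        "L2": [0.0, np.nan, 0.0],
        "L3": [2.0, 2.0, 0.0],
        "L4": [2.0, np.nan, 0.0],
    })
    path = tmp_path / "tiny.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadGenotypes:
    def test_tsv_shape(self, tiny_tsv):
        gm = read_genotypes(tiny_tsv)
        assert gm.n_variants == 3 and gm.lines == ["L1", "L2", "L3", "L4"]

    def test_vcf_het_missing_policy(self, tiny_vcf):
        gm = read_genotypes(tiny_vcf)
        assert np.isnan(gm.dosages[1, 1])  # het call masked
        assert np.isnan(gm.dosages[1, 3])  # ./. missing

    def test_vcf_het_dosage1_policy(self, tiny_vcf):
        gm = read_genotypes(tiny_vcf, het_policy="dosage1")
        assert gm.dosages[1, 1] == 1.0

    def test_vcf_and_tsv_equivalent(self, tiny_vcf, tiny_tsv):
        gv = read_genotypes(tiny_vcf)
        gt = read_genotypes(tiny_tsv)
        assert gv.lines == gt.lines
        assert np.array_equal(gv.dosages, gt.dosages, equal_nan=True)
        assert (gv.variants["pos"] == gt.variants["pos"]).all()

    def test_missing_meta_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"id": ["v"], "L1": [0]}).to_csv(path, sep="\t",
                                                      index=False)
        with pytest.raises(ValueError, match="chrom"):
            read_genotypes(path)

    def test_call_rates(self, tiny_tsv):
        gm = read_genotypes(tiny_tsv)
        assert gm.call_rates()[1] == pytest.approx(0.5)


class TestFilterVariants:
    def test_monomorphic_removed(self, tiny_tsv):
        gm = read_genotypes(tiny_tsv)
        kept = filter_variants(gm, min_minor_lines=1)
        assert "v3" not in set(kept.variants["id"])

    def test_threshold_zero_is_identity(self, tiny_tsv):
        gm = read_genotypes(tiny_tsv)
        assert filter_variants(gm, 0).n_variants == gm.n_variants

    def test_minor_line_counts(self, rng):
        dos = np.zeros((1, 166))
        dos[0, :4] = 2.0
        gm = GenotypeMatrix(
            pd.DataFrame({"id": ["v"], "chrom": ["2L"], "pos": [1],
                          "ref": ["A"], "alt": ["T"]}),
            dos, [f"L{i}" for i in range(166)],
        )
        assert gm.minor_line_counts()[0] == 4
        assert filter_variants(gm, 4).n_variants == 1
        assert filter_variants(gm, 5).n_variants == 0


def make_matrix(dosages, lines):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    n = dosages.shape[0]
    return GenotypeMatrix(
        pd.DataFrame({"id": [f"v{i}" for i in range(n)],
                      "chrom": ["2L"] * n, "pos": range(1, n + 1),
                      "ref": ["A"] * n, "alt": ["T"] * n}),
        dosages, list(lines),
    )


class TestScan:
    def test_perfect_fit_effect_half_per_dosage_unit(self):
        lines = ["a", "b", "c", "d"]
        gm = make_matrix([[0, 0, 2, 2]], lines)
        pheno = pd.Series([0.0, 0.0, 1.0, 1.0], index=lines)
        res = LineMeansScan(pheno, gm).fit()
        row = res.table.iloc[0]
        assert row["beta"] == pytest.approx(0.5)
        assert row["P"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_genotype_null_effect(self):
        lines = list("abcdef")
        gm = make_matrix([[0, 2, 0, 2, 0, 2]], lines)
        pheno = pd.Series([1, 1, -1, -1, 0, 0], index=lines, dtype=float)
        res = LineMeansScan(pheno, gm).fit()
        assert res.table.iloc[0]["beta"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.iloc[0]["P"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        lines = [f"L{i}" for i in range(40)]
        G = (rng.random((30, 40)) < 0.3) * 2.0
        cov = pd.DataFrame({"c1": rng.normal(size=40),
                            "c2": rng.integers(0, 2, 40)}, index=lines)
        pheno = pd.Series(rng.normal(size=40), index=lines)
        res = LineMeansScan(pheno, make_matrix(G, lines), covariates=cov).fit()
        for i in range(5):
            X = sm.add_constant(np.column_stack(
                [cov.to_numpy(), G[i]]))
            ref = sm.OLS(pheno.to_numpy(), X).fit()
            assert res.table.loc[i, "beta"] == pytest.approx(
                ref.params[-1], abs=1e-10)
            assert res.table.loc[i, "se"] == pytest.approx(
                ref.bse[-1], abs=1e-10)
            assert res.table.loc[i, "P"] == pytest.approx(
                ref.pvalues[-1], abs=1e-10)

    def test_missing_calls_fall_back_to_complete_lines(self, rng):
        import statsmodels.api as sm

        lines = [f"L{i}" for i in range(30)]
        g = (rng.random(30) < 0.4) * 2.0
        g[5] = np.nan
        pheno = pd.Series(rng.normal(size=30), index=lines)
        res = LineMeansScan(pheno, make_matrix([g], lines)).fit()
        mask = ~np.isnan(g)
        ref = sm.OLS(pheno.to_numpy()[mask],
                     sm.add_constant(g[mask])).fit()
        assert res.table.loc[0, "beta"] == pytest.approx(ref.params[-1],
                                                         abs=1e-10)
        assert res.table.loc[0, "n"] == mask.sum()

    def test_rank_deficient_covariates_rejected(self, rng):
        lines = [f"L{i}" for i in range(10)]
        cov = pd.DataFrame({"c1": np.ones(10), "c2": np.ones(10)},
                           index=lines)
        pheno = pd.Series(rng.normal(size=10), index=lines)
        with pytest.raises(ValueError, match="rank deficient"):
            LineMeansScan(pheno, make_matrix([[0, 2] * 5], lines),
                          covariates=cov)

    def test_no_shared_lines_fatal(self):
        gm = make_matrix([[0, 2]], ["x", "y"])
        pheno = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="shared"):
            LineMeansScan(pheno, gm)

    def test_permutation_destroys_causal_signal(self, rng):
        n = 166
        lines = [f"L{i}" for i in range(n)]
        g = (rng.random(n) < 0.3) * 2.0
        pheno_vals = 0.8 * g + rng.normal(size=n)
        pheno = pd.Series(pheno_vals, index=lines)
        gm = make_matrix([g], lines)
        p_causal = LineMeansScan(pheno, gm).fit().table.loc[0, "P"]
        assert p_causal < 1e-10
        perm = pd.Series(rng.permutation(pheno_vals), index=lines)
        p_perm = LineMeansScan(perm, gm).fit().table.loc[0, "P"]
        assert p_perm > 1e-4

    def test_power_increases_with_effect_size(self, rng):
        n = 166
        lines = [f"L{i}" for i in range(n)]
        mean_logp = []
        for effect in (0.0, 0.3, 0.8):
            logps = []
            for _ in range(20):
                g = (rng.random(n) < 0.3) * 2.0
                pheno = pd.Series(effect * g + rng.normal(size=n),
                                  index=lines)
                p = LineMeansScan(pheno, make_matrix([g], lines)
                                  ).fit().table.loc[0, "P"]
                logps.append(-np.log10(max(p, 1e-300)))
            mean_logp.append(np.mean(logps))
        assert mean_logp[0] < mean_logp[1] < mean_logp[2]


class TestQQAndHits:
    def test_single_p_value(self):
        pts = qq_points([0.5])
        assert pts["expected"].iloc[0] == pytest.approx(-np.log10(0.5))

    def test_uniform_p_values_on_diagonal(self, rng):
        pts = qq_points(rng.uniform(size=5000))
        inner = pts.iloc[100:-100]
        assert np.abs(inner["expected"] - inner["observed"]).max() < 0.25

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            pts = qq_points([0.0, 0.5])
        assert np.isfinite(pts["observed"]).all()

    def test_hits_tiers_and_thresholds(self, rng):
        n = 166
        lines = [f"L{i}" for i in range(n)]
        G = (rng.random((50, n)) < 0.3) * 2.0
        pheno = pd.Series(2.0 * G[7] + rng.normal(size=n), index=lines)
        res = LineMeansScan(pheno, make_matrix(G, lines)).fit()
        hits = res.hits(alpha=0.05, n_tests=2_400_000, suggestive=1e-5)
        assert "v7" in set(hits["id"])
        top = hits.iloc[0]
        assert top["id"] == "v7" and top["tier"] == "significant"
        assert top["P"] <= 0.05 / 2_400_000

    def test_empty_results_give_empty_table(self):
        lines = list("abcd")
        gm = make_matrix([[0, 0, 2, 2]], lines)
        pheno = pd.Series([0.0, 1.0, 0.0, 1.0], index=lines)
        res = LineMeansScan(pheno, gm).fit()
        hits = res.hits(alpha=0.05, n_tests=10**6, suggestive=None)
        assert len(hits) == 0

    def test_summary_mentions_top_hit(self, rng):
        lines = [f"L{i}" for i in range(20)]
        G = (rng.random((5, 20)) < 0.4) * 2.0
        pheno = pd.Series(rng.normal(size=20), index=lines)
        res = LineMeansScan(pheno, make_matrix(G, lines)).fit()
        assert "top hit" in res.summary()
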