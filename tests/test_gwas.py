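"""SNP QC and the GRAMMAR scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from equigen.gwas import grammar_scan, hwe_exact_test, manhattan_table, qc_filter
from equigen.mixed_models import VarianceComponents
from equigen.pedigree import a_matrix
from equigen.simulate import GenotypeMatrix, GenotypeSimConfig, half_sib_pedigree, simulate_genotypes, simulate_records
from _oracles import hwe_exact_fraction


def _matrix(dosages, chrom="1"):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    m = len(dosages)
    snps = pd.DataFrame(
        {"snp": [f"s{i}" for i in range(m)], "chrom": chrom, "pos": np.arange(1, m + 1)}
    )
    ids = [f"h{i}" for i in range(dosages.shape[1])]
    return GenotypeMatrix(snps, dosages, ids)


class TestHwe:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_balanced_counts_match_enumeration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_exact_fraction(25, 50, 25), abs=1e-12
        )

    def test_no_heterozygotes_fails_threshold(self):
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_random_triples_match_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(2, 200))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = n - a - b
            assert hwe_exact_test(a, b, c) == pytest.approx(
                hwe_exact_fraction(a, b, c), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestQc:
    def test_low_maf_removed_with_reason(self):
        n = 200
        rare = np.zeros(n)
        rare[:2] = 1  # maf 0.005
        common = np.tile([0, 1, 2, 1], n // 4)
        filtered, report = qc_filter(_matrix([rare, common]))
        assert list(filtered.snps["snp"]) == ["s1"]
        assert report.loc[report["snp"] == "s0", "reason"].iloc[0] == "maf"

    def test_missingness_removed_with_reason(self, rng):
        good = rng.choice([0.0, 1.0, 2.0], size=100, p=[0.25, 0.5, 0.25])
        bad = good.copy()
        bad[:15] = np.nan
        _, report = qc_filter(_matrix([good, bad]))
        assert report["pass"].tolist() == [True, False]
        assert "callrate" in report["reason"].iloc[1]

    def test_hwe_failure_reason(self):
        hom_only = np.array([0.0] * 50 + [2.0] * 50)
        _, report = qc_filter(_matrix([hom_only]))
        assert "hwe" in report["reason"].iloc[0]

    def test_filter_is_idempotent(self, rng):
        ped = half_sib_pedigree(10, 10)
        geno, _, miss = simulate_genotypes(ped, GenotypeSimConfig(n_snps=300, qtl=None), rng)
        dos = geno.dosages.copy()
        dos[miss] = np.nan
        geno.dosages = dos
        once, _ = qc_filter(geno)
        twice, report = qc_filter(once)
        assert np.array_equal(once.dosages, twice.dosages, equal_nan=True)
        assert report["pass"].all()

    def test_clean_panel_mostly_retained(self, rng):
        ped = half_sib_pedigree(20, 20)
        geno, _, _ = simulate_genotypes(
            ped, GenotypeSimConfig(n_snps=500, missing_rate=0.0, qtl=None), rng
        )
        _, report = qc_filter(geno)
        assert report["pass"].mean() >= 0.99


class TestGrammarScan:
    def test_duplicating_individuals_keeps_beta(self, rng):
        g = rng.choice([0.0, 1.0, 2.0], size=40)
        y = 0.4 * g + rng.normal(size=40)
        resp1 = pd.Series(y, index=[f"h{i}" for i in range(40)])
        scan1 = grammar_scan(resp1, _matrix([g]))
        g2 = np.concatenate([g, g])
        ids2 = [f"h{i}" for i in range(80)]
        resp2 = pd.Series(np.concatenate([y, y]), index=ids2)
        m2 = GenotypeMatrix(_matrix([g]).snps, g2[None, :], ids2)
        scan2 = grammar_scan(resp2, m2)
        assert scan1["beta"].iloc[0] == pytest.approx(scan2["beta"].iloc[0], abs=1e-12)

    def test_zero_variance_snp_flagged(self, rng):
        g_const = np.full(30, 1.0)
        g_ok = rng.choice([0.0, 1.0, 2.0], size=30)
        resp = pd.Series(rng.normal(size=30), index=[f"h{i}" for i in range(30)])
        scan = grammar_scan(resp, _matrix([g_const, g_ok]))
        row = scan[scan["snp"] == "s0"].iloc[0]
        assert np.isnan(row["beta"]) and row["p"] == 1.0 and row["flag"] == "monomorphic"

    def test_beta_close_to_gls_oracle_when_polygenic_small(self, rng):
        # GRAMMAR approximation regime: small polygenic variance (the
        # first-step variances are fixed at the truth to isolate the
        # residual-regression approximation itself)
        h2 = 0.02
        ped = half_sib_pedigree(60, 5)
        off = [i for i in ped.ids if "O" in i]
        truth = VarianceComponents(["y"], [[h2]], np.zeros((0, 0)), [[1 - h2]], [])
        data, _ = simulate_records(ped, off, truth, 1, rng)
        g = rng.binomial(2, 0.4, size=len(off)).astype(float)
        data["y"] = data["y"] + 0.5 * g
        from equigen.mixed_models import TraitModelSpec, build_mme

        spec = TraitModelSpec(traits=["y"])
        sol = build_mme(spec, data, ped, truth).solve()
        resid = sol.residuals.groupby("animal")["y"].mean()
        gm = GenotypeMatrix(_matrix([g]).snps, g[None, :], list(off))
        scan = grammar_scan(resid.loc[off], gm)
        # GLS oracle with the true covariance structure
        A, _ = a_matrix(ped)
        idx = [ped.index[i] for i in off]
        V = h2 * A[np.ix_(idx, idx)] + (1 - h2) * np.eye(len(off))
        X = np.column_stack([np.ones(len(off)), g])
        Vi = np.linalg.inv(V)
        b_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ data["y"].to_numpy())
        assert scan["beta"].iloc[0] == pytest.approx(b_gls[1], rel=0.05)

    def test_null_pvalues_roughly_uniform(self, rng):
        n = 300
        g = rng.binomial(2, rng.uniform(0.1, 0.5, size=(2000, 1)), size=(2000, n)).astype(float)
        resp = pd.Series(rng.normal(size=n), index=[f"h{i}" for i in range(n)])
        scan = grammar_scan(resp, _matrix(g))
        ks = stats.kstest(scan["p"], "uniform")
        assert ks.pvalue > 1e-3

    def test_sorted_by_position_and_manhattan(self, rng):
        g = rng.choice([0.0, 1.0, 2.0], size=(4, 30))
        snps = pd.DataFrame(
            {"snp": list("abcd"), "chrom": ["2", "1", "1", "2"], "pos": [5, 7, 3, 1]}
        )
        gm = GenotypeMatrix(snps.sort_values(["chrom", "pos"]).reset_index(drop=True),
                            g, [f"h{i}" for i in range(30)])
        resp = pd.Series(rng.normal(size=30), index=[f"h{i}" for i in range(30)])
        scan = grammar_scan(resp, gm)
        assert scan.groupby("chrom")["pos"].apply(lambda s: s.is_monotonic_increasing).all()
        mt = manhattan_table(scan)
        assert {"chrom", "pos", "neg_log10_p"} <= set(mt.columns)
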