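"""Synthetic-population generator: determinism and statistical structure."""

import numpy as np
import pandas as pd
import pytest

from equigen.mixed_models import VarianceComponents
from equigen.pedigree import Pedigree
from equigen.simulate import (
    CompetitionSimConfig,
    GenotypeSimConfig,
    JudgeSimConfig,
    PedigreeSimConfig,
    QtlSpec,
    StudyConfig,
    default_trait_system,
    half_sib_pedigree,
    mendelian_breeding_values,
    simulate_genotypes,
    simulate_pedigree,
    simulate_records,
    simulate_study,
)
from equigen.gwas import hwe_exact_test


class TestPedigreeSimulation:
    def test_zero_generations_gives_founders_only(self, rng):
        ped, _ = simulate_pedigree(PedigreeSimConfig(n_founders=12, n_generations=0), rng)
        assert len(ped) == 12
        assert ped.n_founders == 12

    def test_same_seed_identical(self):
        cfg = PedigreeSimConfig(n_founders=20, n_generations=2, n_per_generation=30)
        p1, s1 = simulate_pedigree(cfg, np.random.default_rng(3))
        p2, s2 = simulate_pedigree(cfg, np.random.default_rng(3))
        assert p1.to_frame().equals(p2.to_frame())
        assert s1.equals(s2)

    def test_every_nonfounder_has_both_parents(self, rng):
        ped, _ = simulate_pedigree(
            PedigreeSimConfig(n_founders=30, n_generations=2, n_per_generation=40), rng
        )
        frame = ped.to_frame()
        nonfounders = frame[frame["id"].str.startswith(("G1", "G2"))]
        assert (nonfounders["sire"] != "0").all()
        assert (nonfounders["dam"] != "0").all()

    def test_too_few_founders_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_pedigree(PedigreeSimConfig(n_founders=1), rng)


class TestBreedingValues:
    def test_zero_genetic_variance_gives_zero_values(self, rng):
        ped = half_sib_pedigree(5, 4)
        a = mendelian_breeding_values(ped, np.zeros((2, 2)), rng)
        assert np.all(a == 0.0)

    def test_non_psd_g_rejected(self, rng):
        with pytest.raises(ValueError):
            mendelian_breeding_values(
                half_sib_pedigree(2, 2), np.array([[1.0, 2.0], [2.0, 1.0]]), rng
            )

    def test_sire_offspring_covariance_is_half_g(self, rng):
        # Monte-Carlo oracle: cov(a_sire, a_offspring) = G/2
        G = np.array([[1.0, 0.5], [0.5, 2.0]])
        n_pairs = 10_000
        recs = []
        for i in range(n_pairs):
            recs.append((f"s{i}", None, None))
            recs.append((f"o{i}", f"s{i}", None))
        ped = Pedigree.from_records(recs)
        a = mendelian_breeding_values(ped, G, rng)
        sidx = [ped.index[f"s{i}"] for i in range(n_pairs)]
        oidx = [ped.index[f"o{i}"] for i in range(n_pairs)]
        for t1 in range(2):
            for t2 in range(2):
                emp = np.cov(a[sidx, t1], a[oidx, t2])[0, 1]
                assert emp == pytest.approx(0.5 * G[t1, t2], abs=0.1 * abs(0.5 * G[t1, t2]) + 0.03)

    def test_record_variance_components_match_config(self, rng):
        truth = VarianceComponents(["y"], [[0.4]], [[0.25]], [[0.35]], ["y"])
        ped = half_sib_pedigree(100, 25)
        off = [i for i in ped.ids if "O" in i]
        data, _ = simulate_records(ped, off, truth, 2, rng)
        wide = data.groupby("animal")["y"].agg(["first", "last"])
        total = data["y"].var(ddof=1)
        within_cov = wide.cov().iloc[0, 1]  # = sigma_a2 + sigma_p2
        assert total == pytest.approx(1.0, rel=0.1)
        assert within_cov == pytest.approx(0.65, rel=0.12)


class TestGenotypes:
    def test_founder_dosage_mean_matches_frequency(self):
        ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(1000)])
        cfg = GenotypeSimConfig(n_snps=50, maf_range=(0.4999, 0.5001), qtl=None)
        geno, _, _ = simulate_genotypes(ped, cfg, np.random.default_rng(11))
        assert np.abs(geno.dosages.mean(axis=1) - 1.0).max() < 0.05 * 2

    def test_founders_in_hardy_weinberg(self):
        ped = Pedigree.from_records([(f"f{i}", None, None) for i in range(500)])
        cfg = GenotypeSimConfig(n_snps=1000, missing_rate=0.0, qtl=None)
        geno, _, _ = simulate_genotypes(ped, cfg, np.random.default_rng(5))
        pvals = []
        for row in geno.dosages:
            n0, n1, n2 = (row == 0).sum(), (row == 1).sum(), (row == 2).sum()
            pvals.append(hwe_exact_test(n0, n1, n2))
        assert np.mean(np.array(pvals) > 1e-6) >= 0.99

    def test_positions_strictly_increasing(self, rng):
        ped = half_sib_pedigree(5, 5)
        geno, _, _ = simulate_genotypes(ped, GenotypeSimConfig(n_snps=200), rng)
        for _, grp in geno.snps.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()

    def test_bad_frequency_range_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_genotypes(
                half_sib_pedigree(2, 2), GenotypeSimConfig(maf_range=(0.0, 0.5)), rng
            )

    def test_qtl_trait_must_exist(self):
        cfg = StudyConfig(
            seed=1,
            pedigree=PedigreeSimConfig(n_founders=10, n_generations=1, n_per_generation=20),
            n_measured=20,
            n_genotyped=5,
            n_events=3,
            genotypes=GenotypeSimConfig(n_snps=30, qtl=QtlSpec(trait="no_such_trait")),
            competition=CompetitionSimConfig(years=(2015,), starts_per_horse_year=1),
        )
        with pytest.raises(ValueError, match="QTL trait"):
            simulate_study(cfg)


class TestStudy:
    def test_deterministic_given_seed(self, tiny_study):
        from dataclasses import replace

        again = simulate_study(replace(tiny_study.config))
        pd.testing.assert_frame_equal(tiny_study.gait_records, again.gait_records)
        pd.testing.assert_frame_equal(tiny_study.competitions, again.competitions)
        pd.testing.assert_frame_equal(tiny_study.scores, again.scores)
        assert np.array_equal(
            tiny_study.genotypes.dosages, again.genotypes.dosages, equal_nan=True
        )

    def test_ranks_are_permutations(self, tiny_study):
        for (_, _), grp in tiny_study.competitions.groupby(["year", "event"]):
            n = grp["n_starters"].iloc[0]
            assert sorted(grp["rank"]) == list(range(1, n + 1))

    def test_walk_single_trot_canter_double(self, tiny_study):
        rec = tiny_study.gait_records
        per_horse = rec.groupby(["horse", "gait"]).size().unstack()
        assert (per_horse["W"] == 1).all()
        assert (per_horse["T"] == 2).all()
        assert (per_horse["C"] == 2).all()
        assert rec.loc[rec["gait"] == "C", "S"].isna().all()
        assert (rec["velocity"] > 0).all()

    def test_zero_starters_raises(self):
        cfg = StudyConfig(
            seed=1,
            pedigree=PedigreeSimConfig(n_founders=10, n_generations=1, n_per_generation=15),
            n_measured=15,
            n_genotyped=5,
            n_events=3,
            genotypes=GenotypeSimConfig(n_snps=20, qtl=None),
            competition=CompetitionSimConfig(n_starters=0),
        )
        with pytest.raises(ValueError, match="starter"):
            simulate_study(cfg)

    def test_kpa_zero_scores_independent_of_parent_average(self):
        cfg = StudyConfig(
            seed=9,
            pedigree=PedigreeSimConfig(n_founders=60, n_generations=2, n_per_generation=400),
            n_measured=400,
            n_genotyped=5,
            n_events=6,
            genotypes=GenotypeSimConfig(n_snps=12, qtl=None),
            competition=CompetitionSimConfig(years=(2015,), starts_per_horse_year=1),
            judge=JudgeSimConfig(k_pa=0.0),
        )
        study = simulate_study(cfg)
        merged = study.scores.merge(study.ebv, on="horse")
        intr = study.breeding_values.loc[merged["horse"], "judge_intrinsic"].to_numpy()
        jm = study.meta["judge"]
        non_genetic = merged["score"].to_numpy() - jm["mean"] - jm["sd"] * intr
        r = np.corrcoef(non_genetic, merged["pa_ebv"])[0, 1]
        assert abs(r) < 0.12

    def test_default_trait_system_is_valid(self):
        vc, meta = default_trait_system()
        assert "height" in vc.traits and "competition" in vc.traits
        # residual covariance zero across gaits and with height
        traits = list(vc.traits)
        i_t = traits.index("T_SF")
        i_c = traits.index("C_SF")
        i_h = traits.index("height")
        assert vc.R[i_t, i_c] == 0.0
        assert vc.R[i_t, i_h] == 0.0
        assert np.linalg.eigvalsh(vc.G).min() > -1e-10
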