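"""Henderson equations, BLUP solutions and EM-REML behaviour."""

import numpy as np
import pandas as pd
import pytest

import equigen.mixed_models as mm
from equigen.mixed_models import (
    TraitModelSpec,
    VarianceComponents,
    build_mme,
    em_reml,
    genetic_parameters,
    solve_blup,
    start_values,
)
from equigen.pedigree import Pedigree, a_matrix
from equigen.simulate import half_sib_pedigree, simulate_records


def _unrelated(n):
    return Pedigree.from_records([(f"a{i}", None, None) for i in range(n)])


def _single_trait_vc(sa, se, sp=None):
    if sp is None:
        return VarianceComponents(["y"], [[sa]], np.zeros((0, 0)), [[se]], [])
    return VarianceComponents(["y"], [[sa]], [[sp]], [[se]], ["y"])


class TestBlup:
    def test_shrinkage_regression_reduction(self):
        # unrelated animals, one record each: a_hat = (y - ybar)/(1 + se/sa)
        y = np.array([1.0, 3.0, -2.0, 4.0, 0.5, -1.5])
        ped = _unrelated(len(y))
        data = pd.DataFrame({"animal": ped.ids, "y": y})
        vc = _single_trait_vc(2.0, 1.0)
        sol = solve_blup(build_mme(TraitModelSpec(traits=["y"]), data, ped, vc))
        assert sol.fixed["y"]["(intercept)"] == pytest.approx(y.mean())
        expect = (y - y.mean()) / (1 + 1.0 / 2.0)
        assert np.allclose(sol.a["y"].loc[ped.ids].to_numpy(), expect)

    def test_coefficient_matrix_symmetric(self, rng):
        ped = half_sib_pedigree(4, 3)
        off = [i for i in ped.ids if "O" in i]
        vc = _single_trait_vc(1.0, 1.0, 0.5)
        data, _ = simulate_records(ped, off, vc, 2, rng)
        data["grp"] = rng.choice(["a", "b"], size=len(data))
        system = build_mme(
            TraitModelSpec(traits=["y"], fixed={"y": ["grp"]}, pe_traits=["y"]), data, ped, vc
        )
        C, *_ = system._assemble(vc)
        assert np.allclose(C, C.T)

    def test_fixed_effects_match_gls_oracle(self, rng):
        # b_hat from the MME equals GLS with V = sa*ZAZ' + se*I exactly
        ped = half_sib_pedigree(6, 5)
        off = [i for i in ped.ids if "O" in i]
        vc = _single_trait_vc(1.3, 0.9)
        data, _ = simulate_records(ped, off, vc, 1, rng)
        data["x"] = rng.normal(size=len(data))
        data["y"] = data["y"] + 0.7 * data["x"]
        spec = TraitModelSpec(traits=["y"], covariates={"y": ["x"]})
        sol = solve_blup(build_mme(spec, data, ped, vc))
        A, _ = a_matrix(ped)
        Z = np.zeros((len(data), len(ped)))
        for r, animal in enumerate(data["animal"]):
            Z[r, ped.index[animal]] = 1.0
        V = 1.3 * Z @ A @ Z.T + 0.9 * np.eye(len(data))
        X = np.column_stack([np.ones(len(data)), data["x"]])
        Vi = np.linalg.inv(V)
        b_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ data["y"].to_numpy())
        assert np.allclose(sol.fixed["y"].to_numpy(), b_gls, atol=1e-8)

    def test_unrecorded_animal_gets_parent_average(self, rng):
        recs = [("s", None, None), ("d", None, None), ("c", "s", "d")]
        ped = Pedigree.from_records(recs)
        vc = _single_trait_vc(1.0, 1.0)
        data = pd.DataFrame({"animal": ["s", "s", "d", "d"], "y": [2.0, 1.0, -1.0, 0.0]})
        sol = solve_blup(build_mme(TraitModelSpec(traits=["y"]), data, ped, vc))
        assert sol.a.loc["c", "y"] == pytest.approx(
            0.5 * (sol.a.loc["s", "y"] + sol.a.loc["d", "y"])
        )

    def test_duplicating_every_record_keeps_fixed_effects(self, rng):
        ped = half_sib_pedigree(5, 4)
        off = [i for i in ped.ids if "O" in i]
        vc = _single_trait_vc(1.0, 1.0)
        data, _ = simulate_records(ped, off, vc, 1, rng)
        spec = TraitModelSpec(traits=["y"])
        b1 = solve_blup(build_mme(spec, data, ped, vc)).fixed["y"]
        doubled = pd.concat([data, data], ignore_index=True)
        b2 = solve_blup(build_mme(spec, doubled, ped, vc)).fixed["y"]
        assert b1["(intercept)"] == pytest.approx(b2["(intercept)"], abs=1e-8)

    def test_iterative_solver_matches_direct(self, rng, monkeypatch):
        ped = half_sib_pedigree(6, 5)
        off = [i for i in ped.ids if "O" in i]
        vc = _single_trait_vc(1.0, 0.8, 0.4)
        data, _ = simulate_records(ped, off, vc, 2, rng)
        spec = TraitModelSpec(traits=["y"], pe_traits=["y"])
        system = build_mme(spec, data, ped, vc)
        direct = system.solve(vc)
        monkeypatch.setattr(mm, "DIRECT_SOLVE_LIMIT", 0)
        iterative = system.solve(vc)
        assert np.allclose(direct.theta, iterative.theta, atol=1e-6)

    def test_residuals_satisfy_identity(self, rng):
        ped = half_sib_pedigree(4, 4)
        off = [i for i in ped.ids if "O" in i]
        vc = _single_trait_vc(1.0, 1.0, 0.3)
        data, _ = simulate_records(ped, off, vc, 2, rng)
        spec = TraitModelSpec(traits=["y"], pe_traits=["y"])
        sol = solve_blup(build_mme(spec, data, ped, vc))
        recon = (
            sol.fixed["y"]["(intercept)"]
            + sol.a["y"].loc[data["animal"]].to_numpy()
            + sol.p["y"].loc[data["animal"]].to_numpy()
            + sol.residuals["y"].to_numpy()
        )
        assert np.allclose(recon, data["y"], atol=1e-8)


class TestEmReml:
    def test_loglik_trace_is_monotone(self, rng):
        ped = half_sib_pedigree(10, 6)
        off = [i for i in ped.ids if "O" in i]
        truth = _single_trait_vc(0.5, 0.3, 0.2)
        data, _ = simulate_records(ped, off, truth, 3, rng)
        _, trace, _ = em_reml(
            TraitModelSpec(traits=["y"], pe_traits=["y"]), data, ped, tol=1e-4
        )
        assert np.all(np.diff(trace) >= -1e-6)

    def test_null_heritability_recovered_at_boundary(self, rng):
        ped = half_sib_pedigree(30, 10)
        off = [i for i in ped.ids if "O" in i]
        truth = _single_trait_vc(1e-12, 0.5, 0.5)
        data, _ = simulate_records(ped, off, truth, 2, rng)
        vc, _, _ = em_reml(
            TraitModelSpec(traits=["y"], pe_traits=["y"]), data, ped, tol=1e-5
        )
        assert genetic_parameters(vc).heritability.iloc[0] < 0.05

    def test_matches_half_sib_anova_oracle(self, rng):
        # balanced paternal half-sib, single records: h2 from the sire
        # variance component, 4 * s2_s / (s2_s + s2_w)
        ped = half_sib_pedigree(40, 20)
        off = [i for i in ped.ids if "O" in i]
        truth = _single_trait_vc(0.4, 0.6)
        data, _ = simulate_records(ped, off, truth, 1, rng)
        vc, _, _ = em_reml(TraitModelSpec(traits=["y"]), data, ped, tol=1e-6)
        h2_reml = genetic_parameters(vc).heritability.iloc[0]
        sires = data["animal"].str.split("O").str[0]
        grp = data.groupby(sires.to_numpy())["y"]
        k = 20
        means = grp.mean()
        msb = k * means.var(ddof=1)
        msw = grp.apply(lambda v: v.var(ddof=1)).mean()
        s2_s = (msb - msw) / k
        h2_anova = 4 * s2_s / (s2_s + msw)
        assert abs(h2_reml - h2_anova) < 0.05

    def test_repeated_trait_equals_bitrait_with_unit_correlation(self, rng):
        # one repeated trait == two traits with r_g -> 1 and equal variances
        ped = half_sib_pedigree(8, 6)
        off = [i for i in ped.ids if "O" in i]
        truth = _single_trait_vc(0.5, 0.5)
        sa, se = 0.5, 0.5
        data, _ = simulate_records(ped, off, truth, 2, rng)
        data["type"] = np.tile(["working", "medium"], len(off))
        single_spec = TraitModelSpec(traits=["y"], fixed={"y": ["type"]})
        single = build_mme(single_spec, data, ped)
        ll_single = single.loglik(_single_trait_vc(sa, se))

        wide = pd.DataFrame(
            {
                "animal": off,
                "working": data[data["type"] == "working"]["y"].to_numpy(),
                "medium": data[data["type"] == "medium"]["y"].to_numpy(),
            }
        )
        r = 1 - 1e-4
        vc2 = VarianceComponents(
            ["working", "medium"],
            sa * np.array([[1, r], [r, 1]]),
            np.zeros((0, 0)),
            se * np.eye(2),
            [],
        )
        bi = build_mme(TraitModelSpec(traits=["working", "medium"]), wide, ped)
        assert bi.loglik(vc2) == pytest.approx(ll_single, abs=0.05)

    def test_zero_pattern_preserved_exactly(self, rng):
        # height as covariate on a gait trait, residual covariance
        # constrained to zero (structured-equation treatment)
        ped = half_sib_pedigree(15, 6)
        off = [i for i in ped.ids if "O" in i]
        G = np.array([[0.4, 0.1], [0.1, 0.3]])
        R = np.array([[0.6, 0.0], [0.0, 0.7]])
        truth = VarianceComponents(["gait", "height"], G, np.zeros((0, 0)), R, [])
        data, _ = simulate_records(ped, off, truth, 1, rng)
        height = data[["animal", "height"]].copy()
        height["gait"] = np.nan
        gait = data[["animal", "gait"]].copy()
        gait["height_cov"] = data["height"].to_numpy()
        gait["height"] = np.nan
        height["height_cov"] = 0.0
        stacked = pd.concat([gait, height], ignore_index=True)
        spec = TraitModelSpec(
            traits=["gait", "height"],
            covariates={"gait": ["height_cov"]},
            r_zero_pairs=[("gait", "height")],
        )
        vc, trace, _ = em_reml(spec, stacked, ped, tol=1e-4)
        assert vc.R[0, 1] == 0.0
        assert np.all(np.diff(trace) >= -1e-6)

    def test_singular_residual_block_is_reported(self, rng):
        ped = _unrelated(4)
        data = pd.DataFrame(
            {"animal": ped.ids, "y1": [1.0, 2.0, 3.0, 4.0], "y2": [1.0, 2.0, 3.0, 4.0]}
        )
        spec = TraitModelSpec(traits=["y1", "y2"])
        vc = VarianceComponents(
            ["y1", "y2"], np.eye(2), np.zeros((0, 0)), np.ones((2, 2)), []
        )
        with pytest.raises(mm.MixedModelError, match="singular residual"):
            build_mme(spec, data, ped, vc).solve()

    def test_non_psd_start_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            VarianceComponents(["a", "b"], [[1.0, 2.0], [2.0, 1.0]], np.zeros((0, 0)), np.eye(2), [])


class TestGeneticParameters:
    def test_equal_components_give_third(self):
        vc = VarianceComponents(
            ["a", "b"], np.eye(2), np.eye(2), np.eye(2), ["a", "b"]
        )
        pars = genetic_parameters(vc)
        assert np.allclose(pars.heritability, 1 / 3)
        assert np.allclose(pars.repeatability, 2 / 3)

    def test_diagonal_components_give_zero_correlations(self):
        vc = VarianceComponents(
            ["a", "b"], np.diag([0.5, 0.4]), np.zeros((0, 0)), np.diag([0.5, 0.6]), []
        )
        pars = genetic_parameters(vc)
        assert pars.genetic_correlation.loc["a", "b"] == 0.0
        assert pars.phenotypic_correlation.loc["a", "b"] == 0.0

    def test_two_trait_recovery_matches_breeding_value_correlation(self, rng):
        G = np.array([[0.5, 0.3], [0.3, 0.5]])
        R = np.array([[0.5, 0.1], [0.1, 0.5]])
        truth = VarianceComponents(["u", "v"], G, np.zeros((0, 0)), R, [])
        ped = half_sib_pedigree(40, 8)
        off = [i for i in ped.ids if "O" in i]
        data, bv = simulate_records(ped, off, truth, 1, rng)
        vc, _, _ = em_reml(TraitModelSpec(traits=["u", "v"]), data, ped, tol=1e-4)
        est = genetic_parameters(vc).genetic_correlation.loc["u", "v"]
        true_sample = np.corrcoef(bv["u"], bv["v"])[0, 1]
        assert abs(est - true_sample) < 0.25

    def test_zero_total_variance_raises(self):
        vc = VarianceComponents(["a"], [[0.0]], np.zeros((0, 0)), [[0.0]], [])
        with pytest.raises(ValueError, match="zero total variance"):
            genetic_parameters(vc)

    def test_start_values_split_phenotypic_variance(self, rng):
        data = pd.DataFrame({"animal": [f"a{i}" for i in range(50)], "y": rng.normal(2, 3, 50)})
        vc = start_values(TraitModelSpec(traits=["y"], pe_traits=["y"]), data)
        total = vc.G[0, 0] + vc.P[0, 0] + vc.R[0, 0]
        assert total == pytest.approx(np.var(data["y"], ddof=1))
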