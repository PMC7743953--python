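"""Parameter-recovery and calibration experiments.

Each function here is a self-contained simulation study: it generates data
with the :mod:`~equigen.simulate` generator at a stated design, runs the
estimation machinery, and reports how well the truth is recovered.  They
double as end-to-end validation of the pipeline and as documentation of
the operating characteristics of the methods at desk scale.

All experiments are deterministic given their seed; replicate seeds are
spawned from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scoring
from .attenuation import monte_carlo_attenuated_correlation, residual_scores
from .gwas import grammar_scan, qc_filter
from .mixed_models import (
    TraitModelSpec,
    VarianceComponents,
    em_reml,
    genetic_parameters,
)
from .pedigree import Pedigree, a_inverse, a_matrix
from .simulate import (
    CompetitionSimConfig,
    GenotypeSimConfig,
    JudgeSimConfig,
    PedigreeSimConfig,
    QtlSpec,
    StudyConfig,
    _qtl_overlay,
    half_sib_pedigree,
    simulate_genotypes,
    simulate_records,
    simulate_study,
)

__all__ = [
    "random_pedigree",
    "relationship_inverse_check",
    "h2_recovery_experiment",
    "bitrait_recovery_experiment",
    "grammar_null_calibration",
    "grammar_power_experiment",
    "score_reversal_experiment",
    "attenuation_mc_grid",
]


# --------------------------------------------------------------------------- #
# relationship algebra

def random_pedigree(n: int, rng: np.random.Generator, p_known: float = 0.9) -> Pedigree:
    """Random overlapping-generation pedigree with inbreeding loops.

    Parents are drawn among all earlier individuals, so ancestral loops
    (e.g. sire also being a maternal grandsire) arise naturally.
    """
    n0 = max(4, n // 10)
    records: list[tuple[str, str | None, str | None]] = [
        (f"I{i}", None, None) for i in range(n0)
    ]
    for i in range(n0, n):
        sire = f"I{rng.integers(i)}" if rng.random() < p_known else None
        dam = f"I{rng.integers(i)}" if rng.random() < p_known else None
        if dam == sire:
            dam = None
        records.append((f"I{i}", sire, dam))
    return Pedigree.from_records(records)


def relationship_inverse_check(
    n_pedigrees: int = 50, max_size: int = 300, seed: int = 0
) -> dict:
    """Max |A^-1 A - I| over random inbred pedigrees (dense-inverse oracle)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    mean_f = []
    for _ in range(n_pedigrees):
        n = int(rng.integers(20, max_size + 1))
        ped = random_pedigree(n, rng)
        A, factors = a_matrix(ped)
        err = np.abs(a_inverse(ped).toarray() @ A - np.eye(n)).max()
        worst = max(worst, float(err))
        mean_f.append(factors.inbreeding.mean())
    return {"max_error": worst, "mean_inbreeding": float(np.mean(mean_f))}


# --------------------------------------------------------------------------- #
# REML recovery

def h2_recovery_experiment(
    n_reps: int = 20,
    seed: int = 0,
    n_sires: int = 40,
    n_per_sire: int = 10,
    n_records: int = 5,
    h2: float = 0.5,
    repeatability: float = 0.7,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> dict:
    """Single-trait repeatability design: recover h2 and repeatability.

    Paternal half-sib families, ``n_records`` records per phenotyped horse
    (n_sires * n_per_sire * n_records records in total), unit phenotypic
    variance split as (h2, repeatability - h2, 1 - repeatability).
    """
    truth = VarianceComponents(
        ["t"], [[h2]], [[repeatability - h2]], [[1.0 - repeatability]], ["t"]
    )
    spec = TraitModelSpec(traits=["t"], pe_traits=["t"])
    rngs = np.random.default_rng(seed).spawn(n_reps)
    h2_hat, rep_hat = [], []
    for rng in rngs:
        ped = half_sib_pedigree(n_sires, n_per_sire)
        offspring = [i for i in ped.ids if "O" in i]
        data, _ = simulate_records(ped, offspring, truth, n_records, rng)
        vc, _, _ = em_reml(spec, data, relationship=ped, tol=tol, max_iter=max_iter)
        pars = genetic_parameters(vc)
        h2_hat.append(float(pars.heritability.iloc[0]))
        rep_hat.append(float(pars.repeatability.iloc[0]))
    return {
        "true_h2": h2,
        "true_repeatability": repeatability,
        "mean_h2": float(np.mean(h2_hat)),
        "mean_repeatability": float(np.mean(rep_hat)),
        "h2_reps": h2_hat,
        "repeatability_reps": rep_hat,
    }


def bitrait_recovery_experiment(
    n_reps: int = 20,
    seed: int = 0,
    n_sires: int = 40,
    n_per_sire: int = 10,
    h2: float = 0.45,
    r_g: float = 0.9,
    r_e: float = 0.4,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> dict:
    """Working/medium bi-trait model: recover the genetic correlation.

    Each phenotyped horse carries one working and one medium record of the
    same measurement, modelled as two traits with additive effects only
    (no permanent environment), the structure used to decide whether the
    two gaits are genetically the same trait.
    """
    G = h2 * np.array([[1.0, r_g], [r_g, 1.0]])
    R = (1 - h2) * np.array([[1.0, r_e], [r_e, 1.0]])
    truth = VarianceComponents(["working", "medium"], G, np.zeros((0, 0)), R, [])
    spec = TraitModelSpec(traits=["working", "medium"])
    rngs = np.random.default_rng(seed).spawn(n_reps)
    rg_hat = []
    for rng in rngs:
        ped = half_sib_pedigree(n_sires, n_per_sire)
        offspring = [i for i in ped.ids if "O" in i]
        data, _ = simulate_records(ped, offspring, truth, 1, rng)
        vc, _, _ = em_reml(spec, data, relationship=ped, tol=tol, max_iter=max_iter)
        rg_hat.append(
            float(genetic_parameters(vc).genetic_correlation.loc["working", "medium"])
        )
    return {"true_r_g": r_g, "mean_r_g": float(np.mean(rg_hat)), "r_g_reps": rg_hat}


# --------------------------------------------------------------------------- #
# GRAMMAR GWAS

def _polygenic_residual_response(
    ped: Pedigree,
    animals: list[str],
    h2: float,
    rng: np.random.Generator,
    extra: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> pd.Series:
    """First GRAMMAR step for a single-record trait: REML fit, residuals."""
    truth = VarianceComponents(["y"], [[h2]], np.zeros((0, 0)), [[1.0 - h2]], [])
    data, _ = simulate_records(ped, animals, truth, 1, rng)
    if extra is not None:
        data["y"] = data["y"].to_numpy() + extra
    spec = TraitModelSpec(traits=["y"])
    vc, _, _ = em_reml(spec, data, relationship=ped, tol=tol, max_iter=max_iter)
    from .mixed_models import build_mme

    sol = build_mme(spec, data, ped, vc).solve()
    resid = sol.residuals.groupby("animal")["y"].mean()
    return resid


def grammar_null_calibration(
    seed: int = 0,
    n_snps: int = 10_000,
    n_sires: int = 70,
    n_per_sire: int = 10,
    h2: float = 0.4,
) -> np.ndarray:
    """P-values of a scan where the response is permuted against genotypes.

    The polygenic first step runs on the real family structure; the
    residuals are then permuted so every SNP is null.  Returns the p-value
    vector (uniform under correct calibration).
    """
    rng = np.random.default_rng(seed)
    ped = half_sib_pedigree(n_sires, n_per_sire)
    offspring = [i for i in ped.ids if "O" in i]
    geno, _, miss = simulate_genotypes(
        ped, GenotypeSimConfig(n_snps=n_snps, qtl=None), rng
    )
    dos = geno.dosages.copy()
    dos[miss] = np.nan
    geno.dosages = dos
    resid = _polygenic_residual_response(ped, offspring, h2, rng)
    permuted = pd.Series(
        rng.permutation(resid.loc[offspring].to_numpy()), index=offspring
    )
    scan = grammar_scan(permuted, geno.subset_individuals(offspring))
    return scan.loc[scan["flag"] == "", "p"].to_numpy()


def grammar_power_experiment(
    n_reps: int = 20,
    seed: int = 0,
    n_sires: int = 70,
    n_per_sire: int = 10,
    n_snps: int = 1000,
    qtl_var: float = 0.10,
    h2_polygenic: float = 0.25,
) -> dict:
    """Injected-QTL detection rate: is the QTL the minimum-p SNP?

    One QTL explaining ``qtl_var`` of the response variance is dropped
    through the pedigree; each replicate re-simulates genotypes and
    phenotypes, reruns the polygenic first step, QC and the scan.
    """
    rngs = np.random.default_rng(seed).spawn(n_reps)
    hits = 0
    for rng in rngs:
        ped = half_sib_pedigree(n_sires, n_per_sire)
        offspring = [i for i in ped.ids if "O" in i]
        geno, freqs, miss = simulate_genotypes(
            ped, GenotypeSimConfig(n_snps=n_snps, qtl=None), rng
        )
        qtl = QtlSpec(trait="y", chrom="3", position=105_652_000, variance_explained=qtl_var)
        j, dev = _qtl_overlay(geno, freqs, qtl, 1.0, rng)
        qtl_snp = geno.snps.loc[j, "snp"]
        col = {a: k for k, a in enumerate(geno.ids)}
        extra = np.array([dev[col[a]] for a in offspring])
        resid = _polygenic_residual_response(ped, offspring, h2_polygenic, rng, extra=extra)
        dos = geno.dosages.copy()
        dos[miss] = np.nan
        geno.dosages = dos
        filtered, _ = qc_filter(geno.subset_individuals(offspring))
        scan = grammar_scan(resid, filtered)
        if scan.loc[scan["p"].idxmin(), "snp"] == qtl_snp:
            hits += 1
    return {"hits": hits, "n_reps": n_reps}


# --------------------------------------------------------------------------- #
# raw vs residual scores

def score_reversal_experiment(
    n_reps: int = 10,
    seed: int = 0,
    n_measured: int = 220,
    k_pa: float = 1.0,
    tol: float = 5e-4,
    max_iter: int = 80,
) -> dict:
    """End-to-end raw vs EBV-residualized score-competition correlation.

    Each replicate simulates a small study in which judges' scores carry a
    parent-average-EBV component (weight ``k_pa``), derives the annual
    competition trait from simulated event ranks, and estimates the
    bivariate genetic correlation between score and competition twice:
    with the raw scores and with the scores residualized on the PA EBV.
    With ``k_pa > 0`` the raw correlation is positive and the residual one
    collapses toward (or below) zero.
    """
    seeds = np.random.default_rng(seed).integers(2**31 - 1, size=n_reps)
    raw_rg, res_rg = [], []
    for rep_seed in seeds:
        cfg = StudyConfig(
            seed=int(rep_seed),
            pedigree=PedigreeSimConfig(
                n_founders=60, n_generations=2, n_per_generation=n_measured, prop_sires=0.25
            ),
            n_measured=n_measured,
            n_genotyped=2,
            n_events=8,
            genotypes=GenotypeSimConfig(n_snps=12, chroms=("3",), missing_rate=0.0, qtl=None),
            competition=CompetitionSimConfig(
                years=(2015, 2016, 2017), starts_per_horse_year=3, n_starters=12
            ),
            judge=JudgeSimConfig(k_pa=k_pa),
        )
        study = simulate_study(cfg)
        annual = scoring.annual_performance(study.competitions)
        resid_tbl, _ = residual_scores(study.scores, study.ebv)

        def _fit(score_col: pd.DataFrame) -> float:
            rows = [
                {"animal": h, "score": s, "perf": np.nan, "year": "none"}
                for h, s in zip(score_col["horse"], score_col.iloc[:, 1])
            ]
            rows += [
                {"animal": h, "score": np.nan, "perf": lp, "year": str(y)}
                for h, y, lp in zip(annual["horse"], annual["year"], annual["log_points"])
            ]
            data = pd.DataFrame(rows)
            spec = TraitModelSpec(
                traits=["score", "perf"], fixed={"perf": ["year"]}, pe_traits=["perf"]
            )
            vc, _, _ = em_reml(
                spec, data, relationship=study.pedigree, tol=tol, max_iter=max_iter
            )
            return float(genetic_parameters(vc).genetic_correlation.loc["score", "perf"])

        raw_rg.append(_fit(study.scores[["horse", "score"]]))
        res_rg.append(_fit(resid_tbl[["horse", "residual_score"]]))
    raw = np.array(raw_rg)
    res = np.array(res_rg)
    return {
        "raw_r_g": raw_rg,
        "residual_r_g": res_rg,
        "n_raw_positive": int((raw > 0).sum()),
        "n_residual_smaller": int((res < raw).sum()),
        "n_reps": n_reps,
    }


# --------------------------------------------------------------------------- #
# attenuation formula vs Monte Carlo

def attenuation_mc_grid(
    seed: int = 0,
    n: int = 100_000,
    r_grid: tuple = (0.2, 0.4, 0.7),
    cd_grid: tuple = (0.15, 0.312, 0.45),
) -> pd.DataFrame:
    """Closed form vs structural Monte Carlo on a (r_a, CD0) grid."""
    rng = np.random.default_rng(seed)
    rows = []
    for r_a in r_grid:
        for cd0 in cd_grid:
            mc = monte_carlo_attenuated_correlation(r_a, cd0, n=n, rng=rng)
            rows.append(
                {
                    "r_a": r_a,
                    "cd0": cd0,
                    "formula": mc["r_formula"],
                    "monte_carlo": mc["r_mc"],
                    "mc_se": mc["se"],
                }
            )
    return pd.DataFrame(rows)
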