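"""End-to-end orchestration of the synthetic study and all analysis stages.

``run_pipeline`` executes, in order: data simulation; annual competition
scoring; the working/medium bi-trait check; per-gait adjustment + PCA and
record-level PC traits; per-PC animal-model REML/BLUP (the GRAMMAR first
step) with height as a covariate; SNP QC and the GRAMMAR scan; a
three-trait (PC, judges' score, competition) correlation run with diagonal
residual structure; and the EBV-residual attenuation analysis.  Every
stage writes a TSV artifact into the output directory and the run is
deterministic given the seed.

REML stages operate on a configurable subsample of the measured horses
(``max_reml_animals``) with ancestors to four generations, keeping the
dense equations at desk scale while the simulated population itself can be
study-sized.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, scoring
from .attenuation import expected_attenuated_correlation, residual_scores
from .gaits_pca import adjust_phenotypes, fit_pca, pc_scores
from .gwas import grammar_scan, manhattan_table, qc_filter
from .mixed_models import (
    TraitModelSpec,
    build_mme,
    em_reml,
    genetic_parameters,
)
from .pedigree import extract_ancestors
from .simulate import StudyConfig, StudyData, simulate_study

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    study: StudyConfig = field(default_factory=StudyConfig)
    score_scale: float = 1.0
    score_base: float = 2.0
    maf_min: float = 0.02
    hwe_min: float = 1e-6
    callrate_min: float = 0.90
    max_reml_animals: int = 400
    reml_tol: float = 1e-4
    reml_max_iter: int = 120
    pedigree_depth: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study_raw = raw.pop("study", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        for k, v in study_raw.items():
            fdef = {f.name: f for f in dataclasses.fields(StudyConfig)}
            if k in fdef:
                cur = getattr(cfg.study, k)
                if dataclasses.is_dataclass(cur) and isinstance(v, dict):
                    setattr(cfg.study, k, dataclasses.replace(cur, **v))
                else:
                    setattr(cfg.study, k, v)
        return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_study(study: StudyData, out: Path) -> list[str]:
    study.pedigree.to_frame().to_csv(out / "pedigree.csv", index=False)
    io.write_table(study.gait_records, out / "gait_records.tsv")
    io.write_table(study.height, out / "height.tsv")
    io.write_genotypes(study.genotypes, out / "genotypes.tsv")
    io.write_table(study.competitions, out / "competitions.tsv")
    io.write_table(study.scores, out / "scores.tsv")
    io.write_table(study.ebv, out / "ebv.tsv")
    return [
        "pedigree.csv",
        "gait_records.tsv",
        "height.tsv",
        "genotypes.tsv",
        "competitions.tsv",
        "scores.tsv",
        "ebv.tsv",
    ]


def _bitrait_check(cfg: PipelineConfig, study: StudyData, relationship, sub: list[str]) -> pd.DataFrame:
    """Model-(1) analogue: working vs medium DVD at trot as two traits."""
    rec = study.gait_records
    rows = rec[(rec["gait"] == "T") & (rec["horse"].isin(sub))]
    wide = rows.pivot_table(
        index="horse", columns="type", values=["DVD", "velocity"], aggfunc="first"
    )
    data = pd.DataFrame(
        {
            "animal": wide.index,
            "dvd_working": wide[("DVD", "working")].to_numpy(),
            "dvd_medium": wide[("DVD", "medium")].to_numpy(),
            "vel_working": wide[("velocity", "working")].to_numpy(),
            "vel_medium": wide[("velocity", "medium")].to_numpy(),
        }
    ).reset_index(drop=True)
    meta = rows.drop_duplicates("horse").set_index("horse")
    data["gender"] = meta.loc[data["animal"], "gender"].to_numpy()
    data["age"] = meta.loc[data["animal"], "age"].to_numpy()
    data["event"] = meta.loc[data["animal"], "event"].to_numpy()
    spec = TraitModelSpec(
        traits=["dvd_working", "dvd_medium"],
        fixed={t: ["gender", "age", "event"] for t in ("dvd_working", "dvd_medium")},
        covariates={"dvd_working": ["vel_working"], "dvd_medium": ["vel_medium"]},
    )
    vc, _, info = em_reml(
        spec, data, relationship=relationship, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter
    )
    pars = genetic_parameters(vc)
    return pd.DataFrame(
        {
            "trait": ["dvd_working", "dvd_medium"],
            "h2": pars.heritability.to_numpy(),
            "r_g": pars.genetic_correlation.iloc[0, 1],
            "r_p": pars.phenotypic_correlation.iloc[0, 1],
            "converged": info["converged"],
        }
    )


def _pc_record_table(study: StudyData, models: dict) -> pd.DataFrame:
    """Record-level PC trait values with covariates, all gaits stacked."""
    rec = study.gait_records.merge(study.height, on="horse", how="left")
    frames = []
    for gait, model in models.items():
        rows = rec[rec["gait"] == gait].reset_index(drop=True)
        scores = pc_scores(model, rows)
        keep = rows[["horse", "gait", "type", "velocity", "event", "gender", "age", "height"]]
        frames.append(pd.concat([keep, scores], axis=1))
    return pd.concat(frames, ignore_index=True)


def _pc_truth(study: StudyData, models: dict) -> dict:
    """Generator-implied h2 of each PC trait (quadratic form in the loadings)."""
    vc = study.trait_system
    traits = list(vc.traits)
    Ppad = vc.p_padded()
    out = {}
    for gait, model in models.items():
        names = [f"{gait}_{m}" for m in model.measurements]
        idx = [traits.index(n) for n in names]
        for r, comp in enumerate(model.component_names):
            w = model.eigenvectors[:, r]
            num = w @ vc.G[np.ix_(idx, idx)] @ w
            den = w @ (vc.G + Ppad + vc.R)[np.ix_(idx, idx)] @ w
            out[comp] = float(num / den)
    return out


def _fit_pc_models(cfg: PipelineConfig, study: StudyData, pc_records, relationship, sub):
    """Per-PC animal-model REML/BLUP: GRAMMAR first step + h2 estimates."""
    results = []
    responses = {}
    for comp in [c for c in pc_records.columns if c.startswith("PC")]:
        gait = comp[2]
        rows = pc_records[pc_records[comp].notna() & pc_records["horse"].isin(sub)].copy()
        rows = rows.rename(columns={"horse": "animal"})
        repeated = gait in ("T", "C")
        covs = ["height"]
        if repeated:
            for typ in ("working", "medium"):
                rows[f"vel_{typ}"] = np.where(rows["type"] == typ, rows["velocity"], 0.0)
            covs = ["vel_working", "vel_medium", "height"]
        else:
            covs = ["velocity", "height"]
        rows = rows[rows["height"].notna()]
        spec = TraitModelSpec(
            traits=[comp],
            fixed={comp: ["gender", "age", "event"] + (["type"] if repeated else [])},
            covariates={comp: covs},
            pe_traits=[comp] if repeated else [],
        )
        vc, _, info = em_reml(
            spec, rows, relationship=relationship, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter
        )
        sol = build_mme(spec, rows, relationship, vc).solve()
        if repeated:
            responses[comp] = sol.p[comp]
        else:
            responses[comp] = sol.residuals.groupby("animal")[comp].mean()
        pars = genetic_parameters(vc)
        results.append(
            {
                "trait": comp,
                "h2_hat": float(pars.heritability.iloc[0]),
                "repeatability_hat": float(pars.repeatability.iloc[0]),
                "converged": info["converged"],
            }
        )
    return pd.DataFrame(results), responses


def _height_fit(cfg: PipelineConfig, study: StudyData, relationship, sub):
    data = study.height[study.height["horse"].isin(sub)].rename(
        columns={"horse": "animal"}
    )
    spec = TraitModelSpec(traits=["height"])
    vc, _, _ = em_reml(
        spec, data, relationship=relationship, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter
    )
    sol = build_mme(spec, data, relationship, vc).solve()
    resid = sol.residuals.groupby("animal")["height"].mean()
    h2 = float(genetic_parameters(vc).heritability.iloc[0])
    return h2, resid


def _three_trait(cfg: PipelineConfig, study, pc_records, annual, score_col, relationship, sub, pc_name):
    rows = []
    pcr = pc_records[pc_records[pc_name].notna() & pc_records["horse"].isin(sub)]
    for _, r in pcr.iterrows():
        rows.append(
            {
                "animal": r["horse"],
                "pc": r[pc_name],
                "score": np.nan,
                "perf": np.nan,
                "gender": r["gender"],
                "age": str(r["age"]),
                "event": r["event"],
                "type": r["type"],
                "velocity": r["velocity"],
                "year": "none",
            }
        )
    for _, r in score_col.iterrows():
        if r["horse"] in set(sub):
            rows.append(
                {
                    "animal": r["horse"],
                    "pc": np.nan,
                    "score": r.iloc[1],
                    "perf": np.nan,
                    "gender": "female",
                    "age": "0",
                    "event": "none",
                    "type": "none",
                    "velocity": 0.0,
                    "year": "none",
                }
            )
    for _, r in annual.iterrows():
        if r["horse"] in set(sub):
            rows.append(
                {
                    "animal": r["horse"],
                    "pc": np.nan,
                    "score": np.nan,
                    "perf": r["log_points"],
                    "gender": "female",
                    "age": "0",
                    "event": "none",
                    "type": "none",
                    "velocity": 0.0,
                    "year": str(r["year"]),
                }
            )
    data = pd.DataFrame(rows)
    repeated_pc = pc_name[2] in ("T", "C")
    spec = TraitModelSpec(
        traits=["pc", "score", "perf"],
        fixed={"pc": ["gender", "age", "event"] + (["type"] if repeated_pc else []), "perf": ["year"]},
        covariates={"pc": ["velocity"]},
        pe_traits=(["pc"] if repeated_pc else []) + ["perf"],
        r_zero_pairs=[("pc", "score"), ("pc", "perf"), ("score", "perf")],
    )
    vc, _, info = em_reml(
        spec, data, relationship=relationship, tol=cfg.reml_tol, max_iter=cfg.reml_max_iter
    )
    pars = genetic_parameters(vc)
    return vc, pars, info


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic data; returns a report dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.study.seed, "version": __version__, "config_hash": _config_hash(cfg)}

    study = simulate_study(cfg.study)
    artifacts = _write_study(study, out)

    annual = scoring.annual_performance(
        study.competitions, scale=cfg.score_scale, base=cfg.score_base
    )
    io.write_table(annual, out / "annual_performance.tsv")
    artifacts.append("annual_performance.tsv")

    sub = study.measured[: cfg.max_reml_animals]
    relationship = extract_ancestors(study.pedigree, sub, cfg.pedigree_depth)

    bitrait = _bitrait_check(cfg, study, relationship, sub)
    io.write_table(bitrait, out / "bitrait_working_medium.tsv")
    artifacts.append("bitrait_working_medium.tsv")
    report["bitrait_r_g"] = float(bitrait["r_g"].iloc[0])

    models = {}
    for gait in ("T", "C", "W"):
        adj = adjust_phenotypes(study.gait_records, gait)
        models[gait] = fit_pca(adj, gait=gait)
        io.write_table(
            models[gait].loadings_frame().reset_index(names="measurement"),
            out / f"pca_loadings_{gait}.tsv",
        )
        artifacts.append(f"pca_loadings_{gait}.tsv")
    pc_records = _pc_record_table(study, models)
    io.write_table(pc_records, out / "pc_records.tsv")
    artifacts.append("pc_records.tsv")

    pc_fits, responses = _fit_pc_models(cfg, study, pc_records, relationship, sub)
    truth = _pc_truth(study, models)
    pc_fits["h2_generator"] = pc_fits["trait"].map(truth)
    io.write_table(pc_fits, out / "pc_genetic_parameters.tsv")
    artifacts.append("pc_genetic_parameters.tsv")

    h2_height, height_resid = _height_fit(cfg, study, relationship, sub)
    report["h2_height"] = h2_height

    filtered, qc_report = qc_filter(
        study.genotypes, cfg.maf_min, cfg.hwe_min, cfg.callrate_min
    )
    io.write_table(qc_report, out / "snp_qc.tsv")
    artifacts.append("snp_qc.tsv")
    pct1 = next(c for c in responses if c.startswith("PCT1"))
    scans = {"height": height_resid, pct1: responses[pct1]}
    top_hits = []
    for name, resp in scans.items():
        scan = grammar_scan(resp, filtered)
        io.write_table(scan, out / f"gwas_{name}.tsv")
        io.write_table(manhattan_table(scan), out / f"manhattan_{name}.tsv")
        artifacts += [f"gwas_{name}.tsv", f"manhattan_{name}.tsv"]
        best = scan.loc[scan["p"].idxmin()]
        top_hits.append(
            {"response": name, "snp": best["snp"], "chrom": best["chrom"], "pos": best["pos"], "p": best["p"]}
        )
    io.write_table(pd.DataFrame(top_hits), out / "gwas_top_hits.tsv")
    artifacts.append("gwas_top_hits.tsv")
    report["qtl_snp"] = study.meta.get("qtl", {}).get("snp", "")
    report["top_hit_height"] = top_hits[0]["snp"]

    pc_for_three = next(
        (c for c in pc_records.columns if c.startswith("PCC") and c.endswith("LGA")),
        next(c for c in pc_records.columns if c.startswith("PCC")),
    )
    vc3, pars3, _ = _three_trait(
        cfg, study, pc_records, annual, study.scores, relationship, sub, pc_for_three
    )
    io.write_table(
        pars3.genetic_correlation.reset_index(names="trait"),
        out / "three_trait_genetic_correlations.tsv",
    )
    artifacts.append("three_trait_genetic_correlations.tsv")
    report["three_trait_pc"] = pc_for_three

    resid_tbl, resid_info = residual_scores(study.scores, study.ebv)
    io.write_table(resid_tbl, out / "residual_scores.tsv")
    artifacts.append("residual_scores.tsv")
    raw_rg = float(pars3.genetic_correlation.loc["score", "perf"])
    expected = expected_attenuated_correlation(
        float(np.clip(raw_rg, -0.99, 0.99)), min(resid_info["mean_reliability"], 0.99)
    )
    atten = pd.DataFrame(
        [
            {
                "raw_score_perf_r_g": raw_rg,
                "mean_pa_reliability": resid_info["mean_reliability"],
                "expected_residual_r_g": expected,
                "regression_slope": resid_info["slope"],
            }
        ]
    )
    io.write_table(atten, out / "attenuation_report.tsv")
    artifacts.append("attenuation_report.tsv")
    report["raw_score_perf_r_g"] = raw_rg
    report["expected_residual_r_g"] = expected

    log = [
        f"equigen {__version__}",
        f"seed {cfg.study.seed}",
        f"config_hash {report['config_hash']}",
        "artifacts " + " ".join(artifacts),
    ]
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    report["artifacts"] = artifacts
    return report
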