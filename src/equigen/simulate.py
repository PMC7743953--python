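"""Synthetic horse-population generator.

Reproduces the statistical structure the downstream analyses assume, so the
whole pipeline is testable without external data: a multi-generation
pedigree with half-sib family structure; multivariate breeding values by
generation-wise Mendelian sampling under a genetic covariance G (so
inbreeding shrinks within-family variance without ever factorizing
A (x) G); permanent-environment effects and structured residuals; repeated
working/medium gait records for trot and canter and single walk records
with velocity, gender, age and event fixed effects; SNP genotypes by
single-locus gene dropping with one major height QTL; competition ranks
driven by a heritable latent performance; and judges' scores containing a
component proportional to the horse's parent-average EBV for competition.

All randomness flows from one seed through ``numpy.random.Generator.spawn``
substreams, so every output is reproducible bit-for-bit for a given seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .mixed_models import VarianceComponents
from .pedigree import Pedigree, relationship_factors

__all__ = [
    "PedigreeSimConfig",
    "QtlSpec",
    "GenotypeSimConfig",
    "CompetitionSimConfig",
    "JudgeSimConfig",
    "StudyConfig",
    "GenotypeMatrix",
    "StudyData",
    "simulate_pedigree",
    "half_sib_pedigree",
    "mendelian_breeding_values",
    "simulate_records",
    "simulate_genotypes",
    "default_trait_system",
    "simulate_study",
]

# --------------------------------------------------------------------------- #
# configuration

@dataclass
class PedigreeSimConfig:
    n_founders: int = 150
    n_generations: int = 3
    n_per_generation: int = 1500
    prop_sires: float = 0.12


@dataclass
class QtlSpec:
    trait: str = "height"
    chrom: str = "3"
    position: int = 105_652_000
    variance_explained: float = 0.15


@dataclass
class GenotypeSimConfig:
    n_snps: int = 5000
    chroms: Sequence[str] = ("1", "2", "3")
    chrom_length: int = 120_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    qtl: QtlSpec | None = field(default_factory=QtlSpec)


@dataclass
class CompetitionSimConfig:
    years: Sequence[int] = (2015, 2016, 2017)
    starts_per_horse_year: int = 4
    n_starters: int = 12
    n_levels: int = 5
    event_noise_sd: float = 0.5


@dataclass
class JudgeSimConfig:
    #: weight of the parent-average competition EBV (in score-SD units per
    #: standardized PA unit); 0 removes the mechanism entirely
    k_pa: float = 1.0
    sire_reliability: float = 0.62
    dam_reliability: float = 0.62


@dataclass
class StudyConfig:
    seed: int = 20201216
    pedigree: PedigreeSimConfig = field(default_factory=PedigreeSimConfig)
    n_measured: int = 1477
    n_genotyped: int = 702
    n_events: int = 26
    genotypes: GenotypeSimConfig = field(default_factory=GenotypeSimConfig)
    competition: CompetitionSimConfig = field(default_factory=CompetitionSimConfig)
    judge: JudgeSimConfig = field(default_factory=JudgeSimConfig)
    #: fixed-effect dispersion (SD units) for gender/age contrasts
    fixed_effect_sd: float = 0.15
    #: half-range of event effects, in phenotypic SD units (range ~ 1 SD)
    event_effect_range: float = 0.5


# --------------------------------------------------------------------------- #
# containers

@dataclass
class GenotypeMatrix:
    """SNP dosages, one row per SNP, columns aligned with ``ids``.

    ``dosages`` counts copies of the alternative allele (0/1/2, NaN for a
    missing call); positions are 1-based and strictly increasing within a
    chromosome.
    """

    snps: pd.DataFrame  # columns snp, chrom, pos
    dosages: np.ndarray  # (n_snps, n_individuals) float
    ids: list[str]

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.snps), len(self.ids)):
            raise ValueError("dosage matrix does not match SNP/individual lists")
        for _, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions not strictly increasing within chromosome")

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {v: k for k, v in enumerate(self.ids)}
        cols = [idx[i] for i in ids]
        return GenotypeMatrix(self.snps.copy(), self.dosages[:, cols], list(ids))


@dataclass
class StudyData:
    config: StudyConfig
    pedigree: Pedigree
    sex: pd.Series
    measured: list[str]
    genotyped: list[str]
    trait_system: VarianceComponents
    breeding_values: pd.DataFrame
    permanent_effects: pd.DataFrame
    gait_records: pd.DataFrame
    height: pd.DataFrame
    genotypes: GenotypeMatrix
    competitions: pd.DataFrame
    scores: pd.DataFrame
    ebv: pd.DataFrame
    meta: dict


# --------------------------------------------------------------------------- #
# pedigree

def simulate_pedigree(
    cfg: PedigreeSimConfig, rng: np.random.Generator
) -> tuple[Pedigree, pd.Series]:
    """Generation-structured pedigree with polygynous (half-sib) matings.

    Returns the sorted pedigree and a per-individual sex series ('M'/'F').
    Founders are generation 0; each later generation draws sires from a
    small male subset of the previous generation and dams from its females.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    ids = [f"G0_{k}" for k in range(cfg.n_founders)]
    sex = list(rng.choice(["M", "F"], size=cfg.n_founders, p=[0.5, 0.5]))
    records = [(i, None, None) for i in ids]
    prev = list(ids)
    prev_sex = list(sex)
    for g in range(1, cfg.n_generations + 1):
        males = [i for i, s in zip(prev, prev_sex) if s == "M"]
        females = [i for i, s in zip(prev, prev_sex) if s == "F"]
        if not males or not females:
            raise ValueError(f"generation {g - 1} lacks one sex; cannot mate")
        n_sires = max(1, int(round(cfg.prop_sires * len(males))))
        sires = list(rng.choice(males, size=n_sires, replace=False))
        cur, cur_sex = [], []
        for k in range(cfg.n_per_generation):
            child = f"G{g}_{k}"
            records.append((child, rng.choice(sires), rng.choice(females)))
            cur.append(child)
            cur_sex.append(rng.choice(["M", "F"]))
        sex += cur_sex
        prev, prev_sex = cur, cur_sex
    ped = Pedigree.from_records(records)
    sex_series = pd.Series(dict(zip([r[0] for r in records], sex))).reindex(ped.ids)
    return ped, sex_series


def half_sib_pedigree(n_sires: int, n_per_sire: int, prefix: str = "") -> Pedigree:
    """Paternal half-sib design: unrelated sires, unknown dams."""
    records = [(f"{prefix}S{j}", None, None) for j in range(n_sires)]
    for j in range(n_sires):
        for k in range(n_per_sire):
            records.append((f"{prefix}S{j}O{k}", f"{prefix}S{j}", None))
    return Pedigree.from_records(records)


# --------------------------------------------------------------------------- #
# trait values

def mendelian_breeding_values(
    ped: Pedigree,
    G: np.ndarray,
    rng: np.random.Generator,
    extra_additive: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Multivariate breeding values by generation-wise Mendelian sampling.

    Child value = mean of known parents + a within-family deviation with
    covariance ``d_i * G`` where ``d_i`` is the Mendelian-sampling variance
    from parental inbreeding (founders: ``d = 1``).  ``extra_additive``
    maps a pedigree id to an additive deviation vector added afterwards
    (used for major-QTL overlays).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    t = G.shape[0]
    w = np.linalg.eigvalsh((G + G.T) / 2)
    if w.min() < -1e-8 * max(w.max(), 1e-300):
        raise ValueError("G is not positive semi-definite")
    L = np.linalg.cholesky(G + 1e-12 * np.trace(G) / t * np.eye(t)) if np.trace(G) > 0 else np.zeros((t, t))
    factors = relationship_factors(ped)
    n = len(ped)
    a = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        mean = np.zeros(t)
        if s >= 0:
            mean += 0.5 * a[s]
        if d >= 0:
            mean += 0.5 * a[d]
        a[i] = mean + np.sqrt(factors.mendelian_variances[i]) * (L @ z[i])
    if np.trace(G) == 0:
        a[:] = 0.0
    if extra_additive:
        for name, dev in extra_additive.items():
            a[ped.index[name]] += dev
    return a


def simulate_records(
    ped: Pedigree,
    animals: Sequence[str],
    vc: VarianceComponents,
    n_records: int,
    rng: np.random.Generator,
    mu: float | np.ndarray = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plain repeated-records phenotypes under (G, P, R): y = mu + a + p + e.

    Each of ``animals`` gets ``n_records`` rows, every row observing all
    traits.  Returns (records, true breeding values for all pedigree
    animals).  The workhorse behind the parameter-recovery experiments.
    """
    traits = list(vc.traits)
    t = len(traits)
    a = mendelian_breeding_values(ped, vc.G, rng)
    a_df = pd.DataFrame(a, index=ped.ids, columns=traits)
    p = _draw_pe(vc, len(animals), rng)
    rows = []
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (t,))
    e = rng.multivariate_normal(
        np.zeros(t), vc.R, size=len(animals) * n_records, method="cholesky"
    )
    k = 0
    for j, animal in enumerate(animals):
        base = mu + a_df.loc[animal].to_numpy() + p[j]
        for _ in range(n_records):
            rows.append([animal] + list(base + e[k]))
            k += 1
    records = pd.DataFrame(rows, columns=["animal"] + traits)
    return records, a_df


def _draw_pe(
    vc: VarianceComponents, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Permanent-environment draws, zero columns for traits without pe."""
    t = len(vc.traits)
    out = np.zeros((n, t))
    if vc.P.size:
        idx = [list(vc.traits).index(x) for x in vc.pe_traits]
        out[:, idx] = rng.multivariate_normal(
            np.zeros(len(idx)), vc.P + 1e-12 * np.eye(len(idx)), size=n, method="cholesky"
        )
    return out


# --------------------------------------------------------------------------- #
# genotypes

def simulate_genotypes(
    ped: Pedigree, cfg: GenotypeSimConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Founder sampling plus single-locus gene dropping for all individuals.

    Founder dosages are Binomial(2, f) with per-SNP frequencies drawn
    uniformly from ``maf_range``; a child inherits from each parent one
    allele that is ALT with probability dosage/2 (unknown parents transmit
    from the base population).  Returns the complete (pre-missingness)
    matrix, the founder frequencies, and a missingness mask.
    """
    lo, hi = cfg.maf_range
    if not (0 < lo < hi < 1):
        raise ValueError("founder allele frequencies must lie in (0, 1)")
    m = cfg.n_snps
    freqs = rng.uniform(lo, hi, size=m)
    per_chrom = np.array_split(np.arange(m), len(cfg.chroms))
    snp_rows = []
    for chrom, idx in zip(cfg.chroms, per_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length, size=len(idx), replace=False)) + 1
        for j, p in zip(idx, pos):
            snp_rows.append((f"snp{j}", str(chrom), int(p)))
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos"])

    n = len(ped)
    dos = np.zeros((m, n), dtype=np.float64)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        p_sire = dos[:, s] / 2.0 if s >= 0 else freqs
        p_dam = dos[:, d] / 2.0 if d >= 0 else freqs
        dos[:, i] = (rng.random(m) < p_sire).astype(float) + (
            rng.random(m) < p_dam
        ).astype(float)
    miss = rng.random((m, n)) < cfg.missing_rate
    return GenotypeMatrix(snps, dos, list(ped.ids)), freqs, miss


def _qtl_overlay(
    geno: GenotypeMatrix,
    freqs: np.ndarray,
    qtl: QtlSpec,
    trait_sd: float,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Pick the panel SNP closest to the QTL position on its chromosome and
    return (snp index, per-individual additive deviation) scaled so the
    locus explains ``variance_explained`` of the trait's phenotypic
    variance in the founder population."""
    if not (0 <= qtl.variance_explained < 1):
        raise ValueError("variance_explained must be in [0, 1)")
    on_chrom = geno.snps.index[geno.snps["chrom"] == str(qtl.chrom)]
    if len(on_chrom) == 0:
        raise ValueError(f"no SNPs on chromosome {qtl.chrom!r}")
    j = int(on_chrom[np.argmin(np.abs(geno.snps.loc[on_chrom, "pos"] - qtl.position))])
    f = freqs[j]
    alpha = trait_sd * np.sqrt(qtl.variance_explained / (2 * f * (1 - f)))
    dev = alpha * (geno.dosages[j] - 2 * f)
    return j, dev


# --------------------------------------------------------------------------- #
# default trait system

def _load_defaults() -> dict:
    with importlib.resources.files("equigen.data").joinpath("gait_defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_trait_system(raw: dict | None = None) -> tuple[VarianceComponents, dict]:
    """Assemble (G, P, R) over gait measurements + height + competition +
    judge-intrinsic from the shipped factor-loading catalogue.

    Correlations come from ``C = L L' + diag(1 - ||l||^2)`` per component,
    scaled by the per-trait variance shares; residual correlations are kept
    within gait only (zero across gaits and with height), matching the
    record structure (each record carries one gait's measurements).
    Returns the trait system on the standardized scale and a metadata dict
    with means, SDs, velocity parameters and trait grouping.
    """
    raw = raw or _load_defaults()
    names: list[str] = []
    h2, pe_var, res_var = [], [], []
    g_loads, e_loads = [], []
    meta: dict = {"gaits": {}, "means": {}, "sds": {}, "beta_v": {}, "velocity": {}}
    for gait, gdef in raw["gaits"].items():
        code = gdef["code"]
        meta["velocity"][code] = gdef["velocity"]
        meta["gaits"][code] = []
        for mname, mdef in gdef["measurements"].items():
            trait = f"{code}_{mname}"
            names.append(trait)
            meta["gaits"][code].append(trait)
            if "mean" in mdef:
                meta["means"][trait] = {"walk": float(mdef["mean"])}
            else:
                meta["means"][trait] = {
                    "working": float(mdef["mean_working"]),
                    "medium": float(mdef["mean_medium"]),
                }
            meta["sds"][trait] = float(mdef["sd"])
            meta["beta_v"][trait] = float(mdef["beta_v"])
            h2.append(float(mdef["h2"]))
            pe_var.append(max(float(mdef.get("rep", mdef["h2"])) - float(mdef["h2"]), 0.0))
            res_var.append(1.0 - float(mdef["h2"]) - pe_var[-1])
            g_loads.append(mdef["g_load"])
            e_loads.append(mdef["e_load"])
    for extra, key in (("height", "height"), ("competition", "competition"), ("judge_intrinsic", "judge")):
        block = raw[key]
        names.append(extra)
        h2.append(float(block.get("h2", block.get("h2_intrinsic"))))
        rep = float(block.get("repeatability", h2[-1]))
        pe_var.append(max(rep - h2[-1], 0.0))
        res_var.append(1.0 - h2[-1] - pe_var[-1])
        g_loads.append(block["g_load"])
        e_loads.append([0.0] * len(block["g_load"]))
    meta["height"] = {"mean": float(raw["height"]["mean"]), "sd": float(raw["height"]["sd"])}
    meta["judge"] = {"mean": float(raw["judge"]["mean"]), "sd": float(raw["judge"]["sd"])}

    def _corr(loads: list) -> np.ndarray:
        L = np.asarray(loads, dtype=float)
        C = L @ L.T
        np.fill_diagonal(C, 1.0)
        return C

    h2 = np.asarray(h2)
    pe_var = np.asarray(pe_var)
    res_var = np.asarray(res_var)
    Cg = _corr(g_loads)
    Ce = _corr(e_loads)
    G = np.sqrt(np.outer(h2, h2)) * Cg
    pe_traits = [n for n, v in zip(names, pe_var) if v > 0]
    pe_idx = [names.index(n) for n in pe_traits]
    P = (np.sqrt(np.outer(pe_var, pe_var)) * Ce)[np.ix_(pe_idx, pe_idx)]
    # residual correlations within gait blocks only
    Rmask = np.zeros((len(names), len(names)), dtype=bool)
    for code, traits in meta["gaits"].items():
        idx = [names.index(t) for t in traits]
        Rmask[np.ix_(idx, idx)] = True
    R = np.sqrt(np.outer(res_var, res_var)) * Ce * Rmask
    np.fill_diagonal(R, res_var)
    vc = VarianceComponents(names, G, P, R, pe_traits)
    return vc, meta


# --------------------------------------------------------------------------- #
# study generator

def _parent_average_ebv(
    ped: Pedigree,
    horses: Sequence[str],
    a_comp: pd.Series,
    sigma_a: float,
    cd_sire: float,
    cd_dam: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Parent-average EBV for the competition trait with noisy parental
    evaluations of the stated reliabilities; PA reliability is
    (CD_sire + CD_dam) / 4.  Unknown parents contribute a zero EBV with
    zero reliability."""
    ebv_cache: dict[str, float] = {}

    def parent_ebv(pid: str | None, cd: float) -> tuple[float, float]:
        if pid is None:
            return 0.0, 0.0
        if pid not in ebv_cache:
            noise = np.sqrt(max(cd * (1 - cd), 0.0)) * sigma_a * rng.standard_normal()
            ebv_cache[pid] = cd * a_comp.loc[pid] + noise
        return ebv_cache[pid], cd

    rows = []
    for h in horses:
        sire, dam = ped.parents_of(h)
        es, cds = parent_ebv(sire, cd_sire)
        ed, cdd = parent_ebv(dam, cd_dam)
        rows.append((h, 0.5 * (es + ed), (cds + cdd) / 4.0))
    return pd.DataFrame(rows, columns=["horse", "pa_ebv", "reliability"])


def simulate_study(cfg: StudyConfig) -> StudyData:
    """Generate the complete synthetic study for a configuration."""
    master = np.random.default_rng(cfg.seed)
    rng_ped, rng_geno, rng_traits, rng_rec, rng_comp, rng_judge = master.spawn(6)

    ped, sex = simulate_pedigree(cfg.pedigree, rng_ped)
    last_gen = [i for i in ped.ids if i.startswith(f"G{cfg.pedigree.n_generations}_")]
    if len(last_gen) < cfg.n_measured:
        raise ValueError(
            f"last generation has {len(last_gen)} horses < n_measured={cfg.n_measured}"
        )
    measured = last_gen[: cfg.n_measured]
    genotyped = measured[: cfg.n_genotyped]

    vc, meta = default_trait_system()
    traits = list(vc.traits)

    geno_all, freqs, miss = simulate_genotypes(ped, cfg.genotypes, rng_geno)
    qtl_meta = {}
    G = vc.G.copy()
    extra_arr = np.zeros((len(ped), len(traits)))
    if cfg.genotypes.qtl is not None:
        qtl = cfg.genotypes.qtl
        if qtl.trait not in traits:
            raise ValueError(f"QTL trait {qtl.trait!r} not in trait system")
        k = traits.index(qtl.trait)
        # the polygenic share shrinks so that QTL + polygene keep the trait's h2
        shrink = max(G[k, k] - qtl.variance_explained, 1e-6) / G[k, k]
        G[k, :] *= np.sqrt(shrink)
        G[:, k] *= np.sqrt(shrink)
        j, dev = _qtl_overlay(geno_all, freqs, qtl, 1.0, rng_geno)
        qtl_meta = {"snp": geno_all.snps.loc[j, "snp"], "index": j, "freq": float(freqs[j])}
        extra_arr[:, k] = dev

    a = mendelian_breeding_values(ped, G, rng_traits) + extra_arr
    bv = pd.DataFrame(a, index=ped.ids, columns=traits)

    # permanent-environment effects for measured horses
    pe = pd.DataFrame(
        _draw_pe(vc, len(measured), rng_traits), index=measured, columns=traits
    )

    records, height = _gait_records(cfg, ped, sex, measured, bv, pe, vc, meta, rng_rec)
    competitions = _competition(cfg, measured, bv, pe, vc, rng_comp)
    scores, ebv = _judge_scores(cfg, ped, measured, bv, vc, meta, rng_judge)

    return StudyData(
        config=cfg,
        pedigree=ped,
        sex=sex,
        measured=measured,
        genotyped=genotyped,
        trait_system=vc,
        breeding_values=bv,
        permanent_effects=pe,
        gait_records=records,
        height=height,
        genotypes=_apply_missing(geno_all, miss).subset_individuals(genotyped),
        competitions=competitions,
        scores=scores,
        ebv=ebv,
        meta={**meta, "qtl": qtl_meta},
    )


def _apply_missing(geno: GenotypeMatrix, miss: np.ndarray) -> GenotypeMatrix:
    dos = geno.dosages.copy()
    dos[miss] = np.nan
    return GenotypeMatrix(geno.snps, dos, geno.ids)


def _gait_records(cfg, ped, sex, measured, bv, pe, vc, meta, rng):
    measurements = ["SF", "R", "S", "DVD", "DVA", "LGA", "LTA"]
    n_meas_traits = sum(len(v) for v in meta["gaits"].values())
    # study-level fixed-effect catalogues
    gender_eff = {
        lv: rng.normal(0, cfg.fixed_effect_sd, size=n_meas_traits)
        for lv in ("female", "male", "gelding")
    }
    gender_eff["male"] *= 0.0  # stallions are the reference
    age_eff = {4: np.zeros(n_meas_traits), 5: rng.normal(0, cfg.fixed_effect_sd, size=n_meas_traits)}
    event_eff = rng.uniform(
        -cfg.event_effect_range, cfg.event_effect_range, size=(cfg.n_events, n_meas_traits)
    )
    meas_traits = [t for traits in meta["gaits"].values() for t in traits]
    tcol = {t: i for i, t in enumerate(meas_traits)}

    rows = []
    height_rows = []
    tsys = list(vc.traits)
    hk = tsys.index("height")
    h_meta = meta["height"]
    for h in measured:
        gender = (
            "female"
            if sex.loc[h] == "F"
            else ("gelding" if rng.random() < 0.7 else "male")
        )
        age = 4 if rng.random() < 0.42 else 5
        event = int(rng.integers(cfg.n_events))
        for code, gtraits in meta["gaits"].items():
            types = ["working", "medium"] if code in ("T", "C") else ["walk"]
            # residual draws correlated within gait, independent across records
            gidx = [tsys.index(t) for t in gtraits]
            Rg = vc.R[np.ix_(gidx, gidx)]
            for typ in types:
                vmean, vsd = meta["velocity"][code][typ]
                vel = rng.normal(vmean, vsd)
                e = rng.multivariate_normal(np.zeros(len(gidx)), Rg, method="cholesky")
                vals = {}
                for jj, trait in enumerate(gtraits):
                    z = (
                        gender_eff[gender][tcol[trait]]
                        + age_eff[age][tcol[trait]]
                        + event_eff[event, tcol[trait]]
                        + meta["beta_v"][trait] * (vel - vmean) / vsd
                        + bv.loc[h, trait]
                        + pe.loc[h, trait]
                        + e[jj]
                    )
                    mean = meta["means"][trait][typ]
                    vals[trait.split("_", 1)[1]] = mean + meta["sds"][trait] * z
                row = {
                    "horse": h,
                    "gait": code,
                    "type": typ if code in ("T", "C") else "",
                    "velocity": vel,
                    "event": f"E{event}",
                    "gender": gender,
                    "age": age,
                }
                for mname in measurements:
                    row[mname] = vals.get(mname, np.nan)
                rows.append(row)
        z_h = bv.loc[h, "height"] + rng.normal(0, np.sqrt(vc.R[hk, hk]))
        height_rows.append((h, h_meta["mean"] + h_meta["sd"] * z_h))
    records = pd.DataFrame(rows)
    if (records["velocity"] <= 0).any():
        records.loc[records["velocity"] <= 0, "velocity"] = 0.1
    height = pd.DataFrame(height_rows, columns=["horse", "height"])
    return records, height


def _competition(cfg, measured, bv, pe, vc, rng):
    ccfg = cfg.competition
    if ccfg.n_starters < 1:
        raise ValueError("events need at least one starter")
    k = list(vc.traits).index("competition")
    annual_sd = float(np.sqrt(vc.R[k, k]))
    rows = []
    for year in ccfg.years:
        annual = {
            h: bv.loc[h, "competition"]
            + pe.loc[h, "competition"]
            + rng.normal(0, annual_sd)
            for h in measured
        }
        order = list(measured)
        for start in range(ccfg.starts_per_horse_year):
            rng.shuffle(order)
            for enum, chunk_start in enumerate(range(0, len(order), ccfg.n_starters)):
                chunk = order[chunk_start : chunk_start + ccfg.n_starters]
                if len(chunk) < 2:
                    continue
                event = f"Y{year}S{start}E{enum}"
                level = int(rng.integers(ccfg.n_levels))
                noisy = {
                    h: annual[h] + rng.normal(0, ccfg.event_noise_sd) for h in chunk
                }
                ranked = sorted(chunk, key=lambda h: -noisy[h])
                for r, h in enumerate(ranked, start=1):
                    rows.append((h, year, event, level, r, len(chunk)))
    return pd.DataFrame(
        rows, columns=["horse", "year", "event", "level", "rank", "n_starters"]
    )


def _judge_scores(cfg, ped, measured, bv, vc, meta, rng):
    jcfg = cfg.judge
    traits = list(vc.traits)
    sigma_a_comp = float(np.sqrt(vc.G[traits.index("competition"), traits.index("competition")]))
    ebv = _parent_average_ebv(
        ped,
        measured,
        bv["competition"],
        sigma_a_comp,
        jcfg.sire_reliability,
        jcfg.dam_reliability,
        rng,
    )
    pa_std = ebv["pa_ebv"].to_numpy() / sigma_a_comp
    intr = bv.loc[measured, "judge_intrinsic"].to_numpy()
    ji = traits.index("judge_intrinsic")
    resid_sd = float(np.sqrt(vc.R[ji, ji]))
    z = intr + jcfg.k_pa * pa_std + resid_sd * rng.standard_normal(len(measured))
    jm = meta["judge"]
    scores = pd.DataFrame(
        {"horse": measured, "score": jm["mean"] + jm["sd"] * z}
    )
    return scores, ebv
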