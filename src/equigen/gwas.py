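"""SNP quality control and the GRAMMAR two-step association scan.

GRAMMAR fits the polygenic animal model once (without SNPs) and then tests
every SNP by ordinary regression of the model's residuals — or, for traits
with repeated records, of the permanent-environment estimates p-hat — on
the additive dosage.  This trades a small loss of power for a scan that is
a vectorized least-squares pass over the whole panel, while the polygenic
pre-fit absorbs family structure.

QC follows the usual panel thresholds: minor-allele frequency, exact-test
Hardy-Weinberg p-value and per-SNP call rate; dosages count the minor
allele and missing calls are mean-imputed before regression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

from .simulate import GenotypeMatrix

__all__ = [
    "hwe_exact_test",
    "qc_filter",
    "grammar_scan",
    "manhattan_table",
]


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, by probability mass).

    The p-value sums the probabilities of all heterozygote counts that are
    no more probable than the observed one, conditional on the allele
    counts.  Computed in log space, so it is stable for large samples.
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_hom_ref + n_het  # copies of the 'ref' allele
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hom_rare - hets
    logw = (
        hets * np.log(2.0)
        - special.gammaln(hom_rare + 1)
        - special.gammaln(hets + 1)
        - special.gammaln(hom_common + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    w_obs = w[hets == n_het][0]
    p = float(w[w <= w_obs * (1 + 1e-12)].sum() / w.sum())
    return min(p, 1.0)


def _counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP genotype counts and call counts from a dosage matrix."""
    valid = ~np.isnan(dosages)
    n_called = valid.sum(axis=1)
    d = np.where(valid, dosages, -1)
    n0 = (d == 0).sum(axis=1)
    n1 = (d == 1).sum(axis=1)
    n2 = (d == 2).sum(axis=1)
    return n0, n1, n2, n_called


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.02,
    hwe_min: float = 1e-6,
    callrate_min: float = 0.90,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep SNPs with MAF > maf_min, HWE p > hwe_min, call rate > callrate_min.

    Returns the filtered matrix and a per-SNP report with the metrics and,
    for removed SNPs, the failed checks (semicolon-joined).  MAF is
    computed on non-missing calls.
    """
    n_ind = len(geno.ids)
    n0, n1, n2, called = _counts(geno.dosages)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (n1 + 2 * n2) / (2 * np.maximum(called, 1))
    maf = np.minimum(freq, 1 - freq)
    call_rate = called / n_ind
    hwe = np.array([hwe_exact_test(a, b, c) if t else 1.0 for a, b, c, t in zip(n0, n1, n2, called)])
    reasons = []
    for m, h, c in zip(maf, hwe, call_rate):
        r = []
        if not m > maf_min:
            r.append("maf")
        if not h > hwe_min:
            r.append("hwe")
        if not c > callrate_min:
            r.append("callrate")
        reasons.append(";".join(r))
    keep = np.array([r == "" for r in reasons])
    report = geno.snps.copy()
    report["maf"] = maf
    report["call_rate"] = call_rate
    report["hwe_p"] = hwe
    report["pass"] = keep
    report["reason"] = reasons
    if not keep.any():
        warnings.warn("all SNPs removed by QC", RuntimeWarning)
    filtered = GenotypeMatrix(
        geno.snps[keep].reset_index(drop=True), geno.dosages[keep], list(geno.ids)
    )
    return filtered, report


def grammar_scan(response: pd.Series, geno: GenotypeMatrix) -> pd.DataFrame:
    """Second GRAMMAR step: per-SNP regression of p-hat (or residuals).

    ``response`` is indexed by horse id; only genotyped horses present in
    it are used.  Dosages are recoded to count the minor allele and
    missing calls are mean-imputed.  Returns one row per SNP with the
    effect, its standard error, the two-sided t-test p-value and a
    Bonferroni-adjusted column, sorted by genome position.
    """
    ids = [i for i in geno.ids if i in response.index]
    if len(ids) < 3:
        raise ValueError("fewer than 3 genotyped horses with a response value")
    sub = geno.subset_individuals(ids)
    y = response.loc[ids].to_numpy(dtype=float)
    g = sub.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g, axis=1) / 2.0
    flip = freq > 0.5
    g[flip] = 2.0 - g[flip]
    means = np.nanmean(g, axis=1)
    nan_mask = np.isnan(g)
    g[nan_mask] = np.broadcast_to(means[:, None], g.shape)[nan_mask]
    n = len(ids)
    gc = g - g.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sgg = (gc**2).sum(axis=1)
    sgy = gc @ yc
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sgy / sgg
        rss = syy - beta * sgy
        se = np.sqrt(np.maximum(rss, 0) / (n - 2) / sgg)
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    degenerate = sgg <= 1e-12
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    p[degenerate] = 1.0
    out = sub.snps.copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n_used"] = int(n)
    out["bonferroni"] = np.minimum(p * len(out), 1.0)
    out["flag"] = np.where(degenerate, "monomorphic", "")
    out["chrom"] = out["chrom"].astype(str)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def manhattan_table(scan: pd.DataFrame) -> pd.DataFrame:
    """Plain (chrom, pos, -log10 p) table for plotting."""
    out = scan[["chrom", "pos"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(scan["p"].to_numpy())
    return out
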