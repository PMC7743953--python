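"""Pre-adjustment of gait measurements and PCA of horse effects.

Trot and canter measurements are repeated (working + medium record), so the
per-horse summary is the BLUP of an iid random horse effect from the
repeatability model ``y = Xb + Zu + e`` with velocity-within-type
covariates; walk has a single record per horse and the summary is the
fixed-effect-adjusted phenotype ``y - X b_hat``.  A correlation-matrix PCA
of the horse x measurement table then yields three synthetic traits per
gait, named by rank, gait letter and the measurement with the largest
loading (e.g. ``PCT1_DVD``).

The random-effect model here has a single iid effect, so REML is computed
on a small Schur complement (the horse block of the equations is diagonal)
rather than through the general pedigree machinery — the cost per
iteration is O(fixed-effects^2 x horses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PcModel",
    "adjust_phenotypes",
    "fit_pca",
    "pc_scores",
    "fit_iid_repeatability",
]


def _design(df: pd.DataFrame, factors: Sequence[str], covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    n = len(df)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    for f in factors:
        levels = sorted(df[f].astype(str).unique())
        codes = df[f].astype(str).to_numpy()
        for lv in levels[1:]:
            cols.append((codes == lv).astype(float))
            names.append(f"{f}[{lv}]")
    for c in covariates:
        cols.append(df[c].astype(float).to_numpy())
        names.append(c)
    return np.column_stack(cols), names


def fit_iid_repeatability(
    y: np.ndarray,
    X: np.ndarray,
    group: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> dict:
    """EM-REML for y = Xb + u_group + e with iid u; returns b, u and variances.

    The group block of Henderson's equations is diagonal, so each EM
    iteration works on the fixed-effect Schur complement only.
    """
    n, f = X.shape
    groups, gidx = np.unique(group, return_inverse=True)
    m = len(groups)
    counts = np.bincount(gidx, minlength=m).astype(float)
    Zty_base = np.bincount(gidx, weights=y, minlength=m)
    XtX = X.T @ X
    Xty = X.T @ y
    # X'Z columns summed per group
    XtZ = np.zeros((f, m))
    for j in range(f):
        XtZ[j] = np.bincount(gidx, weights=X[:, j], minlength=m)
    var_y = max(np.var(y, ddof=1), 1e-12)
    su, se = var_y / 3, 2 * var_y / 3
    b = np.zeros(f)
    u = np.zeros(m)
    for _ in range(max_iter):
        lam_d = counts / se + 1.0 / su
        S = XtX / se - (XtZ / se) @ ((XtZ / se).T / lam_d[:, None])
        rhs = Xty / se - (XtZ / se) @ (Zty_base / se / lam_d)
        b = np.linalg.solve(S, rhs)
        u = (Zty_base / se - (XtZ.T / se) @ b) / lam_d
        e = y - X @ b - u[gidx]
        Sinv = np.linalg.inv(S)
        T = (XtZ / se) / lam_d[None, :]
        tr_cuu = float(np.sum(1.0 / lam_d)) + float(np.sum((Sinv @ T) * T))
        su_new = (float(u @ u) + tr_cuu) / m
        tr_wcw = se * (f + m) - se / su * tr_cuu
        se_new = (float(e @ e) + tr_wcw) / n
        if abs(su_new - su) + abs(se_new - se) < tol * var_y:
            su, se = su_new, se_new
            break
        su, se = max(su_new, 1e-12 * var_y), max(se_new, 1e-12 * var_y)
    return {"b": b, "u": u, "groups": groups, "sigma_u2": su, "sigma_e2": se}


def adjust_phenotypes(
    records: pd.DataFrame,
    gait: str,
    measurements: Sequence[str] | None = None,
    factors: Sequence[str] = ("gender", "age", "event"),
) -> pd.DataFrame:
    """Per-horse adjusted values for one gait's measurements.

    Trot/canter (repeated records): BLUP u-hat of the horse effect from the
    repeatability model with type factor and velocity-within-type
    covariates.  Walk (single record): residual ``y - X b_hat`` from the
    fixed-effect fit with a plain velocity covariate; repeated walk rows
    are an error.
    """
    sub = records[records["gait"] == gait].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no records for gait {gait!r}")
    if measurements is None:
        measurements = [
            c
            for c in ("SF", "R", "S", "DVD", "DVA", "LGA", "LTA")
            if c in sub.columns and sub[c].notna().any()
        ]
    repeated = gait in ("T", "C")
    if not repeated and sub["horse"].duplicated().any():
        raise ValueError("walk records must be one row per horse")
    out = {}
    if repeated:
        sub = sub.copy()
        for typ in sorted(sub["type"].unique()):
            sub[f"vel_{typ}"] = np.where(
                sub["type"] == typ, sub["velocity"].astype(float), 0.0
            )
        covs = [f"vel_{typ}" for typ in sorted(sub["type"].unique())]
        X, _ = _design(sub, list(factors) + ["type"], covs)
        for mcol in measurements:
            mask = sub[mcol].notna().to_numpy()
            fit = fit_iid_repeatability(
                sub.loc[mask, mcol].to_numpy(dtype=float),
                X[mask],
                sub.loc[mask, "horse"].to_numpy(),
            )
            out[mcol] = pd.Series(fit["u"], index=fit["groups"])
    else:
        X, _ = _design(sub, list(factors), ["velocity"])
        for mcol in measurements:
            mask = sub[mcol].notna().to_numpy()
            yv = sub.loc[mask, mcol].to_numpy(dtype=float)
            bhat, *_ = np.linalg.lstsq(X[mask], yv, rcond=None)
            out[mcol] = pd.Series(yv - X[mask] @ bhat, index=sub.loc[mask, "horse"].to_numpy())
    return pd.DataFrame(out)


@dataclass
class PcModel:
    """Correlation-matrix PCA of adjusted horse effects for one gait."""

    gait: str
    measurements: list[str]
    eigenvectors: np.ndarray  # (n_measurements, n_components)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    explained: np.ndarray  # fractions over all components
    component_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.eigenvectors, index=self.measurements, columns=self.component_names
        )


def fit_pca(adjusted: pd.DataFrame, gait: str = "", n_components: int = 3) -> PcModel:
    """PCA of standardized adjusted values; deterministic sign and names.

    Components are ordered by decreasing eigenvalue; each eigenvector is
    flipped so its largest-magnitude loading is positive (ties broken by
    measurement order); names follow rank-gait-measurement, e.g. PCT1_DVD.
    """
    if adjusted.shape[1] < 2 or adjusted.shape[0] < 3:
        raise ValueError("need at least 2 measurements and 3 horses")
    cols = list(adjusted.columns)
    mat = adjusted.to_numpy(dtype=float)
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    for c, s in zip(cols, sds):
        if s <= 0 or not np.isfinite(s):
            raise ValueError(f"constant measurement column {c!r}")
    z = (mat - means) / sds
    corr = (z.T @ z) / (len(mat) - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_components = min(n_components, len(cols))
    names = []
    for r in range(len(cols)):
        lead = int(np.argmax(np.abs(np.round(v[:, r], 12))))
        if v[lead, r] < 0:
            v[:, r] = -v[:, r]
        if r < n_components:
            names.append(f"PC{gait}{r + 1}_{cols[lead]}")
    return PcModel(
        gait=gait,
        measurements=cols,
        eigenvectors=v[:, :n_components],
        eigenvalues=w,
        explained=np.clip(w, 0, None) / np.clip(w, 0, None).sum(),
        component_names=names,
        means=means,
        sds=sds,
    )


def pc_scores(model: PcModel, data: pd.DataFrame) -> pd.DataFrame:
    """Project rows onto the component axes using the training scaler.

    ``data`` may be the training table (scores then have mean zero and
    variance equal to the eigenvalues) or any table with the same
    measurement columns, e.g. record-level measurements for the GWAS.
    """
    missing = [m for m in model.measurements if m not in data.columns]
    if missing:
        raise ValueError(f"missing measurement columns: {missing}")
    z = (data[model.measurements].to_numpy(dtype=float) - model.means) / model.sds
    scores = z @ model.eigenvectors
    return pd.DataFrame(scores, index=data.index, columns=model.component_names)
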