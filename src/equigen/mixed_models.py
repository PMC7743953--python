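"""Animal-model mixed equations, BLUP and EM-REML variance components.

The model family is the multi-trait animal model

    y = Xb + Za + Zp + e

with additive genetic values ``a`` (covariance ``G (x) A`` across traits and
pedigree), optional permanent-environment effects ``p`` for traits with
repeated records (covariance ``P (x) I``), and residuals with trait
covariance ``R`` applied per record; records missing some traits use the
corresponding sub-block of ``R``.  ``R`` may carry a zero pattern (pairs of
traits constrained to zero residual covariance), which is how the
structured-equation treatment of height-as-covariate keeps the
environmental covariance between height and the gait traits at exactly
zero.

Variance components are estimated by EM-REML on Henderson's equations.
Each EM step needs the prediction-error (co)variances, i.e. blocks of the
inverse coefficient matrix, so problem sizes are kept in the dense range
(a few thousand equations).  Plain EM is slow near the optimum; an
over-relaxation step (accepted only when it does not decrease the
restricted likelihood, so the likelihood trace stays monotone) typically
cuts the iteration count several-fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, a_inverse as _ped_a_inverse, log_det_a as _ped_log_det_a

__all__ = [
    "TraitModelSpec",
    "VarianceComponents",
    "BlupSolution",
    "GeneticParameters",
    "MixedModelEquations",
    "build_mme",
    "solve_blup",
    "em_reml",
    "genetic_parameters",
    "start_values",
]

#: above this many equations, solve_blup switches to preconditioned CG
DIRECT_SOLVE_LIMIT = 6000


class MixedModelError(RuntimeError):
    pass


@dataclass
class TraitModelSpec:
    """Trait list plus per-trait fixed effects and random-term layout.

    ``fixed`` maps a trait to categorical factor columns, ``covariates`` to
    numeric regressor columns; an intercept is always included.
    ``pe_traits`` lists the traits that receive a permanent-environment
    effect (traits with repeated records).  ``r_zero_pairs`` are trait
    pairs whose residual covariance is constrained to zero.
    """

    traits: Sequence[str]
    fixed: Mapping[str, Sequence[str]] = field(default_factory=dict)
    covariates: Mapping[str, Sequence[str]] = field(default_factory=dict)
    pe_traits: Sequence[str] = ()
    r_zero_pairs: Sequence[tuple[str, str]] = ()
    animal: str = "animal"

    def __post_init__(self) -> None:
        self.traits = list(self.traits)
        self.pe_traits = [t for t in self.traits if t in set(self.pe_traits)]
        for t in self.pe_traits:
            if t not in self.traits:
                raise ValueError(f"pe trait {t!r} not in trait list")
        for a, b in self.r_zero_pairs:
            if a not in self.traits or b not in self.traits:
                raise ValueError(f"zero-pattern pair ({a!r},{b!r}) not in trait list")

    def r_zero_mask(self) -> np.ndarray:
        """Boolean t x t matrix, True where R is constrained to zero."""
        t = len(self.traits)
        idx = {name: k for k, name in enumerate(self.traits)}
        mask = np.zeros((t, t), dtype=bool)
        for a, b in self.r_zero_pairs:
            mask[idx[a], idx[b]] = mask[idx[b], idx[a]] = True
        return mask


def _check_psd(m: np.ndarray, name: str) -> None:
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh((m + m.T) / 2)
    scale = max(abs(w).max(), 1e-300)
    if w.min() < -1e-8 * scale:
        raise ValueError(f"{name} is not positive semi-definite (min eig {w.min():.3g})")


@dataclass
class VarianceComponents:
    """Genetic (G), permanent-environment (P) and residual (R) covariances.

    ``G`` and ``R`` are trait x trait; ``P`` is indexed by ``pe_traits``
    only.  All must be symmetric PSD.
    """

    traits: Sequence[str]
    G: np.ndarray
    P: np.ndarray
    R: np.ndarray
    pe_traits: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.traits = list(self.traits)
        self.pe_traits = list(self.pe_traits)
        t, tp = len(self.traits), len(self.pe_traits)
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float)) if tp else np.zeros((0, 0))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if self.G.shape != (t, t) or self.R.shape != (t, t):
            raise ValueError("G and R must be trait x trait")
        if self.P.shape != (tp, tp):
            raise ValueError("P must be pe_trait x pe_trait")
        _check_psd(self.G, "G")
        _check_psd(self.R, "R")
        if tp:
            _check_psd(self.P, "P")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            self.traits, self.G.copy(), self.P.copy(), self.R.copy(), self.pe_traits
        )

    def p_padded(self) -> np.ndarray:
        """P expanded to trait x trait with zeros for traits without pe."""
        t = len(self.traits)
        out = np.zeros((t, t))
        idx = [self.traits.index(x) for x in self.pe_traits]
        for i, ii in enumerate(idx):
            for j, jj in enumerate(idx):
                out[ii, jj] = self.P[i, j]
        return out


@dataclass
class BlupSolution:
    """Solutions of the mixed-model equations."""

    fixed: Mapping[str, pd.Series]
    a: pd.DataFrame
    p: pd.DataFrame
    residuals: pd.DataFrame
    theta: np.ndarray


@dataclass
class GeneticParameters:
    heritability: pd.Series
    repeatability: pd.Series
    genetic_correlation: pd.DataFrame
    phenotypic_correlation: pd.DataFrame


def _psd_clip(m: np.ndarray, floor_frac: float = 1e-10) -> tuple[np.ndarray, bool]:
    m = (m + m.T) / 2
    w, v = np.linalg.eigh(m)
    floor = floor_frac * max(w.max(), 1e-300)
    if w.min() >= floor:
        return m, False
    w = np.maximum(w, floor)
    return (v * w) @ v.T, True


def _design_matrix(
    df: pd.DataFrame, rows: np.ndarray, factors: Sequence[str], covariates: Sequence[str]
) -> tuple[sp.csr_matrix, list[str]]:
    """Intercept + drop-first dummies + covariates for the given rows."""
    n = len(rows)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["(intercept)"]
    sub = df.iloc[rows]
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor column {f!r} not in data")
        levels = sorted(sub[f].astype(str).unique())
        codes = sub[f].astype(str).to_numpy()
        for lv in levels[1:]:
            cols.append((codes == lv).astype(float))
            names.append(f"{f}[{lv}]")
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate column {c!r} not in data")
        vals = sub[c].astype(float).to_numpy()
        if np.isnan(vals).any():
            raise ValueError(f"covariate {c!r} has missing values on observed records")
        cols.append(vals)
        names.append(c)
    return sp.csr_matrix(np.column_stack(cols)), names


class MixedModelEquations:
    """Assembled Henderson equations for a :class:`TraitModelSpec`.

    Data-side cross-products are cached per missing-trait pattern, so
    re-weighting by new variance components (every REML iteration) costs
    O(pattern count), not O(records).
    """

    def __init__(
        self,
        spec: TraitModelSpec,
        data: pd.DataFrame,
        relationship: Pedigree | tuple[sp.spmatrix, Sequence[str], float] | None = None,
        vc: VarianceComponents | None = None,
    ):
        self.spec = spec
        self.data = data.reset_index(drop=True)
        self.vc = vc
        t = len(spec.traits)
        if spec.animal not in self.data.columns:
            raise ValueError(f"data has no animal column {spec.animal!r}")
        animals_in_data = self.data[spec.animal].astype(str)

        # --- animal universe and A-inverse ---------------------------------
        if relationship is None:
            self.animal_ids = sorted(animals_in_data.unique())
            q = len(self.animal_ids)
            self.ainv = sp.identity(q, format="csr")
            self.log_det_a = 0.0
        elif isinstance(relationship, Pedigree):
            self.animal_ids = list(relationship.ids)
            self.ainv = _ped_a_inverse(relationship)
            self.log_det_a = _ped_log_det_a(relationship)
        else:
            ainv, ids, ld = relationship
            self.animal_ids = list(ids)
            self.ainv = sp.csr_matrix(ainv)
            self.log_det_a = float(ld)
        self.q = len(self.animal_ids)
        aidx = {a: k for k, a in enumerate(self.animal_ids)}
        unknown = set(animals_in_data.unique()) - set(self.animal_ids)
        if unknown:
            raise ValueError(f"animals not in pedigree: {sorted(unknown)[:5]} ...")
        self._row_animal = animals_in_data.map(aidx).to_numpy()

        # --- permanent-environment universe: animals with any record -------
        self.pe_animal_ids = sorted(animals_in_data.unique())
        peidx = {a: k for k, a in enumerate(self.pe_animal_ids)}
        self.n_pe = len(self.pe_animal_ids)
        self._row_pe = animals_in_data.map(peidx).to_numpy()

        # --- parameter layout ----------------------------------------------
        self.trait_rows: list[np.ndarray] = []
        self.y: list[np.ndarray] = []
        designs: list[sp.csr_matrix] = []
        self.fixed_names: list[list[str]] = []
        for k, trait in enumerate(spec.traits):
            if trait not in self.data.columns:
                raise ValueError(f"trait column {trait!r} not in data")
            rows = np.flatnonzero(self.data[trait].notna().to_numpy())
            if len(rows) == 0:
                raise ValueError(f"trait {trait!r} has no observed records")
            self.trait_rows.append(rows)
            self.y.append(self.data[trait].to_numpy(dtype=float)[rows])
            X, names = _design_matrix(
                self.data, rows, spec.fixed.get(trait, ()), spec.covariates.get(trait, ())
            )
            designs.append(X)
            self.fixed_names.append(names)
        self.f_sizes = [X.shape[1] for X in designs]
        self.fixed_off = np.concatenate(([0], np.cumsum(self.f_sizes)))[:-1]
        self.nf = int(sum(self.f_sizes))
        self.a_off = self.nf
        self.p_off = self.nf + t * self.q
        self.pe_trait_idx = [spec.traits.index(x) for x in spec.pe_traits]
        self.M = self.p_off + len(spec.pe_traits) * self.n_pe

        # --- per-trait full-row W matrices ---------------------------------
        n_df = len(self.data)
        self.W: list[sp.csr_matrix] = []
        pe_pos = {k: i for i, k in enumerate(self.pe_trait_idx)}
        for k in range(t):
            rows = self.trait_rows[k]
            X = designs[k].tocoo()
            r = list(rows[X.row])
            c = list(X.col + self.fixed_off[k])
            v = list(X.data)
            r += list(rows)
            c += list(self.a_off + k * self.q + self._row_animal[rows])
            v += [1.0] * len(rows)
            if k in pe_pos:
                r += list(rows)
                c += list(self.p_off + pe_pos[k] * self.n_pe + self._row_pe[rows])
                v += [1.0] * len(rows)
            self.W.append(
                sp.coo_matrix((v, (r, c)), shape=(n_df, self.M)).tocsr()
            )

        # --- missing-trait patterns and cached cross-products --------------
        observed = np.column_stack(
            [self.data[tr].notna().to_numpy() for tr in spec.traits]
        )
        pattern_key = [tuple(np.flatnonzero(row)) for row in observed]
        self.patterns: dict[tuple[int, ...], np.ndarray] = {}
        for i, key in enumerate(pattern_key):
            if not key:
                continue
            self.patterns.setdefault(key, []).append(i)
        self.patterns = {k: np.asarray(v) for k, v in self.patterns.items()}

        yfull = {
            k: self.data[spec.traits[k]].to_numpy(dtype=float) for k in range(t)
        }
        self._M_kl: dict = {}
        self._V_kl: dict = {}
        self._s_kl: dict = {}
        for pat, rows in self.patterns.items():
            for a in pat:
                Wa = self.W[a][rows]
                for b in pat:
                    if b < a:
                        continue
                    Wb = self.W[b][rows]
                    self._M_kl[(pat, a, b)] = (Wa.T @ Wb).tocsr()
                    self._s_kl[(pat, a, b)] = float(yfull[a][rows] @ yfull[b][rows])
                for b in pat:
                    self._V_kl[(pat, a, b)] = np.asarray(
                        (self.W[a][rows].T @ yfull[b][rows])
                    ).ravel()
        self._ainv_dense: np.ndarray | None = None

    # ------------------------------------------------------------------ #

    def _ainv_as_dense(self) -> np.ndarray:
        if self._ainv_dense is None:
            self._ainv_dense = self.ainv.toarray()
        return self._ainv_dense

    def _rinv_blocks(self, vc: VarianceComponents) -> dict:
        out = {}
        R = vc.R
        for pat in self.patterns:
            sub = R[np.ix_(pat, pat)]
            try:
                inv = np.linalg.inv(sub)
            except np.linalg.LinAlgError:
                inv = np.full_like(sub, np.nan)
            if not np.all(np.isfinite(inv)):
                names = [self.spec.traits[k] for k in pat]
                raise MixedModelError(
                    f"singular residual sub-block for record pattern {names}"
                )
            out[pat] = (inv, float(np.linalg.slogdet(sub)[1]))
        return out

    def _assemble(self, vc: VarianceComponents) -> tuple[np.ndarray, np.ndarray, float, float, dict]:
        """Dense C, rhs, y'R^-1 y and sum of log|R_pattern| for given vc."""
        rinv = self._rinv_blocks(vc)
        C = sp.csr_matrix((self.M, self.M))
        rhs = np.zeros(self.M)
        yry = 0.0
        logdet_r = 0.0
        for pat, rows in self.patterns.items():
            Ri, ld = rinv[pat]
            logdet_r += len(rows) * ld
            for ia, a in enumerate(pat):
                for ib, b in enumerate(pat):
                    w = Ri[ia, ib]
                    if w == 0.0:
                        continue
                    if b >= a:
                        C = C + w * self._M_kl[(pat, a, b)]
                        if b > a:
                            C = C + w * self._M_kl[(pat, a, b)].T
                    rhs += w * self._V_kl[(pat, a, b)]
                    key = (pat, a, b) if b >= a else (pat, b, a)
                    yry += w * self._s_kl[key]
        Cd = C.toarray()
        t = len(self.spec.traits)
        # penalty blocks
        Ginv = np.linalg.inv(vc.G)
        aslice = slice(self.a_off, self.a_off + t * self.q)
        Cd[aslice, aslice] += np.kron(Ginv, self._ainv_as_dense())
        if self.spec.pe_traits:
            Pinv = np.linalg.inv(vc.P)
            pslice = slice(self.p_off, self.M)
            Cd[pslice, pslice] += np.kron(Pinv, np.eye(self.n_pe))
        return Cd, rhs, yry, logdet_r, rinv

    def factorize(self, vc: VarianceComponents) -> dict:
        """Cholesky state: factor, solutions and restricted log-likelihood."""
        Cd, rhs, yry, logdet_r, rinv = self._assemble(vc)
        try:
            cho = sla.cho_factor(Cd, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            raise MixedModelError(
                "coefficient matrix not positive definite; "
                "check for collinear fixed effects or zero variances"
            ) from None
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        theta = sla.cho_solve(cho, rhs, check_finite=False)
        t = len(self.spec.traits)
        ll = -0.5 * (
            logdet_r
            + self.q * float(np.linalg.slogdet(vc.G)[1])
            + t * self.log_det_a
            + (self.n_pe * float(np.linalg.slogdet(vc.P)[1]) if self.spec.pe_traits else 0.0)
            + logdet_c
            + yry
            - float(rhs @ theta)
        )
        if not np.isfinite(ll) or not np.all(np.isfinite(theta)):
            raise MixedModelError("non-finite solution; variance components degenerate")
        return {"cho": cho, "theta": theta, "ll": ll, "rinv": rinv, "vc": vc}

    def loglik(self, vc: VarianceComponents) -> float:
        """Restricted log-likelihood (up to an additive constant)."""
        return self.factorize(vc)["ll"]

    # ------------------------------------------------------------------ #

    def solution(self, state: dict) -> BlupSolution:
        theta = state["theta"]
        spec = self.spec
        t = len(spec.traits)
        fixed = {}
        for k, trait in enumerate(spec.traits):
            off = self.fixed_off[k]
            fixed[trait] = pd.Series(
                theta[off : off + self.f_sizes[k]], index=self.fixed_names[k]
            )
        a_hat = theta[self.a_off : self.a_off + t * self.q].reshape(t, self.q)
        a = pd.DataFrame(a_hat.T, index=self.animal_ids, columns=spec.traits)
        if spec.pe_traits:
            p_hat = theta[self.p_off :].reshape(len(spec.pe_traits), self.n_pe)
            p = pd.DataFrame(p_hat.T, index=self.pe_animal_ids, columns=spec.pe_traits)
        else:
            p = pd.DataFrame(index=self.pe_animal_ids)
        resid = pd.DataFrame(
            np.nan, index=range(len(self.data)), columns=spec.traits
        )
        for k, trait in enumerate(spec.traits):
            rows = self.trait_rows[k]
            fitted = np.asarray(self.W[k][rows] @ theta).ravel()
            resid.loc[rows, trait] = self.y[k] - fitted
        resid[spec.animal] = self.data[spec.animal].astype(str).to_numpy()
        return BlupSolution(fixed=fixed, a=a, p=p, residuals=resid, theta=theta)

    def solve(self, vc: VarianceComponents | None = None) -> BlupSolution:
        vc = vc or self.vc
        if vc is None:
            raise ValueError("no variance components supplied")
        if self.M <= DIRECT_SOLVE_LIMIT:
            return self.solution(self.factorize(vc))
        # iterative path for large systems
        Cd, rhs, _, _, _ = self._assemble(vc)
        Cs = sp.csr_matrix(Cd)
        diag = Cs.diagonal()
        precond = spla.LinearOperator(Cs.shape, matvec=lambda x: x / diag)
        theta, info = spla.cg(Cs, rhs, rtol=1e-10, maxiter=5000, M=precond)
        if info != 0:
            raise MixedModelError(f"conjugate gradient failed to converge (info={info})")
        return self.solution({"theta": theta})

    # ------------------------------------------------------------------ #

    def em_step(self, state: dict) -> VarianceComponents:
        """One EM-REML update of (G, P, R) from a factorized state."""
        spec = self.spec
        t = len(spec.traits)
        theta = state["theta"]
        cho = state["cho"]
        cinv = sla.cho_solve(cho, np.eye(self.M), check_finite=False)
        ainv = self.ainv

        a_hat = theta[self.a_off : self.a_off + t * self.q].reshape(t, self.q)
        S_a = np.zeros((t, t))
        for k in range(t):
            for l in range(k, t):
                blk = cinv[
                    self.a_off + k * self.q : self.a_off + (k + 1) * self.q,
                    self.a_off + l * self.q : self.a_off + (l + 1) * self.q,
                ]
                tr = float(ainv.multiply(blk.T).sum())
                S_a[k, l] = S_a[l, k] = float(a_hat[k] @ (ainv @ a_hat[l])) + tr
        G_new = S_a / self.q

        if spec.pe_traits:
            tp = len(spec.pe_traits)
            p_hat = theta[self.p_off :].reshape(tp, self.n_pe)
            S_p = np.zeros((tp, tp))
            for k in range(tp):
                for l in range(k, tp):
                    blk = cinv[
                        self.p_off + k * self.n_pe : self.p_off + (k + 1) * self.n_pe,
                        self.p_off + l * self.n_pe : self.p_off + (l + 1) * self.n_pe,
                    ]
                    S_p[k, l] = S_p[l, k] = float(p_hat[k] @ p_hat[l]) + float(
                        np.trace(blk)
                    )
            P_new = S_p / self.n_pe
        else:
            P_new = np.zeros((0, 0))

        num = np.zeros((t, t))
        cnt = np.zeros((t, t))
        yfull = {k: self.data[spec.traits[k]].to_numpy(dtype=float) for k in range(t)}
        for pat, rows in self.patterns.items():
            e = {}
            B = {}
            for k in pat:
                Wk = self.W[k][rows]
                e[k] = yfull[k][rows] - np.asarray(Wk @ theta).ravel()
                B[k] = Wk @ cinv
            for k in pat:
                for l in pat:
                    if l < k:
                        continue
                    u = np.asarray(self.W[l][rows].multiply(B[k]).sum(axis=1)).ravel()
                    num[k, l] += float(e[k] @ e[l]) + float(u.sum())
                    cnt[k, l] += len(rows)
        R_new = np.zeros((t, t))
        obs = cnt > 0
        R_new[obs] = num[obs] / cnt[obs]
        R_new = np.triu(R_new) + np.triu(R_new, 1).T
        mask = spec.r_zero_mask()
        R_new[mask] = 0.0
        return VarianceComponents(
            spec.traits, G_new, P_new, R_new, spec.pe_traits
        )


def build_mme(
    spec: TraitModelSpec,
    data: pd.DataFrame,
    relationship: Pedigree | tuple[sp.spmatrix, Sequence[str], float] | None = None,
    vc: VarianceComponents | None = None,
) -> MixedModelEquations:
    """Assemble Henderson's mixed-model equations.

    ``relationship`` is a :class:`~equigen.pedigree.Pedigree` (A-inverse is
    built internally), a pre-built ``(a_inverse, ids, log_det_a)`` triple,
    or ``None`` for an iid animal effect (A = I over animals in the data).
    """
    return MixedModelEquations(spec, data, relationship, vc)


def solve_blup(
    system: MixedModelEquations, vc: VarianceComponents | None = None
) -> BlupSolution:
    """Solve the assembled equations for fixed effects, a-hat and p-hat."""
    return system.solve(vc)


def start_values(spec: TraitModelSpec, data: pd.DataFrame) -> VarianceComponents:
    """Default EM start: one third of each trait's sample variance to G, P, R."""
    t = len(spec.traits)
    v = np.zeros(t)
    for k, trait in enumerate(spec.traits):
        vals = data[trait].dropna().to_numpy(dtype=float)
        v[k] = max(np.var(vals, ddof=1), 1e-8)
    G = np.diag(v / 3)
    R = np.diag(v / 3)
    pe_idx = [spec.traits.index(x) for x in spec.pe_traits]
    P = np.diag(v[pe_idx] / 3) if pe_idx else np.zeros((0, 0))
    # traits without pe: their share goes to the residual
    no_pe = [k for k in range(t) if k not in pe_idx]
    for k in no_pe:
        R[k, k] += v[k] / 3
    return VarianceComponents(spec.traits, G, P, R, spec.pe_traits)


def _flatten(vc: VarianceComponents) -> np.ndarray:
    parts = [vc.G[np.triu_indices(vc.G.shape[0])]]
    if vc.P.size:
        parts.append(vc.P[np.triu_indices(vc.P.shape[0])])
    parts.append(vc.R[np.triu_indices(vc.R.shape[0])])
    return np.concatenate(parts)


def _unflatten(vec: np.ndarray, template: VarianceComponents) -> VarianceComponents:
    def _mat(buf: np.ndarray, dim: int) -> np.ndarray:
        m = np.zeros((dim, dim))
        iu = np.triu_indices(dim)
        m[iu] = buf
        return m + np.triu(m, 1).T

    t = len(template.traits)
    tp = len(template.pe_traits)
    n_g = t * (t + 1) // 2
    n_p = tp * (tp + 1) // 2
    G = _psd_clip(_mat(vec[:n_g], t))[0]
    P = _psd_clip(_mat(vec[n_g : n_g + n_p], tp))[0] if tp else np.zeros((0, 0))
    R = _psd_clip(_mat(vec[n_g + n_p :], t))[0]
    return VarianceComponents(template.traits, G, P, R, template.pe_traits)


def em_reml(
    spec: TraitModelSpec,
    data: pd.DataFrame,
    relationship: Pedigree | tuple[sp.spmatrix, Sequence[str], float] | None = None,
    start: VarianceComponents | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    accelerate: bool = True,
) -> tuple[VarianceComponents, list[float], dict]:
    """EM-REML estimation of G, P and R.

    Returns the estimates, the (monotone non-decreasing) restricted
    log-likelihood trace, and an info dict with convergence diagnostics.
    Over-relaxed steps are attempted when ``accelerate`` and kept only if
    they do not lower the likelihood relative to the plain EM step.
    """
    system = build_mme(spec, data, relationship)
    vc = (start or start_values(spec, data)).copy()
    mask = spec.r_zero_mask()
    vc.R[mask] = 0.0
    scale = np.abs(_flatten(vc)).max()
    trace: list[float] = []
    boundary = False
    state = system.factorize(vc)
    converged = False
    n_em = 0

    def _clip_vc(cand: VarianceComponents) -> VarianceComponents:
        nonlocal boundary
        for attr in ("G", "P", "R"):
            m = getattr(cand, attr)
            if m.size:
                clipped, hit = _psd_clip(m)
                if hit:
                    boundary = True
                setattr(cand, attr, clipped)
        cand.R[mask] = 0.0
        return cand

    while n_em < max_iter:
        trace.append(state["ll"])
        vc1 = _clip_vc(system.em_step(state))
        state1 = system.factorize(vc1)
        n_em += 1
        delta = np.abs(_flatten(vc1) - _flatten(vc)).max()
        if delta < tol * scale:
            vc, state = vc1, state1
            converged = True
            break
        if not accelerate:
            vc, state = vc1, state1
            continue
        # SQUAREM-style squared extrapolation from two EM steps, accepted
        # only if it does not lower the restricted likelihood
        vc2 = _clip_vc(system.em_step(state1))
        n_em += 1
        f0, f1, f2 = _flatten(vc), _flatten(vc1), _flatten(vc2)
        r = f1 - f0
        v = (f2 - f1) - r
        vnorm = float(np.linalg.norm(v))
        accepted = None
        if vnorm > 1e-14:
            alpha = -max(1.0, float(np.linalg.norm(r)) / vnorm)
            try:
                vc_sq = _clip_vc(_unflatten(f0 - 2 * alpha * r + alpha**2 * v, vc))
                state_sq = system.factorize(vc_sq)
                if state_sq["ll"] >= state1["ll"]:
                    accepted, state = vc_sq, state_sq
            except (ValueError, MixedModelError, np.linalg.LinAlgError):
                accepted = None
        if accepted is None:
            accepted = vc2
            state = system.factorize(vc2)
        delta = np.abs(_flatten(accepted) - _flatten(vc1)).max()
        vc = accepted
        if delta < tol * scale:
            converged = True
            break
    else:
        trace.append(state["ll"])
    if converged:
        trace.append(state["ll"])
    if boundary:
        warnings.warn("a variance update hit the PSD boundary; clamped", RuntimeWarning)
    info = {
        "iterations": n_em,
        "converged": converged,
        "boundary": boundary,
        "loglik": state["ll"],
    }
    return vc, trace, info


def genetic_parameters(vc: VarianceComponents) -> GeneticParameters:
    """Heritabilities, repeatabilities and correlation matrices from (G,P,R).

    Heritability uses the full phenotypic variance sigma_a^2 + sigma_p^2 +
    sigma_e^2 per trait; repeatability adds the permanent-environment
    variance to the numerator.
    """
    traits = list(vc.traits)
    Ppad = vc.p_padded()
    total = np.diag(vc.G) + np.diag(Ppad) + np.diag(vc.R)
    if np.any(total <= 0):
        bad = traits[int(np.argmin(total))]
        raise ValueError(f"zero total variance for trait {bad!r}")
    h2 = pd.Series(np.diag(vc.G) / total, index=traits, name="h2")
    rep = pd.Series((np.diag(vc.G) + np.diag(Ppad)) / total, index=traits, name="repeatability")

    def _corr(m: np.ndarray) -> pd.DataFrame:
        d = np.sqrt(np.clip(np.diag(m), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            c = m / np.outer(d, d)
        c[~np.isfinite(c)] = 0.0
        np.fill_diagonal(c, 1.0)
        return pd.DataFrame(c, index=traits, columns=traits)

    return GeneticParameters(
        heritability=h2,
        repeatability=rep,
        genetic_correlation=_corr(vc.G),
        phenotypic_correlation=_corr(vc.G + Ppad + vc.R),
    )
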