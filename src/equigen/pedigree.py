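"""Pedigree parsing, validation and additive-relationship algebra.

A pedigree is an ordered list of (individual, sire, dam) records in which
every known parent precedes its offspring.  From it this module builds the
numerator relationship matrix **A** (expected additive relationships, with
``diag(A) = 1 + F`` where ``F`` is the inbreeding coefficient) by the
tabular recursion, and its sparse inverse by Henderson's direct rules using
per-individual Mendelian-sampling variances ``d_i``.  Inbreeding for the
sparse inverse is computed without forming A, using the Meuwissen & Luo
ancestor-tracing algorithm, so the inverse scales to pedigrees far larger
than the dense matrix does.

Unknown parents are encoded as ``"0"`` in files and treated as unrelated
base-population founders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

#: File sentinel for an unknown parent.
UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "PedigreeError",
    "Pedigree",
    "RelationshipFactors",
    "load_and_sort",
    "extract_ancestors",
    "relationship_factors",
    "a_matrix",
    "a_inverse",
    "write_a_inverse",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass(frozen=True)
class RelationshipFactors:
    """Per-individual inbreeding F and Mendelian-sampling variance d.

    ``d_i`` is the within-family variance share: 1 for founders (both
    parents unknown), ``0.75 - F_s/4`` with one known parent, and
    ``0.5 - (F_s + F_d)/4`` with both known.
    """

    inbreeding: np.ndarray
    mendelian_variances: np.ndarray


class Pedigree:
    """Topologically ordered pedigree with integer-indexed parent links.

    Parameters are assumed validated; use :meth:`from_frame` or
    :func:`load_and_sort` to construct from raw records.
    """

    def __init__(self, ids: Sequence[str], sire_idx: np.ndarray, dam_idx: np.ndarray):
        self.ids = list(ids)
        self.sire_idx = np.asarray(sire_idx, dtype=np.int64)
        self.dam_idx = np.asarray(dam_idx, dtype=np.int64)
        self.index: dict[str, int] = {i: k for k, i in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        for child, (s, d) in enumerate(zip(self.sire_idx, self.dam_idx)):
            if (s >= child and s >= 0) or (d >= child and d >= 0):
                raise PedigreeError(
                    f"pedigree not sorted: parent of {self.ids[child]!r} follows it"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def __repr__(self) -> str:
        return f"Pedigree(n={len(self)})"

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        k = self.index[individual]
        s, d = self.sire_idx[k], self.dam_idx[k]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)

    def to_frame(self) -> pd.DataFrame:
        sire = [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire_idx]
        dam = [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam_idx]
        return pd.DataFrame({"id": self.ids, "sire": sire, "dam": dam})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Validate, close over undeclared parents and topologically sort.

        Individuals referenced only as parents are appended as founders.
        Raises :class:`PedigreeError` on duplicate ids or cycles (the error
        message names one individual on the cycle).
        """
        ids = frame["id"].astype(str).tolist()
        sires = frame["sire"].fillna(UNKNOWN).astype(str).tolist()
        dams = frame["dam"].fillna(UNKNOWN).astype(str).tolist()
        if UNKNOWN in ids:
            raise PedigreeError(f"{UNKNOWN!r} is reserved for unknown parents")
        seen = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate id {i!r}")
            seen.add(i)
        parent_map: dict[str, tuple[str, str]] = {
            i: (s, d) for i, s, d in zip(ids, sires, dams)
        }
        # closure: undeclared parents become founders
        for s, d in list(parent_map.values()):
            for p in (s, d):
                if p != UNKNOWN and p not in parent_map:
                    parent_map[p] = (UNKNOWN, UNKNOWN)

        graph = nx.DiGraph()
        graph.add_nodes_from(parent_map)
        for child, (s, d) in parent_map.items():
            for p in (s, d):
                if p != UNKNOWN:
                    graph.add_edge(p, child)
        try:
            order = list(nx.topological_sort(graph))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(graph)
            raise PedigreeError(
                f"pedigree cycle detected involving individual {cycle[0][0]!r}"
            ) from None
        # stable order: keep declaration order among ties
        decl = {i: k for k, i in enumerate(parent_map)}
        order = list(nx.lexicographical_topological_sort(graph, key=lambda n: decl[n]))
        idx = {i: k for k, i in enumerate(order)}
        sire_idx = np.array(
            [idx[parent_map[i][0]] if parent_map[i][0] != UNKNOWN else -1 for i in order]
        )
        dam_idx = np.array(
            [idx[parent_map[i][1]] if parent_map[i][1] != UNKNOWN else -1 for i in order]
        )
        return cls(order, sire_idx, dam_idx)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        rows = [
            (i, s if s is not None else UNKNOWN, d if d is not None else UNKNOWN)
            for i, s, d in records
        ]
        return cls.from_frame(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


def load_and_sort(path: str | Path) -> Pedigree:
    """Read a pedigree file (CSV or TSV with header id,sire,dam; 0 = unknown)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"id", "sire", "dam"} - set(frame.columns)
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {sorted(missing)}")
    return Pedigree.from_frame(frame)


def extract_ancestors(ped: Pedigree, focal: Iterable[str], generations: int) -> Pedigree:
    """Sub-pedigree of focal individuals plus ancestors up to a given depth.

    Parents beyond the depth are set unknown.  Depth is the minimum number
    of parent links from any focal individual; ``generations=0`` keeps the
    focal individuals only.
    """
    focal = list(focal)
    if generations < 0:
        raise ValueError("generations must be >= 0")
    for f in focal:
        if f not in ped.index:
            raise PedigreeError(f"unknown focal id {f!r}")
    depth: dict[int, int] = {}
    frontier = [ped.index[f] for f in focal]
    for k in frontier:
        depth[k] = 0
    level = 0
    while frontier and level < generations:
        level += 1
        nxt = []
        for k in frontier:
            for p in (ped.sire_idx[k], ped.dam_idx[k]):
                if p >= 0 and (p not in depth or depth[p] > level):
                    depth[p] = level
                    nxt.append(p)
        frontier = nxt
    keep = sorted(depth)
    kept = set(keep)
    rows = []
    for k in keep:
        s, d = ped.sire_idx[k], ped.dam_idx[k]
        rows.append(
            (
                ped.ids[k],
                ped.ids[s] if s in kept else UNKNOWN,
                ped.ids[d] if d in kept else UNKNOWN,
            )
        )
    return Pedigree.from_frame(pd.DataFrame(rows, columns=["id", "sire", "dam"]))


def relationship_factors(ped: Pedigree) -> RelationshipFactors:
    """Inbreeding F and Mendelian variances d by Meuwissen & Luo tracing.

    Avoids forming the dense A: for each individual the generalized
    Cholesky row L is accumulated over its ancestors, giving
    ``a_ii = sum_j L_ij^2 d_j`` and ``F_i = a_ii - 1``.
    """
    n = len(ped)
    F = np.zeros(n)
    d = np.ones(n)
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, di = sire[i], dam[i]
        if s < 0 and di < 0:
            F[i] = 0.0
            d[i] = 1.0
            continue
        fs = F[s] if s >= 0 else -1.0
        fd = F[di] if di >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        # trace ancestors of i
        L: dict[int, float] = {i: 1.0}
        a_ii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
        F[i] = a_ii - 1.0
    return RelationshipFactors(inbreeding=F, mendelian_variances=d)


def a_matrix(ped: Pedigree) -> tuple[np.ndarray, RelationshipFactors]:
    """Dense numerator relationship matrix by the tabular recursion.

    ``a_ij = (a_{i,s(j)} + a_{i,d(j)}) / 2`` for i < j and
    ``a_ii = 1 + a_{s(i),d(i)} / 2``.  Intended for pedigrees up to a few
    thousand individuals; use :func:`a_inverse` directly for larger ones.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    F = np.diag(A) - 1.0
    fs = np.where(sire >= 0, F[sire], -1.0)
    fd = np.where(dam >= 0, F[dam], -1.0)
    d_i = np.where((sire < 0) & (dam < 0), 1.0, 0.5 - 0.25 * (fs + fd))
    return A, RelationshipFactors(inbreeding=F, mendelian_variances=d_i)


def a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's direct rules with inbreeding.

    For each individual i with Mendelian variance ``d_i``, adds
    ``alpha = 1/d_i`` times the outer product of the coefficient vector
    (1 on i, -1/2 on each known parent) to the inverse.
    """
    factors = relationship_factors(ped)
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / factors.mendelian_variances[i]
        coeff = [(i, 1.0)]
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                coeff.append((int(p), -0.5))
        for a, ca in coeff:
            for b, cb in coeff:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ca * cb)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def log_det_a(ped: Pedigree) -> float:
    """log |A| = sum of log Mendelian variances (A = T D T', T unit-triangular)."""
    return float(np.sum(np.log(relationship_factors(ped).mendelian_variances)))


def write_a_inverse(ped: Pedigree, path: str | Path) -> None:
    """Export the lower triangle of A-inverse as 3-column triplet text."""
    ainv = sp.tril(a_inverse(ped)).tocoo()
    with open(path, "w") as fh:
        fh.write("row_id\tcol_id\tvalue\n")
        for r, c, v in zip(ainv.row, ainv.col, ainv.data):
            fh.write(f"{ped.ids[r]}\t{ped.ids[c]}\t{v:.10g}\n")
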