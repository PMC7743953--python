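"""Annual jumping-performance trait from competition results.

Every starter in an event earns points equal to the product of an event
term (exponential in the difficulty level of the event) and a rank term
(exponential in the normal score of the rank, i.e. the expectation of the
standard-normal order statistic of that rank among the starters).  Points
are summed per horse and year and log-transformed, giving an approximately
Gaussian repeated annual trait.

The exact exponential bases and scales used by national point tables are
not public conventions; ``scale`` and ``base`` are therefore parameters
with documented defaults, not reproductions of any federation's table.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "normal_scores",
    "normal_scores_blom",
    "rank_points",
    "event_points",
    "annual_performance",
]

_QUAD_TOL = 1e-10


def _order_stat_mean(j: int, n: int) -> float:
    """E[Z_(j:n)], the j-th smallest of n iid standard normals, by quadrature.

    Integrand: z * j * C(n, j) * Phi^{j-1} (1-Phi)^{n-j} phi, evaluated in
    logs for stability at large n.
    """
    logc = np.log(j) + special.gammaln(n + 1) - special.gammaln(j + 1) - special.gammaln(n - j + 1)

    def integrand(z: float) -> float:
        logf = (
            logc
            + (j - 1) * stats.norm.logcdf(z)
            + (n - j) * stats.norm.logsf(z)
            + stats.norm.logpdf(z)
        )
        return z * np.exp(logf)

    val, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=_QUAD_TOL, limit=200)
    return val


@lru_cache(maxsize=4096)
def _normal_scores_cached(n: int) -> tuple[float, ...]:
    # antisymmetry: compute the top half, mirror the bottom
    half = [_order_stat_mean(n + 1 - r, n) for r in range(1, n // 2 + 1)]
    mid = [0.0] if n % 2 else []
    return tuple(half + mid + [-v for v in reversed(half)])


def normal_scores(n: int) -> np.ndarray:
    """Expected standard-normal order statistics, best rank first.

    Entry ``k`` (0-based rank ``k+1``) is ``E[Z_(n+1-k : n)]``, so rank 1
    receives the largest expectation.  The vector is antisymmetric and sums
    to zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.array(_normal_scores_cached(int(n)))


def normal_scores_blom(n: int) -> np.ndarray:
    """Blom's approximation Phi^-1((j - 0.375)/(n + 0.25)); fast fallback."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranks = np.arange(1, n + 1)
    return stats.norm.ppf((n + 1 - ranks - 0.375) / (n + 0.25))


def rank_points(rank: int, n_starters: int, scale: float = 1.0) -> float:
    """exp(scale * normal score of the rank): positive, decreasing in rank."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if not 1 <= rank <= n_starters:
        raise ValueError(f"rank {rank} outside 1..{n_starters}")
    return float(np.exp(scale * normal_scores(n_starters)[rank - 1]))


def event_points(level: float, base: float = 2.0) -> float:
    """base**level: geometric in the ordinal difficulty level of the event."""
    if base <= 1:
        raise ValueError("base must be > 1")
    if level < 0:
        raise ValueError("difficulty level must be >= 0")
    return float(base**level)


def _validate_competitions(table: pd.DataFrame) -> None:
    required = {"horse", "year", "event", "level", "rank", "n_starters"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"competition table missing columns: {sorted(missing)}")
    bad = table[(table["rank"] < 1) | (table["rank"] > table["n_starters"])]
    if len(bad):
        raise ValueError(f"rank outside 1..n_starters for horse {bad.iloc[0]['horse']!r}")
    dup = table.duplicated(subset=["event", "year", "rank"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(
            f"duplicate rank {row['rank']} in event {row['event']!r} year {row['year']}"
        )
    dup_h = table.duplicated(subset=["event", "year", "horse"])
    if dup_h.any():
        row = table[dup_h].iloc[0]
        raise ValueError(f"horse {row['horse']!r} started twice in event {row['event']!r}")


def annual_performance(
    table: pd.DataFrame, scale: float = 1.0, base: float = 2.0
) -> pd.DataFrame:
    """Per horse and year, the log of the summed event x rank points.

    Expects columns horse, year, event, level, rank, n_starters.  Horses
    with no starts in a year are simply absent from the output.
    """
    if table.empty:
        return pd.DataFrame(columns=["horse", "year", "log_points"])
    _validate_competitions(table)
    pts_event = np.array([event_points(lv, base) for lv in table["level"]])
    pts_rank = np.array(
        [rank_points(r, n, scale) for r, n in zip(table["rank"], table["n_starters"])]
    )
    per_start = pd.DataFrame(
        {
            "horse": table["horse"].to_numpy(),
            "year": table["year"].to_numpy(),
            "points": pts_event * pts_rank,
        }
    )
    out = (
        per_start.groupby(["horse", "year"], sort=True)["points"]
        .sum()
        .pipe(np.log)
        .rename("log_points")
        .reset_index()
    )
    return out
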