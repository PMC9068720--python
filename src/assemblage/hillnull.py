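"""Hill-order dissimilarity profiles with a constrained-randomisation null.

For a pair of communities the Hill beta diversity of order q is the ratio of
gamma to alpha Hill numbers of the pooled pair (equal weights).  It is mapped
to a dissimilarity in [0, 1]:

    regional (Jaccard-type):  qd = (beta^(q-1) - 1) / (2^(q-1) - 1)
    local (Sorensen-type):    qd = (beta^(1-q) - 1) / (2^(1-q) - 1)

with the q -> 1 limit ln(beta)/ln(2) (Horn).  At q = 0 the regional viewpoint
is the Jaccard distance, which is how the presence/absence anchor of the
profile is read.  The null expectation rebuilds each sample with its observed
richness and read depth from occupancy-weighted OTU draws filled by
metacommunity relative abundances (the Raup-Crick kernel in
:mod:`assemblage.nulls`): dissimilarity close to the null at q = 0 indicates
random assembly of membership; departures at q >= 1 indicate deterministic
structuring of abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CountTable
from .nulls import OccupancyNullModel

__all__ = ["hill_dissimilarity", "hill_null_expectation",
           "summarize_hill_curves", "HillDissimilarityResult",
           "DEFAULT_Q_GRID"]

DEFAULT_Q_GRID = tuple(np.round(np.arange(0.0, 3.0 + 1e-9, 0.25), 4))


def _hill_number(p: np.ndarray, q: float) -> np.ndarray:
    """Hill number of order q for rows of a (possibly unnormalised-weight)
    relative-abundance matrix; zeros contribute nothing at any q."""
    p = np.atleast_2d(p)
    mask = p > 0
    if abs(q - 1.0) < 1e-9:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(mask, p * np.log(np.where(mask, p, 1.0)), 0.0)
        return np.exp(-terms.sum(axis=1))
    s = np.where(mask, np.where(mask, p, 1.0) ** q, 0.0)
    return s.sum(axis=1) ** (1.0 / (1.0 - q))


def _beta_pair(p1: np.ndarray, p2: np.ndarray, q: float) -> np.ndarray:
    """Two-assemblage Hill beta (gamma/alpha, equal weights), rows paired."""
    p1 = np.atleast_2d(p1)
    p2 = np.atleast_2d(p2)
    gamma = _hill_number((p1 + p2) / 2.0, q)
    half = np.concatenate([p1 / 2.0, p2 / 2.0], axis=1)
    if abs(q - 1.0) < 1e-9:
        alpha = _hill_number(half, q) / 2.0
    else:
        mask = half > 0
        s = np.where(mask, np.where(mask, half, 1.0) ** q, 0.0)
        alpha = s.sum(axis=1) ** (1.0 / (1.0 - q)) / 2.0
    return gamma / alpha


def _qd_from_beta(beta: np.ndarray, q: float, viewpoint: str) -> np.ndarray:
    beta = np.clip(beta, 1.0, 2.0)
    if abs(q - 1.0) < 1e-9:
        return np.log(beta) / np.log(2.0)
    if viewpoint == "regional":
        return (beta ** (q - 1.0) - 1.0) / (2.0 ** (q - 1.0) - 1.0)
    if viewpoint == "local":
        return (beta ** (1.0 - q) - 1.0) / (2.0 ** (1.0 - q) - 1.0)
    raise ValueError(f"viewpoint must be 'regional' or 'local', got {viewpoint!r}")


def hill_dissimilarity(p1, p2, q: float, viewpoint: str = "regional") -> float:
    """Hill dissimilarity of order q between two relative-abundance vectors."""
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("mismatched OTU axes")
    for name, p in (("p1", p1), ("p2", p2)):
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} must sum to 1")
    beta = _beta_pair(p1, p2, q)
    return float(np.clip(_qd_from_beta(beta, q, viewpoint), 0.0, 1.0)[0])


def _qd_profile(P1: np.ndarray, P2: np.ndarray, q_grid,
                viewpoint: str) -> np.ndarray:
    """qd for paired rows of P1/P2 over the q grid -> (n_rows, n_q)."""
    out = np.empty((np.atleast_2d(P1).shape[0], len(q_grid)))
    for j, q in enumerate(q_grid):
        beta = _beta_pair(P1, P2, float(q))
        out[:, j] = np.clip(_qd_from_beta(beta, float(q), viewpoint), 0.0, 1.0)
    return out


@dataclass
class HillDissimilarityResult:
    """Observed and null Hill-dissimilarity curves per between-group pair."""

    q_grid: tuple
    pairs: pd.DataFrame  # long format: sample_a, sample_b, group_a, group_b,
    #                      q, observed, null_mean, null_sd
    n_iter: int

    def summarize(self, comparison) -> pd.DataFrame:
        return summarize_hill_curves(self, comparison)


def hill_null_expectation(table: CountTable, groups: pd.Series,
                          comparisons: list[tuple[str, str]] | None = None,
                          q_grid=DEFAULT_Q_GRID, n_iter: int = 999,
                          seed: int = 0, viewpoint: str = "regional"
                          ) -> HillDissimilarityResult:
    """Observed and null qd curves for all between-group sample pairs.

    ``groups`` maps sample id -> group label; ``comparisons`` lists the
    (groupA, groupB) contrasts to evaluate (default: all unordered group
    pairs).  Null pairs preserve each sample's richness and depth via the
    occupancy/metacommunity kernel; ``n_iter`` null pairs are drawn per
    observed pair and qd recomputed on each.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = list(pd.unique(groups))
    if comparisons is None:
        comparisons = [(a, b) for i, a in enumerate(labels)
                       for b in labels[i + 1:]]
    for a, b in comparisons:
        for g in (a, b):
            if (groups == g).sum() < 1:
                raise ValueError(f"group {g!r} has no samples")

    kernel = OccupancyNullModel(table)
    rel = table.relative().to_numpy()
    counts = table.counts
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}
    rng = np.random.default_rng([seed, 11])

    records = []
    for a, b in comparisons:
        sa = [s for s in table.sample_ids if groups[s] == a]
        sb = [s for s in table.sample_ids if groups[s] == b]
        for s1 in sa:
            for s2 in sb:
                if s1 == s2:
                    continue
                i, j = sample_pos[s1], sample_pos[s2]
                obs = _qd_profile(rel[i][None, :], rel[j][None, :],
                                  q_grid, viewpoint)[0]
                n1 = kernel.null_like(counts[i], n_iter, rng).astype(float)
                n2 = kernel.null_like(counts[j], n_iter, rng).astype(float)
                n1 /= n1.sum(axis=1, keepdims=True)
                n2 /= n2.sum(axis=1, keepdims=True)
                null = _qd_profile(n1, n2, q_grid, viewpoint)
                nm = null.mean(axis=0)
                ns = null.std(axis=0, ddof=1) if n_iter > 1 else np.full(len(q_grid), np.nan)
                for k, q in enumerate(q_grid):
                    records.append((s1, s2, a, b, float(q), obs[k], nm[k], ns[k]))
    pairs = pd.DataFrame(records, columns=["sample_a", "sample_b", "group_a",
                                           "group_b", "q", "observed",
                                           "null_mean", "null_sd"])
    return HillDissimilarityResult(q_grid=tuple(float(q) for q in q_grid),
                                   pairs=pairs, n_iter=n_iter)


def summarize_hill_curves(result: HillDissimilarityResult,
                          comparison: tuple[str, str]) -> pd.DataFrame:
    """Mean observed and null curves over all pairs of one group contrast."""
    a, b = comparison
    df = result.pairs
    sel = df[((df.group_a == a) & (df.group_b == b)) |
             ((df.group_a == b) & (df.group_b == a))]
    if sel.empty:
        raise ValueError(f"no pairs for comparison {comparison!r}")
    out = (sel.groupby("q", sort=True)[["observed", "null_mean", "null_sd"]]
           .mean().reset_index())
    return out
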