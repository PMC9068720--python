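"""Phylogenetic beta-null deviation (niche vs neutral axis).

Observed pairwise Generalized UniFrac dissimilarities within each group are
compared with dissimilarities among random communities that preserve each
sample's alpha diversity (richness) and read depth, drawn from the shared
occupancy/metacommunity kernel.  The per-group mean of (observed - null mean)
is the beta-null deviation: values near 0 read as neutrally structured,
values far from 0 as niche structured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_core import CountTable, branch_matrix
from .nulls import OccupancyNullModel

__all__ = ["generalized_unifrac", "beta_null_deviation", "BetaNullResult"]


def _gunifrac_branchprops(bp1: np.ndarray, bp2: np.ndarray,
                          lengths: np.ndarray, alpha: float) -> np.ndarray:
    """Generalized UniFrac from branch-proportion rows (paired)."""
    bp1 = np.atleast_2d(bp1)
    bp2 = np.atleast_2d(bp2)
    tot = bp1 + bp2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tot > 0, np.abs(bp1 - bp2) / np.where(tot == 0, 1, tot), 0.0)
    w = lengths[None, :] * np.where(tot > 0, tot, 0.0) ** alpha
    denom = w.sum(axis=1)
    num = (w * ratio).sum(axis=1)
    return np.where(denom > 0, num / np.where(denom == 0, 1, denom), 0.0)


def generalized_unifrac(p1, p2, tree: TreeNode, alpha: float = 0.5,
                        otu_ids=None) -> float:
    """Generalized UniFrac dissimilarity between two relative-abundance vectors.

    ``alpha`` moderates the weight of abundant lineages; ``alpha=1`` equals
    weighted normalized UniFrac.  ``otu_ids`` names the vector entries
    (defaults to the tree's tips in traversal order).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if otu_ids is None:
        otu_ids = [t.name for t in tree.tips()]
    if p1.shape != p2.shape or len(p1) != len(otu_ids):
        raise ValueError("mismatched OTU axes")
    for name, p in (("p1", p1), ("p2", p2)):
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} must sum to 1")
    tips = {t.name for t in tree.tips()}
    missing = [o for o, a, b in zip(otu_ids, p1, p2) if (a > 0 or b > 0)
               and o not in tips]
    if missing:
        raise ValueError(f"OTUs with abundance missing from tree: {missing[:5]}")
    lengths, inc = branch_matrix(tree, otu_ids)
    bp1 = inc.astype(float) @ p1
    bp2 = inc.astype(float) @ p2
    return float(np.clip(_gunifrac_branchprops(bp1, bp2, lengths, alpha), 0, 1)[0])


@dataclass
class BetaNullResult:
    """Per-pair deviations and per-group beta-null summaries."""

    pairs: pd.DataFrame    # group, sample_a, sample_b, observed, null_mean,
    #                        null_sd, deviation
    groups: pd.DataFrame   # group, n_pairs, mean_deviation, sd_deviation
    alpha: float
    n_iter: int


def beta_null_deviation(table: CountTable, tree: TreeNode, groups: pd.Series,
                        n_iter: int = 999, seed: int = 0,
                        alpha: float = 0.5) -> BetaNullResult:
    """Beta-null deviation per within-group sample pair and per group.

    Null communities preserve each sample's richness and total reads (OTU
    identities drawn by occupancy, reads by metacommunity relative abundance);
    for each pair the deviation is observed GUniFrac minus the mean GUniFrac
    over ``n_iter`` null pair draws.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    counts = table.counts
    rel = table.relative().to_numpy()
    otus = table.otu_ids
    lengths, inc = branch_matrix(tree, otus)
    incf = inc.astype(float)
    kernel = OccupancyNullModel(table)
    rng = np.random.default_rng([seed, 23])
    sample_pos = {s: i for i, s in enumerate(table.sample_ids)}

    # one set of null communities (and branch proportions) per sample,
    # shared across all pairs involving that sample
    null_bp: dict[str, np.ndarray] = {}
    obs_bp = rel @ incf.T

    records = []
    for g in pd.unique(groups):
        members = [s for s in table.sample_ids if groups[s] == g]
        if len(members) < 2:
            raise ValueError(f"group {g!r} needs >= 2 samples")
        for s in members:
            if s not in null_bp:
                nulls = kernel.null_like(counts[sample_pos[s]], n_iter, rng)
                nrel = nulls / nulls.sum(axis=1, keepdims=True)
                null_bp[s] = nrel @ incf.T
        for i, s1 in enumerate(members):
            for s2 in members[i + 1:]:
                obs = _gunifrac_branchprops(obs_bp[sample_pos[s1]],
                                            obs_bp[sample_pos[s2]],
                                            lengths, alpha)[0]
                null = _gunifrac_branchprops(null_bp[s1], null_bp[s2],
                                             lengths, alpha)
                nm = float(null.mean())
                ns = float(null.std(ddof=1)) if n_iter > 1 else float("nan")
                records.append((g, s1, s2, float(obs), nm, ns, float(obs) - nm))
    pairs = pd.DataFrame(records, columns=["group", "sample_a", "sample_b",
                                           "observed", "null_mean", "null_sd",
                                           "deviation"])
    summary = (pairs.groupby("group", sort=False)["deviation"]
               .agg(n_pairs="size", mean_deviation="mean", sd_deviation="std")
               .reset_index())
    return BetaNullResult(pairs=pairs, groups=summary, alpha=alpha, n_iter=n_iter)
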