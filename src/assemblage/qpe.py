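"""Quantitative process estimates: betaMNTD, betaNTI, RC_bray, classification.

The two-step decision tree assigns each sample pair to one of five assembly
processes.  First the abundance-weighted beta mean-nearest-taxon distance
(betaMNTD) is compared with a null distribution obtained by shuffling taxa
across the tips of the phylogeny (999 randomisations by default); the
standardized deviation is the beta nearest-taxon index (betaNTI).
betaNTI > 2 assigns variable selection, betaNTI < -2 homogeneous selection.
Pairs without a significant phylogenetic deviation move to the
abundance-weighted Raup-Crick metric (RC_bray): null pairs preserve each
sample's richness and depth (occupancy-weighted membership, metacommunity
abundance-weighted reads), Bray-Curtis is computed per null draw, and
RC = 2 * [P(null < obs) + 0.5 * P(null = obs)] - 1.  RC_bray > +0.95 assigns
dispersal limitation, RC_bray < -0.95 homogenizing dispersal; the remainder
is 'undominated'.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_core import CountTable, patristic_distances
from .nulls import OccupancyNullModel

__all__ = ["beta_mntd", "beta_nti", "raup_crick_bray", "classify_pair",
           "process_percentages", "qpe_analysis", "PROCESSES"]

PROCESSES = ("variable_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "undominated")

DEGENERATE = "unclassified_degenerate"


def _betamntd_from_parts(p1, p2, idx1, idx2, dmat) -> float:
    """Symmetric abundance-weighted nearest-taxon distance from index sets."""
    nnd_to_2 = dmat[np.ix_(idx1, idx2)].min(axis=1)
    nnd_to_1 = dmat[np.ix_(idx2, idx1)].min(axis=1)
    return 0.5 * (float(p1[idx1] @ nnd_to_2) + float(p2[idx2] @ nnd_to_1))


def _prep_pair(p1, p2, tree, otu_ids, dmat):
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("mismatched OTU axes")
    for name, p in (("p1", p1), ("p2", p2)):
        if not np.isclose(p.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} must sum to 1")
        if not (p > 0).any():
            raise ValueError(f"{name} has no taxa")
    if dmat is None:
        if otu_ids is None:
            otu_ids = [t.name for t in tree.tips()]
        dmat = patristic_distances(tree, otu_ids)
    return p1, p2, dmat


def beta_mntd(p1, p2, tree: TreeNode | None = None, otu_ids=None,
              dmat: np.ndarray | None = None) -> float:
    """Abundance-weighted beta mean-nearest-taxon distance between two samples.

    For each taxon present in one sample, the patristic distance to its
    closest relative present in the other sample, weighted by relative
    abundance and averaged over both directions.
    """
    p1, p2, dmat = _prep_pair(p1, p2, tree, otu_ids, dmat)
    idx1 = np.flatnonzero(p1 > 0)
    idx2 = np.flatnonzero(p2 > 0)
    return _betamntd_from_parts(p1, p2, idx1, idx2, dmat)


def beta_nti(p1, p2, tree: TreeNode | None = None, n_iter: int = 999,
             seed: int = 0, otu_ids=None, dmat: np.ndarray | None = None,
             exhaustive: bool = False) -> float:
    """Standardized betaMNTD deviation from a tip-shuffle null.

    Null betaMNTD values are obtained by permuting taxa across the tree's tip
    positions (equivalently shuffling names and abundances across the
    phylogeny); returns (obs - null mean) / null SD.  NaN (flag) when the
    null SD is 0 (degenerate phylogeny, e.g. a star tree).  With
    ``exhaustive=True`` the null enumerates all tip permutations (tiny trees
    only) instead of sampling ``n_iter`` of them.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    p1, p2, dmat = _prep_pair(p1, p2, tree, otu_ids, dmat)
    idx1 = np.flatnonzero(p1 > 0)
    idx2 = np.flatnonzero(p2 > 0)
    obs = _betamntd_from_parts(p1, p2, idx1, idx2, dmat)
    n = dmat.shape[0]
    if exhaustive:
        import itertools
        import math

        if math.factorial(n) > 50000:
            raise ValueError("exhaustive null is only feasible for tiny trees")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng([seed, 31])
        perms = [rng.permutation(n) for _ in range(n_iter)]
    null = np.empty(len(perms))
    for it, perm in enumerate(perms):
        sub = dmat[np.ix_(perm[idx1], perm[idx2])]
        null[it] = 0.5 * (float(p1[idx1] @ sub.min(axis=1)) +
                          float(p2[idx2] @ sub.min(axis=0)))
    sd = null.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((obs - null.mean()) / sd)


def _bray_curtis_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    tot = X.sum(axis=1) + Y.sum(axis=1)
    num = np.abs(X - Y).sum(axis=1)
    return np.where(tot > 0, num / np.where(tot == 0, 1, tot), 0.0)


def raup_crick_bray(s1, s2, table: CountTable, n_iter: int = 999,
                    seed: int = 0, kernel: OccupancyNullModel | None = None,
                    rng: np.random.Generator | None = None) -> float:
    """Abundance-weighted Raup-Crick metric in [-1, 1] for one sample pair.

    ``s1``/``s2`` are count vectors on the table's OTU axis.  Ties between
    null and observed Bray-Curtis count half (standard Raup-Crick convention).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    s1 = np.asarray(s1)
    s2 = np.asarray(s2)
    if kernel is None:
        kernel = OccupancyNullModel(table)
    if rng is None:
        rng = np.random.default_rng([seed, 37])
    obs = _bray_curtis_rows(s1[None, :].astype(float), s2[None, :].astype(float))[0]
    n1 = kernel.null_like(s1, n_iter, rng).astype(float)
    n2 = kernel.null_like(s2, n_iter, rng).astype(float)
    null = _bray_curtis_rows(n1, n2)
    less = np.count_nonzero(null < obs - 1e-12)
    equal = np.count_nonzero(np.abs(null - obs) <= 1e-12)
    return float(2.0 * (less + 0.5 * equal) / n_iter - 1.0)


def classify_pair(beta_nti_value: float, rc_bray_value: float | None = None) -> str:
    """Five-way assembly-process label from (betaNTI, RC_bray).

    betaNTI > 2 -> variable selection; betaNTI < -2 -> homogeneous selection;
    otherwise RC_bray > +0.95 -> dispersal limitation, RC_bray < -0.95 ->
    homogenizing dispersal, else undominated.
    """
    if not np.isfinite(beta_nti_value):
        raise ValueError("beta_nti must be finite; degenerate pairs are flagged upstream")
    if beta_nti_value > 2:
        return "variable_selection"
    if beta_nti_value < -2:
        return "homogeneous_selection"
    if rc_bray_value is None or not np.isfinite(rc_bray_value):
        raise ValueError("RC_bray required when |betaNTI| <= 2")
    if rc_bray_value > 0.95:
        return "dispersal_limitation"
    if rc_bray_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def process_percentages(classifications: pd.DataFrame,
                        by: str = "group") -> pd.DataFrame:
    """Percentage of pairs per process within each group (rows sum to 100)."""
    if classifications.empty:
        raise ValueError("no classified pairs")
    df = classifications[~classifications["process"].isin([DEGENERATE])]
    if df.empty:
        raise ValueError("all pairs degenerate")
    out = (df.groupby(by)["process"].value_counts(normalize=True)
           .unstack(fill_value=0.0) * 100.0)
    for p in PROCESSES:
        if p not in out.columns:
            out[p] = 0.0
    return out[list(PROCESSES)]


def qpe_analysis(table: CountTable, tree: TreeNode, groups: pd.Series,
                 n_iter: int = 999, seed: int = 0,
                 cross_group: bool = False) -> pd.DataFrame:
    """betaMNTD/betaNTI/RC_bray and process labels for sample pairs.

    By default only within-group pairs are evaluated (per-group temporal
    summaries); ``cross_group=True`` instead evaluates pairs across different
    groups (e.g. cross-environment contrasts).  Null betaMNTD values share one
    tip permutation per iteration across all pairs, the standard batch scheme.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    otus = table.otu_ids
    dmat = patristic_distances(tree, otus)
    rel = table.relative().to_numpy()
    counts = table.counts
    n_otus = len(otus)
    sample_ids = table.sample_ids
    present = [np.flatnonzero(rel[i] > 0) for i in range(len(sample_ids))]

    pairs: list[tuple[int, int, str]] = []
    glabels = groups.to_numpy()
    for i in range(len(sample_ids)):
        for j in range(i + 1, len(sample_ids)):
            same = glabels[i] == glabels[j]
            if same and not cross_group:
                pairs.append((i, j, str(glabels[i])))
            elif not same and cross_group:
                pairs.append((i, j, f"{glabels[i]}|{glabels[j]}"))
    if not pairs:
        raise ValueError("no sample pairs to evaluate")

    involved = sorted({i for i, j, _ in pairs} | {j for i, j, _ in pairs})
    rng = np.random.default_rng([seed, 31])

    # observed betaMNTD via per-sample nearest-taxon distance vectors
    def nnd_vectors(perm: np.ndarray | None) -> dict[int, np.ndarray]:
        out = {}
        for s in involved:
            idx = present[s]
            cols = idx if perm is None else perm[idx]
            rows = np.arange(n_otus) if perm is None else perm
            out[s] = dmat[np.ix_(rows, cols)].min(axis=1)
        return out

    nnd_obs = nnd_vectors(None)
    obs = np.array([0.5 * (rel[i] @ nnd_obs[j] + rel[j] @ nnd_obs[i])
                    for i, j, _ in pairs])

    null = np.empty((n_iter, len(pairs)))
    for it in range(n_iter):
        perm = rng.permutation(n_otus)
        nnd = nnd_vectors(perm)
        null[it] = [0.5 * (rel[i] @ nnd[j] + rel[j] @ nnd[i])
                    for i, j, _ in pairs]
    null_sd = null.std(axis=0, ddof=1)
    null_mean = null.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)

    kernel = OccupancyNullModel(table)
    rc_rng = np.random.default_rng([seed, 37])
    records = []
    for k, (i, j, g) in enumerate(pairs):
        rc = np.nan
        if np.isnan(bnti[k]):
            proc = DEGENERATE
        elif abs(bnti[k]) > 2:
            proc = classify_pair(bnti[k])
        else:
            rc = raup_crick_bray(counts[i], counts[j], table, n_iter=n_iter,
                                 kernel=kernel, rng=rc_rng)
            proc = classify_pair(bnti[k], rc)
        records.append((g, sample_ids[i], sample_ids[j], obs[k],
                        float(bnti[k]), rc, proc))
    return pd.DataFrame(records, columns=["group", "sample_a", "sample_b",
                                          "beta_mntd", "beta_nti", "rc_bray",
                                          "process"])
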