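"""Taxa-function robustness: attenuation, buffering, gene distribution features.

Each sample is perturbed in silico many times (default 100): a uniformly drawn
number of its taxa is removed and the remainder renormalized.  For every
perturbation the taxonomic shift t (weighted normalized UniFrac between the
original and perturbed taxon profiles) and the functional shift f (cosine
dissimilarity between the corresponding community function profiles, taxa
weighted by genome copy numbers) are recorded, and the power law

    f = e^(-a) * t^b      i.e.   ln f = -a + b ln t

is fitted by ordinary least squares on the log-transformed points.  The
attenuation coefficient a measures how strongly functional shifts are damped
relative to taxonomic shifts (high a = strong robustness via functional
overlap among genomes); the buffering coefficient b measures how large a
perturbation must be before a functional shift becomes noticeable.

The five gene distribution features (GDF) summarise why communities differ in
robustness: abundance-weighted average genome size, genome size variability,
average functional dissimilarity between genomes, average functional
redundancy, and unique-function abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skbio import TreeNode
from skbio.stats.ordination import pcoa

from .io_core import CountTable, branch_matrix
from .betanull import _gunifrac_branchprops

logger = logging.getLogger("assemblage")

__all__ = ["community_function_profile", "perturb_sample", "taxonomic_shift",
           "functional_shift", "fit_robustness", "robustness_profile",
           "gene_distribution_features", "gdf_ordination", "RobustnessProfile"]

GDF_FEATURES = ("avg_genome_size", "genome_size_variability",
                "avg_functional_dissimilarity", "avg_functional_redundancy",
                "unique_function_abundance")


def community_function_profile(p, funcs: pd.DataFrame) -> np.ndarray:
    """Community function abundances: sum_s p_s * copynumber_{s,k}."""
    p = np.asarray(p, dtype=float)
    if len(p) != funcs.shape[0]:
        raise ValueError("abundance vector does not match function table rows")
    return p @ funcs.to_numpy()


def perturb_sample(p, n_perturbations: int = 100, rng=None, seed: int = 0,
                   mode: str = "removal") -> np.ndarray:
    """Perturbed relative-abundance vectors, one row per perturbation.

    Each perturbation removes k taxa (k uniform in 1..S-1 where S is the
    sample's richness) and renormalizes the remainder, spanning small to large
    magnitudes.
    """
    if mode != "removal":
        raise ValueError("only 'removal' perturbations are implemented")
    p = np.asarray(p, dtype=float)
    support = np.flatnonzero(p > 0)
    S = support.size
    if S < 2:
        raise ValueError("sample needs >= 2 taxa to perturb")
    if rng is None:
        rng = np.random.default_rng([seed, 53])
    out = np.empty((n_perturbations, p.size))
    for i in range(n_perturbations):
        k = int(rng.integers(1, S))
        removed = rng.choice(support, size=k, replace=False)
        q = p.copy()
        q[removed] = 0.0
        out[i] = q / q.sum()
    return out


def taxonomic_shift(p, p_perturbed, tree: TreeNode, otu_ids=None) -> float:
    """Weighted normalized UniFrac between original and perturbed profiles."""
    from .betanull import generalized_unifrac

    return generalized_unifrac(p, p_perturbed, tree, alpha=1.0, otu_ids=otu_ids)


def functional_shift(F, F_perturbed) -> float:
    """Cosine dissimilarity (1 - cosine similarity) between function profiles."""
    F = np.asarray(F, dtype=float)
    G = np.asarray(F_perturbed, dtype=float)
    nf, ng = np.linalg.norm(F), np.linalg.norm(G)
    if nf == 0 or ng == 0:
        raise ValueError("zero function profile; discard this perturbation")
    return float(np.clip(1.0 - F @ G / (nf * ng), 0.0, 1.0))


def fit_robustness(points) -> tuple[float, float, dict]:
    """OLS fit of ln f = -a + b ln t over usable (t, f) perturbation points.

    Points with t = 0 or f = 0 cannot enter the log-log regression; if more
    than half of all points have f = 0 the functional profile is essentially
    unperturbable (very high robustness) and the fit is flagged degenerate
    with a censored-high attenuation (a = inf).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (t, f) pairs")
    t, f = pts[:, 0], pts[:, 1]
    zero_f = np.count_nonzero((t > 0) & (f <= 0))
    usable = (t > 0) & (f > 0)
    diagnostics = {"n_points_used": int(usable.sum()),
                   "n_zero_f": int(zero_f),
                   "degenerate": False, "r_squared": np.nan}
    if zero_f > 0.5 * len(pts):
        diagnostics["degenerate"] = True
        logger.info("robustness fit degenerate: %d/%d perturbations left the "
                    "functional profile unchanged", zero_f, len(pts))
        return float("inf"), float("nan"), diagnostics
    if usable.sum() < 5:
        raise ValueError("need >= 5 usable points with t > 0 and f > 0")
    X = sm.add_constant(np.log(t[usable]))
    fit = sm.OLS(np.log(f[usable]), X).fit()
    a = -float(fit.params[0])
    b = float(fit.params[1])
    diagnostics["r_squared"] = float(fit.rsquared)
    return a, b, diagnostics


@dataclass
class RobustnessProfile:
    """Per-sample robustness coefficients and gene distribution features."""

    samples: pd.DataFrame           # sample, a, b, r_squared, n_points_used,
    #                                 degenerate + the five GDF columns
    by_category: pd.DataFrame | None
    n_perturbations: int


def robustness_profile(table: CountTable, tree: TreeNode, funcs: pd.DataFrame,
                       n_perturbations: int = 100, seed: int = 0,
                       category_map: dict[str, str] | None = None
                       ) -> RobustnessProfile:
    """Attenuation/buffering fits and GDFs for every sample in the table.

    ``funcs`` must cover the table's OTUs (align first).  When
    ``category_map`` is given, per-category (a, b) fits reuse the same
    perturbation set with functional shifts computed on each category's
    function sub-vector.
    """
    otus = table.otu_ids
    funcs = funcs.reindex(otus)
    if funcs.isna().any().any():
        raise ValueError("function table missing OTUs; run align_inputs first")
    rel = table.relative().to_numpy()
    F = funcs.to_numpy()
    lengths, inc = branch_matrix(tree, otus)
    incf = inc.astype(float)
    categories: dict[str, np.ndarray] = {}
    if category_map:
        for cat in sorted(set(category_map.values())):
            cols = np.array([j for j, fn in enumerate(funcs.columns)
                             if category_map.get(fn) == cat])
            if cols.size:
                categories[cat] = cols

    rows, cat_rows = [], []
    rng = np.random.default_rng([seed, 53])
    for i, sid in enumerate(table.sample_ids):
        p = rel[i]
        pert = perturb_sample(p, n_perturbations, rng=rng)
        bp0 = incf @ p
        bps = pert @ incf.T
        t = np.array([_gunifrac_branchprops(bp0, bps[k], lengths, 1.0)[0]
                      for k in range(n_perturbations)])
        F0 = p @ F
        Fp = pert @ F
        f = _cosine_rows(F0, Fp)
        a, b, diag = fit_robustness(np.column_stack([t, f]))
        gdf = gene_distribution_features(p, funcs)
        rows.append({"sample": sid, "a": a, "b": b,
                     "r_squared": diag["r_squared"],
                     "n_points_used": diag["n_points_used"],
                     "degenerate": diag["degenerate"], **gdf})
        for cat, cols in categories.items():
            F0c = F0[cols]
            if np.linalg.norm(F0c) == 0:
                cat_rows.append({"sample": sid, "category": cat, "a": np.nan,
                                 "b": np.nan, "degenerate": True})
                continue
            fc = _cosine_rows(F0c, Fp[:, cols])
            try:
                ac, bc, dc = fit_robustness(np.column_stack([t, fc]))
            except ValueError:
                ac, bc, dc = np.nan, np.nan, {"degenerate": True}
            cat_rows.append({"sample": sid, "category": cat, "a": ac, "b": bc,
                             "degenerate": dc["degenerate"]})
    samples = pd.DataFrame(rows)
    by_cat = pd.DataFrame(cat_rows) if cat_rows else None
    return RobustnessProfile(samples=samples, by_category=by_cat,
                             n_perturbations=n_perturbations)


def _cosine_rows(v: np.ndarray, M: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v)
    nM = np.linalg.norm(M, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(nM > 0, M @ v / (np.where(nM == 0, 1, nM) * nv), np.nan)
    return np.clip(1.0 - sim, 0.0, 1.0)


def gene_distribution_features(p, funcs: pd.DataFrame) -> dict[str, float]:
    """The five abundance-weighted gene distribution features of one sample.

    * avg_genome_size: sum_s p_s * |v_s|_1 (total copy numbers per genome)
    * genome_size_variability: abundance-weighted SD of genome sizes
    * avg_functional_dissimilarity: abundance-pair-weighted mean cosine
      dissimilarity between the genome vectors of distinct present taxa
    * avg_functional_redundancy: number of present genomes carrying each
      function, averaged over carried functions weighted by the function's
      community abundance
    * unique_function_abundance: community abundance summed over functions
      carried by exactly one present taxon, as a fraction of the community
      function profile total
    """
    p = np.asarray(p, dtype=float)
    V = funcs.to_numpy()
    present = np.flatnonzero(p > 0)
    if present.size == 0:
        raise ValueError("empty community")
    w = p[present] / p[present].sum()
    Vp = V[present]
    sizes = Vp.sum(axis=1)
    avg_size = float(w @ sizes)
    variability = float(np.sqrt(max(w @ (sizes - avg_size) ** 2, 0.0)))
    if present.size > 1:
        norms = np.linalg.norm(Vp, axis=1)
        sim = (Vp @ Vp.T) / np.outer(norms, norms)
        dis = np.clip(1.0 - sim, 0.0, 1.0)
        W = np.outer(w, w)
        np.fill_diagonal(W, 0.0)
        avg_dis = float((W * dis).sum() / W.sum())
    else:
        avg_dis = float("nan")
    carriers = Vp > 0
    carried = np.flatnonzero(carriers.any(axis=0))
    profile = w @ Vp
    # per-function redundancy = number of present genomes carrying it,
    # averaged over carried functions weighted by the function's community
    # abundance (so the redundancy of abundant functions dominates)
    counts_k = carriers[:, carried].sum(axis=0).astype(float)
    weights_k = profile[carried]
    redundancy = float((weights_k @ counts_k) / weights_k.sum()) \
        if carried.size and weights_k.sum() > 0 else 0.0
    unique_funcs = carried[carriers[:, carried].sum(axis=0) == 1]
    unique_ab = float(profile[unique_funcs].sum() / profile.sum()) \
        if profile.sum() > 0 else 0.0
    return {"avg_genome_size": avg_size,
            "genome_size_variability": variability,
            "avg_functional_dissimilarity": avg_dis,
            "avg_functional_redundancy": redundancy,
            "unique_function_abundance": unique_ab}


def gdf_ordination(gdf_table: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Principal-coordinate embedding of standardized GDF vectors.

    Returns (sample coordinates, feature loadings as correlations with the
    axes, percent variance per axis).  Constant features are dropped with a
    warning.
    """
    if gdf_table.shape[0] < 3:
        raise ValueError("need >= 3 samples for ordination")
    X = gdf_table.astype(float)
    sd = X.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant GDF feature(s): %s", constant)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (X - X.mean()) / sd
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    dm = DistanceMatrix(squareform(pdist(Z.to_numpy())), ids=list(Z.index))
    ord_res = pcoa(dm)
    coords = ord_res.samples
    coords.index = Z.index
    loadings = pd.DataFrame(
        {ax: [np.corrcoef(Z[f], coords[ax])[0, 1] if coords[ax].std() > 0
              else 0.0 for f in Z.columns]
         for ax in coords.columns[:2]}, index=Z.columns)
    pct = ord_res.proportion_explained * 100.0
    return coords, loadings, pct
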