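"""BVSTEP subset search: the smallest OTU set reproducing the full
Bray-Curtis beta-diversity pattern.

The full table's pairwise Bray-Curtis distances (on relative abundances by
default) are the reference pattern; a forward-addition / backward-elimination
hill-climb maximizes the Spearman rank correlation (Mantel-style, no
permutation test) between the subset's distance vector and the reference,
preferring smaller subsets on ties, with multiple random restarts.  The
search stops at a local optimum; the best subset reaching the target rho
(default 0.95) across restarts is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_core import CountTable

__all__ = ["distance_vector", "bvstep_search", "BvstepResult"]


def _pair_contributions(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-OTU |x_i - x_j| and (x_i + x_j) over all sample pairs.

    Returns two (n_otus, n_pairs) matrices so that subset Bray-Curtis is a
    column sum over the chosen OTUs.
    """
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diff = np.abs(values[iu] - values[ju]).T   # (n_otus, n_pairs)
    tot = (values[iu] + values[ju]).T
    return diff, tot


def distance_vector(table: CountTable, otu_subset=None,
                    transform: str | None = None) -> np.ndarray:
    """Condensed pairwise Bray-Curtis vector over an OTU subset.

    Distances use per-sample relative abundances (optionally sqrt- or
    log1p-transformed first).  A pair where either sample has zero total
    within the subset gets distance 1 by convention.
    """
    values = _transformed(table, transform)
    if otu_subset is not None:
        cols = [table.otu_ids.index(o) for o in otu_subset]
        if not cols:
            raise ValueError("empty OTU subset")
        values = values[:, cols]
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    num = np.abs(values[iu] - values[ju]).sum(axis=1)
    den = (values[iu] + values[ju]).sum(axis=1)
    return np.where(den > 0, num / np.where(den == 0, 1, den), 1.0)


def _transformed(table: CountTable, transform: str | None) -> np.ndarray:
    rel = table.relative().to_numpy()
    if transform is None:
        return rel
    if transform == "sqrt":
        return np.sqrt(rel)
    if transform == "log":
        return np.log1p(rel)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class BvstepResult:
    """Selected subset, its rank correlation, and the search trace."""

    selected: list[str]
    rho: float
    trace: pd.DataFrame = field(repr=False)  # restart, step, action, size, rho


def _subset_rho(mask: np.ndarray, diff: np.ndarray, tot: np.ndarray,
                full_vec: np.ndarray) -> float:
    num = diff[mask].sum(axis=0)
    den = tot[mask].sum(axis=0)
    vec = np.where(den > 0, num / np.where(den == 0, 1, den), 1.0)
    if np.all(vec == vec[0]) or np.all(full_vec == full_vec[0]):
        return -1.0
    rho = spearmanr(vec, full_vec).statistic
    return float(rho) if np.isfinite(rho) else -1.0


def bvstep_search(table: CountTable, rho_target: float = 0.95,
                  max_restarts: int = 10, seed: int = 0,
                  initial_size: int = 5,
                  transform: str | None = None) -> BvstepResult:
    """Hill-climb for a minimal OTU subset matching the full BC pattern.

    Each restart begins from a random subset of ``initial_size`` OTUs and
    alternates best-single-addition / best-single-deletion moves while the
    Spearman rho against the full-table distance vector improves (deletions
    preferred on ties, so subsets shrink when an OTU is redundant).  The best
    subset over restarts is returned; ties in rho prefer the smaller subset.
    """
    if not (0.0 < rho_target <= 1.0):
        raise ValueError("rho_target must be in (0, 1]")
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples")
    rng = np.random.default_rng([seed, 61])
    values = _transformed(table, transform)
    n_otus = values.shape[1]
    diff, tot = _pair_contributions(values)
    full_vec = np.where(tot.sum(axis=0) > 0,
                        diff.sum(axis=0) / np.where(tot.sum(axis=0) == 0, 1,
                                                    tot.sum(axis=0)), 1.0)
    if n_otus == 1:
        trace = pd.DataFrame([(0, 0, "init", 1, 1.0)],
                             columns=["restart", "step", "action", "size", "rho"])
        return BvstepResult(selected=list(table.otu_ids), rho=1.0, trace=trace)

    eps = 1e-9
    best_mask, best_rho = None, -np.inf
    trace_rows = []
    for restart in range(max_restarts):
        mask = np.zeros(n_otus, dtype=bool)
        start = rng.choice(n_otus, size=min(initial_size, n_otus), replace=False)
        mask[start] = True
        rho = _subset_rho(mask, diff, tot, full_vec)
        step = 0
        trace_rows.append((restart, step, "init", int(mask.sum()), rho))
        max_steps = 4 * n_otus
        while step < max_steps:
            step += 1
            add_rho, add_k = -np.inf, -1
            for k in np.flatnonzero(~mask):
                mask[k] = True
                r = _subset_rho(mask, diff, tot, full_vec)
                mask[k] = False
                if r > add_rho:
                    add_rho, add_k = r, k
            del_rho, del_k = -np.inf, -1
            if mask.sum() > 1:
                for k in np.flatnonzero(mask):
                    mask[k] = False
                    r = _subset_rho(mask, diff, tot, full_vec)
                    mask[k] = True
                    if r > del_rho:
                        del_rho, del_k = r, k
            improving_del = del_k >= 0 and del_rho > rho + eps
            improving_add = add_k >= 0 and add_rho > rho + eps
            # a deletion that keeps rho (within eps) shrinks the subset for free
            neutral_del = (del_k >= 0 and del_rho >= rho - eps
                           and del_rho >= rho_target)
            if improving_del and del_rho + eps >= add_rho:
                mask[del_k] = False
                rho = del_rho
                action = f"drop:{table.otu_ids[del_k]}"
            elif improving_add:
                mask[add_k] = True
                rho = add_rho
                action = f"add:{table.otu_ids[add_k]}"
            elif neutral_del:
                mask[del_k] = False
                rho = del_rho
                action = f"drop:{table.otu_ids[del_k]}"
            else:
                break
            trace_rows.append((restart, step, action, int(mask.sum()), rho))
        better = (rho > best_rho + eps
                  or (abs(rho - best_rho) <= eps and best_mask is not None
                      and mask.sum() < best_mask.sum()))
        if best_mask is None or better:
            best_mask, best_rho = mask.copy(), rho
        if best_rho >= rho_target:
            break
    trace = pd.DataFrame(trace_rows,
                         columns=["restart", "step", "action", "size", "rho"])
    selected = [table.otu_ids[k] for k in np.flatnonzero(best_mask)]
    return BvstepResult(selected=selected, rho=float(best_rho), trace=trace)
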