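"""Shared constrained-randomisation kernel for the null-model stages.

The Raup-Crick lineage of null models assembles random communities that
preserve each observed sample's richness and read depth: OTU identities are
drawn without replacement with probability proportional to their occupancy
frequency across the dataset, and the sample's reads are then distributed
among the drawn OTUs in proportion to their mean (metacommunity) relative
abundance.  The Hill-dissimilarity null, the beta-null deviation and RC_bray
all share this kernel.
"""

from __future__ import annotations

import numpy as np

from .io_core import CountTable

__all__ = ["OccupancyNullModel"]


class OccupancyNullModel:
    """Null communities constrained to observed richness and depth.

    Parameters
    ----------
    table:
        The dataset defining the species pool: occupancy frequencies (fraction
        of samples in which each OTU occurs) and metacommunity mean relative
        abundances are estimated from it.
    """

    def __init__(self, table: CountTable):
        counts = table.counts
        self.otu_ids = list(table.otu_ids)
        present = counts > 0
        self.occupancy = present.mean(axis=0).astype(float)
        rel = counts / counts.sum(axis=1, keepdims=True)
        self.meta_rel = rel.mean(axis=0)
        self.pool = np.flatnonzero(self.occupancy > 0)
        if self.pool.size == 0:
            raise ValueError("empty species pool")

    def null_samples(self, richness: int, depth: int, n: int,
                     rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` null count vectors with the given richness and depth.

        Returns an ``(n, n_otus)`` integer matrix.  Richness is clamped to the
        pool size when the observed sample is richer than the pool (possible
        only after subsetting).
        """
        if n < 1:
            raise ValueError("need at least one null draw")
        richness = int(min(richness, self.pool.size))
        if richness < 1 or depth < 1:
            raise ValueError("richness and depth must be positive")
        w = self.occupancy[self.pool]
        # weighted sampling without replacement via Gumbel top-k, vectorised
        gumbel = rng.gumbel(size=(n, self.pool.size))
        keys = np.log(w)[None, :] + gumbel
        chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
        cols = self.pool[chosen]                      # (n, richness)
        pvals = self.meta_rel[cols]
        rowsum = pvals.sum(axis=1, keepdims=True)
        uniform = np.full_like(pvals, 1.0 / richness)
        pvals = np.where(rowsum > 0, pvals / np.where(rowsum == 0, 1, rowsum), uniform)
        reads = rng.multinomial(depth, pvals)         # (n, richness)
        out = np.zeros((n, len(self.otu_ids)), dtype=np.int64)
        np.put_along_axis(out, cols, reads, axis=1)
        return out

    def null_like(self, sample_counts: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
        """Null draws matching one observed sample's richness and depth."""
        richness = int((sample_counts > 0).sum())
        depth = int(sample_counts.sum())
        return self.null_samples(richness, depth, n, rng)
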