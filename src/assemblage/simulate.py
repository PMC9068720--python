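"""Synthetic communities with known assembly processes.

Every analysis stage in this package is validated by parameter/process
recovery on data generated here: Wright-Fisher community time series under
neutral drift, homogeneous or variable selection and dispersal limitation;
planted competitive-lottery clades; sequential recruitment orders with a known
phylogenetic dispersion D; and genome function tables with tunable functional
redundancy.  All generators are pure functions of (parameters, seed).

The selection regimes act through a Brownian trait evolved on the supplied
tree, so selection is phylogenetically autocorrelated — the property the
beta-nearest-taxon statistics are designed to detect.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_core import CountTable, patristic_distances

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_metacommunity",
    "brownian_traits",
    "phylo_axis_trait",
    "simulate_community_series",
    "simulate_taxonomy",
    "plant_lottery_clades",
    "simulate_recruitment_series",
    "simulate_genome_functions",
]

REGIMES = ("neutral", "homogeneous_selection", "variable_selection",
           "dispersal_limited")


@dataclass
class SimConfig:
    """Parameters of one community-series simulation.

    The defaults emulate the shape of a feeding-trial gut microbiome study:
    treatment groups sampled at successive time points, tens of samples,
    hundreds of OTUs, amplicon-scale library sizes.  ``community_size`` is the
    Wright-Fisher population size (drift strength scales with
    generations/community_size); ``selection_strength`` multiplies a
    quartic trait-environment mismatch in z-scored trait units (see
    :func:`simulate_community_series`).  ``migration_rate``,
    ``community_size`` and ``n_generations`` default to ``None`` and resolve
    per regime: neutral drift runs large, well-mixed populations
    (m=0.5, J=1000); selection regimes run smaller isolated populations
    (m=0, J=300) so drift diversifies membership within the selected clade;
    dispersal limitation uses large populations briefly drifted from uneven
    founder draws (m=0, J=2000, 20 generations).
    """

    seed: int = 0
    n_otus: int = 200
    n_groups: int = 4
    n_samples: int = 12          # per group (per time point)
    n_timepoints: int = 1
    library_size: int = 2000
    regime: str = "neutral"
    selection_strength: float = 0.7
    migration_rate: float | None = None
    n_generations: int | None = None
    community_size: int | None = None
    trait_model: str = "phylo_axis"   # or "brownian"
    trait_rate: float = 1.0           # Brownian rate (trait_model="brownian")
    niche_power: int = 4              # exponent of the niche mismatch kernel
    env_optimum: float = 2.2          # shared optimum (homogeneous selection)
    env_gap: float = 2.4              # optimum spacing for variable selection
    founder_sigma: float = 1.0        # lognormal founder-effect noise
    founder_meta_coupling: float = 0.3  # exponent on metacommunity at founding
    founder_pool: int = 12            # dispersal_limited: regional pool size
    founder_size: int = 11            # dispersal_limited: founders per sample
    founder_alpha: float = 0.3        # dispersal_limited: Dirichlet evenness
    metacommunity_sigma: float = 1.2
    group_names: list[str] | None = None

    _REGIME_DEFAULTS = {
        # regime: (migration_rate, community_size, n_generations)
        "neutral": (0.5, 1000, 60),
        "homogeneous_selection": (0.0, 300, 60),
        "variable_selection": (0.0, 300, 60),
        "dispersal_limited": (0.0, 2000, 20),
    }

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        m0, j0, g0 = self._REGIME_DEFAULTS[self.regime]
        if self.migration_rate is None:
            self.migration_rate = m0
        if self.community_size is None:
            self.community_size = j0
        if self.n_generations is None:
            self.n_generations = g0
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ValueError("migration_rate must be in [0, 1]")
        for name in ("n_otus", "n_groups", "n_samples", "n_timepoints",
                     "library_size", "community_size", "founder_size",
                     "founder_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.founder_size > self.founder_pool:
            raise ValueError("founder_size cannot exceed founder_pool")
        if self.trait_model not in ("phylo_axis", "brownian"):
            raise ValueError("trait_model must be 'phylo_axis' or 'brownian'")

    @property
    def groups(self) -> list[str]:
        if self.group_names is not None:
            return list(self.group_names)
        return [f"G{i + 1}" for i in range(self.n_groups)]


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    regime: str | None = None
    group_optima: dict[str, float] | None = None
    traits: dict[str, float] | None = None
    founders: dict[str, list[str]] | None = None
    lottery_clades: dict[str, dict] | None = None
    dispersion: float | None = None
    redundancy: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Tree, metacommunity, traits
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed: int = 0) -> TreeNode:
    """Seeded ultrametric birth-death tree with tips OTU_1..OTU_n."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if not birth_rate > death_rate >= 0:
        raise ValueError("require birth_rate > death_rate >= 0")
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, rng=random.Random(seed))
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"OTU_{i + 1}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick])
    tree.length = None  # drop the birth-death stem edge: no taxa diverge on it
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def simulate_metacommunity(tree: TreeNode, sigma: float = 1.2,
                           seed: int = 0) -> pd.Series:
    """Lognormal-ranked regional relative abundances over the tree's tips.

    ``sigma`` is the lognormal shape; 0 gives a uniform metacommunity.
    """
    tips = [t.name for t in tree.tips()]
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, sigma, size=len(tips))) if sigma > 0 \
        else np.ones(len(tips))
    return pd.Series(raw / raw.sum(), index=tips)


def brownian_traits(tree: TreeNode, rate: float = 1.0, seed: int = 0,
                    standardize: bool = True) -> pd.Series:
    """One Brownian trait per tip, evolved root-to-tip on the branch lengths."""
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(max(rate * (node.length or 0.0), 0.0)))
        values[id(node)] = parent_val + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    s = pd.Series(out)
    if standardize:
        sd = s.std(ddof=0)
        s = (s - s.mean()) / (sd if sd > 0 else 1.0)
    return s


# ---------------------------------------------------------------------------
# Community time series
# ---------------------------------------------------------------------------

def _evolve(x: np.ndarray, meta: np.ndarray, fitness: np.ndarray, m: float,
            community_size: int, n_gen: int, rng: np.random.Generator) -> np.ndarray:
    """Wright-Fisher multinomial resampling with migration and selection."""
    for _ in range(n_gen):
        p = (1.0 - m) * x / community_size + m * meta
        p = p * fitness
        p = p / p.sum()
        x = rng.multinomial(community_size, p)
    return x


def phylo_axis_trait(tree: TreeNode, otu_ids=None) -> pd.Series:
    """Maximally phylogenetically conserved niche axis: z-scored first
    principal coordinate of the patristic distance matrix.

    Selection on this axis targets one region of the tree, which is what the
    beta-nearest-taxon statistics are designed to detect; a Brownian trait on
    typical birth-death trees allows substantial convergent similarity across
    clades and gives a much weaker phylogenetic footprint.
    """
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    if otu_ids is None:
        otu_ids = [t.name for t in tree.tips()]
    dmat = patristic_distances(tree, otu_ids)
    axis = pcoa(DistanceMatrix(dmat, ids=list(otu_ids)),
                number_of_dimensions=1).samples.iloc[:, 0].to_numpy()
    sd = axis.std()
    return pd.Series((axis - axis.mean()) / (sd if sd > 0 else 1.0),
                     index=list(otu_ids))


def simulate_community_series(tree: TreeNode, metacommunity: pd.Series,
                              config: SimConfig
                              ) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Simulate a (groups x time points x replicates) community table.

    Every sample is an independent Wright-Fisher chain.  Founding draws
    ``community_size`` individuals with probabilities proportional to
    ``meta^c * fitness * lognormal(founder_sigma)`` — a metacommunity draw
    (coupling exponent ``c = founder_meta_coupling``) filtered by the
    environment and perturbed by founder effects.  Each generation, offspring
    probabilities are proportional to
    ``((1-m) * x/J + m * meta) * fitness`` and the population is multinomially
    resampled (drift); the chain state is multinomially sampled down to
    ``library_size`` reads at every time point.

    Fitness is ``exp(-s * |trait - optimum|^p)`` with a phylogenetically
    conserved niche trait (see :func:`phylo_axis_trait`; ``trait_model=
    'brownian'`` substitutes a Brownian trait).  Homogeneous selection shares
    one optimum (``env_optimum``, in the conserved tail of the trait) across
    groups; variable selection spaces group optima ``env_gap`` trait SDs
    apart, centered on 0.  Setting ``selection_strength`` to 0 makes fitness
    identically 1, so a selection regime reduces exactly to the neutral
    regime at equal migration/population parameters.

    Dispersal limitation founds each sample from ``founder_size`` taxa drawn
    uniformly from a shared regional pool (the ``founder_pool`` most abundant
    metacommunity taxa) with Dirichlet(``founder_alpha``) proportions —
    historical contingency: shared arrivals, divergent early dominance — and
    drifts with no migration.
    """
    otus = list(metacommunity.index)
    n = len(otus)
    meta = metacommunity.to_numpy(dtype=float)
    meta = meta / meta.sum()
    rng = np.random.default_rng([config.seed, 101])
    if config.trait_model == "brownian":
        traits = brownian_traits(tree, config.trait_rate,
                                 seed=int(np.random.default_rng([config.seed, 7])
                                          .integers(2 ** 31)))
    else:
        traits = phylo_axis_trait(tree, otus)
    trait_vec = traits.reindex(otus).to_numpy()

    groups = config.groups
    if config.regime == "variable_selection":
        span = config.env_gap * (len(groups) - 1)
        optima = {g: -span / 2 + i * config.env_gap for i, g in enumerate(groups)}
    elif config.regime == "homogeneous_selection":
        optima = {g: config.env_optimum for g in groups}
    else:
        optima = {g: 0.0 for g in groups}
    strength = (config.selection_strength
                if config.regime in ("homogeneous_selection", "variable_selection")
                else 0.0)
    m = config.migration_rate
    J = config.community_size
    pool = np.argsort(-meta)[:config.founder_pool]

    rows, meta_rows, founders = [], [], {}
    for g in groups:
        mismatch = np.abs(trait_vec - optima[g]) ** config.niche_power
        fitness = np.exp(-strength * mismatch)
        for r in range(config.n_samples):
            chain_id = f"{g}_r{r + 1}"
            if config.regime == "dispersal_limited":
                idx = rng.choice(pool, size=config.founder_size, replace=False)
                p0 = np.zeros(n)
                p0[idx] = rng.dirichlet(np.full(config.founder_size,
                                                config.founder_alpha))
                founders[chain_id] = [otus[i] for i in sorted(idx)]
            else:
                noise = np.exp(rng.normal(0.0, config.founder_sigma, n)) \
                    if config.founder_sigma > 0 else 1.0
                p0 = (meta ** config.founder_meta_coupling) * fitness * noise
                p0 = p0 / p0.sum()
            x = rng.multinomial(J, p0).astype(float)
            for t in range(config.n_timepoints):
                x = _evolve(x, meta, fitness, m, J, config.n_generations, rng)
                reads = rng.multinomial(config.library_size, x / J)
                sid = f"{g}_T{t + 1}_r{r + 1}"
                rows.append(pd.Series(reads, index=otus, name=sid))
                meta_rows.append({"sample_id": sid, "time_point": f"T{t + 1}",
                                  "group": g})

    table = CountTable(pd.DataFrame(rows))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = metadata.loc[table.sample_ids]
    order = sorted(metadata["time_point"].unique())
    metadata["time_point"] = pd.Categorical(metadata["time_point"],
                                            categories=order, ordered=True)
    truth = GroundTruth(regime=config.regime, group_optima=optima,
                        traits=traits.to_dict(),
                        founders=founders or None)
    return table, metadata, truth


# ---------------------------------------------------------------------------
# Taxonomy and lottery clades
# ---------------------------------------------------------------------------

def simulate_taxonomy(tree: TreeNode, genus_size: int = 4
                      ) -> dict[str, dict[str, str]]:
    """Assign tips to synthetic genera of ~genus_size members, in tip order.

    Adjacent tips in the tree's traversal order are phylogenetically close, so
    the chunks behave like small clades.
    """
    tips = [t.name for t in tree.tips()]
    tax = {}
    for i, otu in enumerate(tips):
        tax[otu] = {"domain": "Bacteria", "genus": f"Genus_{i // genus_size + 1}"}
    return tax


def plant_lottery_clades(table: CountTable, tax: dict[str, dict[str, str]],
                         n_clades: int = 3, clade_size: int = 3,
                         winner_mode: str = "fixed", seed: int = 0,
                         winner_share: float = 0.97
                         ) -> tuple[CountTable, GroundTruth]:
    """Rewrite clade abundances so one member 'wins' each sample.

    For each planted clade and each sample where the clade has reads, one
    member receives ``winner_share`` (>0.95) of the clade's reads.  With
    ``winner_mode='fixed'`` the same OTU wins in every sample (winner
    diversity -> 0); with ``'per_sample_random'`` the winner is re-drawn
    uniformly per sample (diversity -> 1).
    """
    if winner_mode not in ("fixed", "per_sample_random"):
        raise ValueError(f"unknown winner_mode {winner_mode!r}")
    rng = np.random.default_rng([seed, 202])
    genus_members: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        g = tax.get(otu, {}).get("genus")
        if g:
            genus_members.setdefault(g, []).append(otu)
    eligible = [g for g, mem in sorted(genus_members.items())
                if len(mem) >= clade_size]
    if len(eligible) < n_clades:
        raise ValueError(
            f"need {n_clades} clades of >= {clade_size} OTUs, found {len(eligible)}")
    chosen = eligible[:n_clades]
    df = table.data.copy()
    planted: dict[str, dict] = {}
    for g in chosen:
        members = genus_members[g][:clade_size]
        fixed_winner = members[int(rng.integers(len(members)))]
        winners: dict[str, str] = {}
        for sid in df.index:
            total = int(df.loc[sid, members].sum())
            if total < clade_size:
                continue  # clade effectively absent here
            winner = (fixed_winner if winner_mode == "fixed"
                      else members[int(rng.integers(len(members)))])
            share = int(np.ceil(winner_share * total))
            rest = total - share
            alloc = {m: 0 for m in members}
            alloc[winner] = share
            losers = [m for m in members if m != winner]
            base = rest // len(losers)
            for i, m in enumerate(losers):
                alloc[m] = base + (1 if i < rest % len(losers) else 0)
            for m in members:
                df.loc[sid, m] = alloc[m]
            winners[sid] = winner
        planted[g] = {"members": members, "winner_mode": winner_mode,
                      "fixed_winner": fixed_winner if winner_mode == "fixed" else None,
                      "winners": winners}
    return CountTable(df), GroundTruth(lottery_clades=planted)


# ---------------------------------------------------------------------------
# Recruitment series with known dispersion
# ---------------------------------------------------------------------------

def simulate_recruitment_series(tree: TreeNode, d_true: float,
                                n_timepoints: int = 6, taxa_per_step: int = 8,
                                seed: int = 0
                                ) -> tuple[list[tuple[str, frozenset]], GroundTruth]:
    """Sequential recruitment with dispersion ``d_true``.

    Taxa are recruited one at a time; the probability of recruiting candidate
    ``s`` is proportional to ``exp(d_true * z_s)`` where ``z_s`` is the mean
    patristic distance from ``s`` to the already-recruited set, standardized
    over the current candidates.  The first taxon is uniform.  ``d_true > 0``
    favours phylogenetically distant recruits (overdispersion), ``< 0``
    favours close relatives (nepotism), ``0`` is equiprobable.
    """
    if not np.isfinite(d_true):
        raise ValueError("d_true must be finite")
    tips = [t.name for t in tree.tips()]
    total = n_timepoints * taxa_per_step
    if total > len(tips):
        raise ValueError("taxa pool exhausted: need more tips than recruits")
    dmat = patristic_distances(tree, tips)
    rng = np.random.default_rng([seed, 303])
    n = len(tips)
    recruited: list[int] = [int(rng.integers(n))]
    sumdist = dmat[:, recruited[0]].astype(float).copy()
    remaining = np.ones(n, dtype=bool)
    remaining[recruited[0]] = False
    while len(recruited) < total:
        cand = np.flatnonzero(remaining)
        z = sumdist[cand] / len(recruited)
        sd = z.std(ddof=0)
        z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
        logits = d_true * z
        pick = cand[int(np.argmax(logits + rng.gumbel(size=cand.size)))]
        recruited.append(int(pick))
        remaining[pick] = False
        sumdist += dmat[:, pick]
    series = []
    for t in range(n_timepoints):
        new = recruited[t * taxa_per_step:(t + 1) * taxa_per_step]
        series.append((f"T{t + 1}", frozenset(tips[i] for i in new)))
    return series, GroundTruth(dispersion=d_true,
                               extra={"order": [tips[i] for i in recruited]})


def recruitment_series_to_table(series, all_otus, library_size: int = 1000,
                                n_samples: int = 3, seed: int = 0
                                ) -> tuple[CountTable, pd.DataFrame]:
    """Render a recruitment series as a presence count table plus metadata."""
    rng = np.random.default_rng([seed, 404])
    present: set[str] = set()
    rows, meta_rows = [], []
    for t, (label, new) in enumerate(series):
        present |= set(new)
        members = sorted(present)
        for r in range(n_samples):
            reads = rng.multinomial(library_size, np.ones(len(members)) / len(members))
            row = pd.Series(0, index=list(all_otus), dtype=np.int64)
            row.loc[members] = reads
            sid = f"R_{label}_r{r + 1}"
            row.name = sid
            rows.append(row)
            meta_rows.append({"sample_id": sid, "time_point": label, "group": "R"})
    table = CountTable(pd.DataFrame(rows))
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    order = [lbl for lbl, _ in series]
    meta["time_point"] = pd.Categorical(meta["time_point"], categories=order,
                                        ordered=True)
    return table, meta


# ---------------------------------------------------------------------------
# Genome function tables
# ---------------------------------------------------------------------------

_SHARE_PROB = {"low": 0.02, "mid": 0.35, "high": 0.9}


def simulate_genome_functions(otu_ids, n_functions: int = 60,
                              redundancy: str = "mid",
                              genome_size_cv: float = 0.3, seed: int = 0,
                              identical: bool = False
                              ) -> tuple[pd.DataFrame, GroundTruth]:
    """Genome copy-number table with tunable functional redundancy.

    ``redundancy`` sets the probability that any genome carries any function:
    'high' makes functions shared by most genomes (low pairwise cosine
    dissimilarity), 'low' makes them mostly genome-unique.  ``identical=True``
    gives every genome the same vector (zero functional dissimilarity).
    Genome sizes are lognormal with coefficient of variation ``genome_size_cv``.
    """
    if redundancy not in _SHARE_PROB:
        raise ValueError(f"redundancy must be one of {sorted(_SHARE_PROB)}")
    otu_ids = list(otu_ids)
    if len(otu_ids) < 1 or n_functions < 1:
        raise ValueError("need at least one OTU and one function")
    rng = np.random.default_rng([seed, 505])
    funcs = [f"K{j + 1:05d}" for j in range(n_functions)]
    if identical:
        base = rng.integers(1, 4, size=n_functions).astype(float)
        mat = np.tile(base, (len(otu_ids), 1))
    else:
        p = _SHARE_PROB[redundancy]
        carry = rng.random((len(otu_ids), n_functions)) < p
        # no genome may be functionless
        for i in np.flatnonzero(~carry.any(axis=1)):
            carry[i, int(rng.integers(n_functions))] = True
        mat = carry * (1.0 + rng.poisson(0.5, size=carry.shape))
        if genome_size_cv > 0:
            sigma = np.sqrt(np.log(1.0 + genome_size_cv ** 2))
            scale = np.exp(rng.normal(-sigma ** 2 / 2, sigma, size=len(otu_ids)))
            mat = mat * scale[:, None]
    df = pd.DataFrame(mat, index=otu_ids, columns=funcs)
    return df, GroundTruth(redundancy="identical" if identical else redundancy)
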