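# Methods

This note documents the models implemented in `assemblage`, the choices made
where the methods literature leaves the design open, and what the synthetic
validation does and does not demonstrate.

## Null-model kernel (shared by hillnull, betanull, qpe)

All three randomisation stages use one constrained kernel
(`assemblage.nulls.OccupancyNullModel`), in the Raup-Crick lineage: a null
community preserves the observed sample's **richness** and **read depth**;
OTU identities are drawn without replacement with probability proportional to
occupancy frequency across the dataset, and reads are then distributed
multinomially in proportion to metacommunity mean relative abundances
(restricted to the drawn OTUs). Holding depth fixed — in addition to the
richness constraint usually described as "preserving alpha diversity" —
avoids library-size artefacts; both constraints are applied always and the
kernel is shared code, so the Hill null, the beta-null deviation and RC_bray
are mutually consistent. Weighted sampling without replacement uses the
Gumbel top-k trick, which vectorises across iterations.

## Hill-order dissimilarity

For a pair of relative-abundance vectors the Hill beta of order q is
γ/α with equal assemblage weights; it maps to a dissimilarity
`qd = (β^(q−1) − 1)/(2^(q−1) − 1)` (regional/Jaccard-type viewpoint, the
default) or `(β^(1−q) − 1)/(2^(1−q) − 1)` (local/Sørensen-type), with the
q→1 limit `ln β / ln 2`. The regional default makes q=0 exactly the Jaccard
distance, matching how presence/absence anchors of the profile are usually
read; the local viewpoint is available by flag. The default q grid is 0 to 3
in steps of 0.25. Terms with zero abundance contribute nothing at any order
(0^0 is treated as 0, not 1).

## Beta-null deviation

Generalized UniFrac with exponent α (default 0.5, the canonical compromise;
α=1 reproduces weighted normalized UniFrac to machine precision, verified
against scikit-bio) is computed branch-wise from a branch × OTU incidence
matrix. The deviation for a pair is observed minus the mean over null pairs
from the shared kernel; the group summary is the mean deviation over
within-group pairs. On data generated by the kernel itself the group mean
deviation is ≈ 0 (|mean| < 0.02 in the test suite).

## Quantitative process estimates

βMNTD is the symmetric, abundance-weighted mean patristic distance from each
taxon present in one sample to its nearest relative present in the other.
βNTI standardizes it against a null that permutes taxa across the tips of the
whole tree (999 iterations by default; an exhaustive-permutation mode exists
for tiny trees and is the oracle in tests). Note that taxa shared by both
samples contribute zero — βMNTD is driven entirely by the unshared taxa.
RC_bray assembles null pairs from the shared kernel, computes Bray-Curtis per
iteration and scales the rank of the observed value to [−1, 1], ties counted
at half weight. Classification follows the standard two-step tree (selection
first at |βNTI| > 2, then dispersal at |RC_bray| > 0.95); RC is only computed
for pairs that pass the selection gate. Pairs whose null SD is zero
(degenerate phylogeny, e.g. a star tree) are flagged rather than classified.
Within-group pairs are classified by default; a cross-group mode serves
cross-environment contrasts.

## Synthetic communities: what the generator emulates

Every sample is an independent Wright-Fisher chain of `community_size`
individuals: offspring probabilities ∝ `((1−m)·x/J + m·meta) · fitness`,
multinomial resampling per generation, and a final multinomial read draw to
`library_size`. The regimes are distinct study conditions with their own
resolved defaults:

* **Neutral** (m=0.5, J=1000, 60 generations): samples track the
  metacommunity with mild drift; pairs classify as undominated.
* **Selection** (m=0, J=300, 60 generations): fitness is
  `exp(−s·|trait − optimum|⁴)` on a **phylogenetically conserved niche
  axis** — the z-scored first principal coordinate of the patristic distance
  matrix. A Brownian trait (available as `trait_model="brownian"`) proved too
  weak a substrate: convergent trait values across clades blur the
  phylogenetic footprint and βNTI rarely leaves the ±2 band. The quartic
  exponent gives a plateau-and-cliff niche that cuts the low-fitness migrant
  tail harder than a Gaussian at equal width. Because βMNTD sees only
  unshared taxa, selection regimes run with **zero migration and small J** so
  drift creates membership turnover *within* the selected clade; founding is
  `meta^0.3 · fitness · lognormal(σ=1)` — an environmentally filtered
  metacommunity draw with founder effects, whose meta-coupling exponent keeps
  the exact identity "selection at s=0 ≡ neutral" at equal m/J/generations.
  Homogeneous selection places the shared optimum at +2.2 trait SD (an
  extreme environment selects a conserved clade tail); variable selection
  spaces group optima 2.4 SD apart, centered on 0.
* **Dispersal limitation** (m=0, J=2000, 20 generations): each sample is
  founded by 11 of the 12 most abundant metacommunity taxa with
  Dirichlet(0.3) proportions — shared arrivals, divergent early dominance
  (historical contingency) — then drifts briefly. Purely random founder
  subsets do *not* work: they flatten occupancy, making the Raup-Crick null
  exactly as divergent as the data and RC_bray uninformative. The shared
  regional pool is what lets the null "know" the samples should overlap.

The generator does **not** emulate sequencing error, chimeras, compositional
biases, overdispersed library sizes, or real taxonomic structure; taxonomy is
synthetic (tree-order chunks as genera). Passing tests therefore demonstrate
statistical recovery of planted processes under the model's own assumptions,
not robustness to real-data artefacts.

Default study shape: 200 OTUs, 12 samples per regime, library 2000 reads,
lognormal (σ=1.2) metacommunity — the scale of a feeding-trial amplicon
study, and small enough that the full validation runs in about a minute.

## Competitive lottery

Winners require strictly more than 90 % of the clade's within-sample reads.
A clade is evaluated in a sample only when it holds ≥ 0.1 % of the sample
(configurable presence floor; the denominator is clade-present samples).
Winner diversity is Shannon entropy of winner identities normalized by
ln(number of distinct winners), defined as 0 for a single distinct winner.
Single-OTU clades are reported but never flagged lottery-like (their winner
is structurally forced); the joint flag is prevalence > 0.75 **and**
diversity > 0.25.

## Recruitment dispersion

The detection series pools samples within a time point per group; a taxon is
"new" at the first time point where it reaches `presence_min_count` (default
1 read) in any sample. The whole series is modelled, first batch included
(the first taxon is uniform) — conditioning on the seed community was found
to discard the most informative early PD step. For each candidate D on a
grid (−4…4, step 0.2) the expected Faith's-PD accumulation fraction is
estimated by ≥200 Monte-Carlo orderings sharing one Gumbel noise tensor
(common random numbers smooth the objective); D̂ minimizes the squared error
between logit-transformed observed and expected PD fractions, refined
parabolically around the grid minimum. z-standardization of candidate
distances at every step makes D unit-free and D̂ invariant to global branch
rescaling (asserted to 1e-6). The 95 % CI is a **parametric** bootstrap:
replicate orderings are simulated under D̂ and refitted against the cached
expected curves. A step-resampling bootstrap was tried first and badly
undercovered — the dominant noise is which taxa happened to be recruited,
which a handful of coupled step errors cannot express. Degenerate (star)
phylogenies make every candidate D give the same PD law and are flagged
unidentifiable; a grid-edge argmin sets `bound_hit`. Recovery is asymmetric:
underdispersion (D<0) compresses PD increments and is intrinsically harder
to resolve from PD curves than overdispersion, so sign recovery for D<0 is
more tree-dependent.

## Taxa-function robustness

Perturbations remove k taxa (k uniform on 1…S−1) and renormalize — the
simplest magnitude-spanning operator; 100 perturbations per sample by
default. Points with zero functional shift cannot enter the log-log
regression; if more than half the points have f=0 the sample is flagged
degenerate with attenuation reported censored-high (∞) rather than inventing
an epsilon, which would silently set the attenuation scale. The five GDFs
are explicit operationalizations: abundance-weighted mean genome size and
its abundance-weighted SD; abundance-pair-weighted mean cosine dissimilarity
between genome vectors; per-function carrier counts averaged over carried
functions weighted by community function abundance; and the community
abundance share of functions carried by exactly one present taxon. The GDF
ordination is PCoA on Euclidean distances of z-scored features, with
feature-axis correlations as loadings; constant features are dropped with a
warning. Attenuation rises strictly with planted functional redundancy
(low < mid < high), the mechanism by which functional overlap buffers
taxonomic perturbations.

## BVSTEP

Distances are Bray-Curtis on relative abundances (sqrt/log1p transforms by
flag); a pair where either sample has zero total within the subset gets
distance 1 by convention. The search is a forward-addition /
backward-elimination hill-climb on the Spearman rank correlation against the
full-table distance vector, with per-OTU pairwise contributions precomputed
so each candidate move is a vector update. Deletions are preferred on ties
(subsets shrink when an OTU is redundant), restarts default to 10 random
size-5 subsets, and the stop target rho is 0.95. The returned subset is
locally optimal within its final search step.

## Pipeline

One master seed derives per-stage seeds via `SeedSequence([seed, stage
index])`, so toggling one stage never shifts another's random stream. Stage
outputs are TSVs with `#` header lines echoing parameters and seed; the
manifest carries seeds, parameters and dropped-record counts, and contains no
timestamps, so identical configurations produce byte-identical output trees.

## Known limitations

* The recruitment objective is a deliberate operationalization (PD matching
  on the logit scale); other software fitting "logistic error models on PD"
  may differ numerically — only simulation-recovery properties are claimed.
* RC_bray calibration inherits a tree-level random effect: the |βNTI|>2
  false-positive rate is binomial only conditional on a tree, so its
  across-dataset variance is wider than binomial.
* The lottery model's presence floor and prevalence denominator (clade-
  present samples) are configurable conventions; published tables using
  all-sample denominators will differ for patchy clades.
* Cross-group QPE comparisons are off by default; enabling them changes the
  pair population and hence the percentage summaries.
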