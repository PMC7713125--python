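# Methods

This note records the models implemented in `pancestry`, the conventions
chosen where the field admits more than one, and what the synthetic tests
do and do not demonstrate.

## Synthetic pangenomes (`pancestry.simulate`)

**Genome tree.** A Yule (pure-birth) process: with k extant lineages the
next split arrives after Exp(k·λ), stopping at the (n+1)-th epoch, so the
expected root-to-tip height is Σ_{k=2..n} 1/(kλ). By default the tree is
rescaled to height 1 so that all rates are expressed per unit of (rescaled)
branch length; set `tree_height=None` to keep raw Yule heights.

**Gene content.** The root carries `root_families` families. Along a
branch of length t, inherited families are lost independently with
probability 1 − e^(−l·t); new families arrive as a Poisson(g·t) process
uniform in time and are thinned by survival over the branch remainder.
Recorded per-branch gains are therefore the families actually present at
the child node, and mean leaf content follows the continuous birth–death
expectation R·e^(−lT) + (g/l)(1 − e^(−lT)) on an ultrametric tree of
height T — the identity the Monte-Carlo tests check.

**Sequences.** Each family draws one ancestral protein (uniform over the
20 standard amino acids; geometric length around `mean_protein_len`,
minimum 30) at its branch of origin and accumulates Poisson(rate·t·L)
substitutions down the tree, each replacing a site with a uniformly chosen
different residue. This keeps identity ≈ e^(−d) analytically tractable.
Defaults (height-1 tree, substitution rate 0.075/site) put within-family
identity near 85–90 % against a ~5 % inter-family background — the
"clearly clusterable" regime the orthology contract targets. Default
content rates (300 root families, gain 30, loss 0.1) hold leaf gene counts
near steady state (~300, within the configured 200–450 target range) while
continually minting new families, i.e. an open pangenome.

**What the generator does not emulate:** insertions/deletions within
proteins (family members share their ancestral length, so core alignments
are nearly gap-free), realistic amino-acid exchangeabilities, gene
transfer *between* lineages (new families are born once; "HGT-like"
signal exists only as gains on single branches), genome rearrangement,
and fragmented/contaminated assemblies beyond the planted QC failures.
Passing tests therefore certify the machinery — scoring, graph building,
partitioning, fitting, search, reconstruction — under a clean, known
model, not performance on messy real assemblies.

## Orthology (`pancestry.alignment`, `pancestry.clustering`)

Pairwise scoring is Smith–Waterman/Gotoh with BLOSUM62 and affine gaps,
open 11 / extend 1, where a gap of length k costs 11 + (k−1) (Biopython's
PairwiseAligner). Significance uses a Karlin–Altschul-style E-value
E = K·m·n′·exp(−λS): (λ, K) are fitted once per scoring scheme from a
Gumbel fit to local scores of random decoy pairs, and n′ is the total
residue count of the proteome set. A shared-4-mer prefilter (≥ 4 common
4-mers) selects candidate pairs before alignment; at the within-family
identities the generator produces, true pairs share dozens of 4-mers while
random pairs share ≈ 0.1, so the prefilter is effectively lossless.

Hit filtering keeps pairs with E ≤ 10⁻¹⁰ and coverage ≥ 75 % — required on
**both** query and subject spans (a flag relaxes this to query-only), since
"75 % of the pairwise alignment" is otherwise ambiguous. The E-value
cutoff is inclusive (≤). An optional ≥ 30 % identity floor implements the
stricter screen used when hunting candidate horizontal transfers.
Self-hits are dropped.

Reciprocal best hits (highest score, ties by lower E-value then
lexicographic subject id) define an undirected graph weighted by
−log10(max(E, 10⁻¹⁸⁰)); intra-genome reciprocal best non-self hits supply
paralog edges. Markov clustering runs per connected component (exact,
since cross-component transition probability is zero): column-normalize,
expand (matrix square), inflate (elementwise power 1.5 — the customary
OrthoMCL value — then renormalize), prune below 10⁻⁵, until the matrix
moves less than 10⁻⁶ or 100 iterations (non-convergence warns and
interprets the current matrix). Attractor rows give clusters; overlaps
resolve to the larger cluster, then lexicographically; every protein ends
in exactly one cluster; representatives are the longest member (ties to
the smaller id).

## Pan-matrix and partition (`pancestry.panmatrix`)

QC filtering is strict (> 99 % completeness AND < 5 % contamination), with
a force-include escape hatch for taxa needed to complete a phylogeny.
Occupancy classes: core = occupancy G; softcore threshold ⌈0.95·G⌉ (106
of 111 genomes); cloud = occupancy ≤ M + 1 where M is the modal occupancy
among non-softcore families (smallest mode on ties) — a documented
formalization of the "most populated non-core cluster and its neighbours"
heuristic, configurable via `cloud_offset`; shell is the remainder. The
four stored sets are disjoint (softcore excludes core); the conventional
superset count is exposed as `softcore_total`. The strict core keeps core
families with exactly one member in every genome.

## Size curves and openness (`pancestry.curves`)

Ten random genome orderings by default (seeded); when G! ≤ the requested
permutation count the exhaustive ordering set is used, making small-G
means exact. Each mean curve is fitted with F(n) = κ·e^(−n/τ) + offset by
bounded nonlinear least squares (τ ∈ [0.1, 10G]), multi-started from a
log-spaced τ grid with (κ, offset) profiled linearly at each start — the
model is ill-conditioned for near-flat curves, which short-circuit to
κ ≈ 0. `saturation_n` = ⌈τ·ln 100⌉ is the smallest n at which the decaying
term falls below 1 % of κ; it is an explicit stand-in for "how many
genomes suffice to find the core", not a claim of equivalence to any other
rule. Openness is judged on the new-genes curve (Tettelin's convention):
open iff the asymptote tg(θ) exceeds ε = 1 family per genome.

## Trees (`pancestry.msa`, `pancestry.trees`)

The progressive aligner orders merges by UPGMA on fractional shared-3-mer
distances and aligns profiles globally with affine gaps, scoring columns
by expected BLOSUM62 sum-of-pairs. It is a desk-scale substitute for an
external MSA tool; any externally computed alignment can be supplied
through the same `Alignment` container, and an externally computed rooted
Newick can replace the in-repo guide tree for ancestral reconstruction.

Distances are Poisson-corrected, d = −ln(1 − p), with complete deletion of
gapped columns by default (pairwise deletion available); a saturated pair
(p ≥ 1) is a hard error naming the pair. Neighbor joining is standard
Saitou–Nei with deterministic lexicographic tie-breaks; negative branch
lengths are clamped to zero with the deficit moved to the sister edge.
Minimum-evolution refinement hill-climbs over NNI moves, re-estimating
branch lengths by OLS on the path-incidence system and minimizing total
(non-negative) branch length; only strictly improving moves are accepted,
so tree length never increases. Bootstrap resamples alignment columns,
rebuilds the tree per replicate (500 by default), and labels internal
edges of the full-data tree with bipartition percentages; replicates whose
resampled distances saturate are skipped and excluded from the
denominator.

The pan-genome tree treats 0/1 family presence as unordered discrete
characters, for which multistate parsimony reduces to Fitch counting;
the search is random-order stepwise addition plus NNI over 10 restarts
(seeded). An all-constant matrix yields a star tree with a warning.

## Ancestral reconstruction (`pancestry.ancestral`)

Sankoff dynamic programming per family over states {0, 1} (presence mode,
default) or 0..cap (count mode, cap 10) with per-unit transition costs:
gain 2, loss 1 by default. The asymmetric reading of "gain/loss cost 2"
— gain 2 against loss 1 — follows the gain-penalty convention of
gene-content software, which discourages inferring horizontal acquisition;
the symmetric setting (2, 2) is one constructor argument away, and
symmetric unit costs reproduce Fitch counts exactly (tested). Ties in the
top-down pass resolve toward the parent's state, and root ties toward
absence (the smallest state): deterministic, and conservative about
spurious events. The guide tree must be rooted with a bifurcating root;
an unrooted tree raises an error pointing at outgroup rooting. Per-branch
events are read off state changes, so Σ(gain·|gains| + loss·|losses|)
equals the DP optimum (asserted in tests).

`classify_lca` splits an internal node's families into *ancestral*
(present at the node and its parent) and *derived* (gained on the incoming
branch). Percentages are **truncated** (not rounded) to one decimal —
1374/2491 reports as 55.1 — matching the truncation convention of the
analyses this package reproduces; the two percentages may thus sum to
99.9.

## Pipeline (`pancestry.pipeline`)

One master seed spawns independent per-stage seeds (NumPy SeedSequence),
so reruns are byte-identical; the summary echoes the full configuration
for provenance. Stages write their artifacts before the next begins.
Without an explicit outgroup or guide tree, the core tree is midpoint
rooted for reconstruction — adequate for clock-like synthetic data, but a
biological analysis should pass a genuine outgroup. Evaluation against
simulated truth reports clustering ARI, Robinson–Foulds distances,
gain-event precision/recall (branches matched by child leaf set, clusters
mapped to families by majority vote), and root-size relative error.

## Problem sizes used in the shipped tests

The test fixtures are deliberately desk-scale: the clustering/tree
recovery fixture uses 12 genomes × ~300 families (~3,600 proteins), the
end-to-end determinism fixture 8 genomes × 80 families with 50 bootstrap
replicates, and the oracle suites use trees of ≤ 6 leaves where exhaustive
enumeration is exact. These sizes keep every oracle computable while
exercising the same code paths a 100-genome analysis would.

## Known limitations

Alignment-free k-mer prefiltering can miss highly diverged true pairs
(below ~40 % identity) that a full search would score; the MCL cloud/shell
boundary is a formalized approximation of a heuristic with no single
published definition; minimum evolution uses NNI only (no SPR); the
progressive aligner has no iterative refinement; ancestral reconstruction
is parsimony, not probabilistic birth–death, so rate heterogeneity across
branches is not modelled.
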