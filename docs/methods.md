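# Methods

`phylofunc` quantifies the concordance between a clade's phylogeny and the
functional organisation of its species. The question it operationalises is
whether phylogenetic proximity predicts functional similarity — the premise
behind using phylogenetic diversity as a proxy for functional diversity —
and, at the species level, whether phylogenetically singular species are
also functionally singular. The package runs four complementary analyses
between a phylogenetic tree and a functional dendrogram derived from a
mixed-type trait table, under five "models" (all traits, the NA-excluded
subdatabase, and the habitat / trophic / behavior trait groups).

## Inputs and functional dendrogram

Trees are rooted, with non-negative branch lengths in arbitrary units;
polytomies are allowed everywhere. Newick input without branch lengths gets
unit lengths with a warning (parsimony topologies legitimately carry none).

Trait tables are species × traits with three declared kinds per trait —
quantitative, categorical, binary — and a group label (habitat, trophic,
behavior). Typing is supplied as a schema file because it is study
configuration, not inferable from a CSV. Missingness is explicit ("NA" or
empty cells); unparseable values under a quantitative trait are an error
rather than a silent NA.

Functional distance is Gower's coefficient: per-trait contributions in
[0, 1] (range-normalised absolute difference for quantitative traits, 0/1
mismatch otherwise), averaged with weight zero whenever either value is
missing. Quantitative ranges are recomputed over the observed values of the
table actually being analysed, so subdatabase distances are self-contained.
Traits carry equal weights; no prior weighting is applied. A species pair
sharing no observed trait has no defined distance and is an error at the
Gower level; the pipeline pre-empts it by greedily dropping the species
involved in the most undefined pairs (recorded in the model manifest).

The dendrogram is hierarchical clustering of the Gower matrix. Five
agglomeration methods are compared — single, complete, UPGMA, WPGMA, Ward —
and the one maximising the cophenetic correlation (Pearson r between input
distances and the distances implied by the dendrogram) is kept.
Correlations are rounded to 12 decimals before the argmax so exact ties
resolve by the fixed method order above, not floating-point noise. Ward
follows the Ward.D2 convention (scipy's, identical to R `hclust` ward.D2);
note its merge heights are objective values rather than dissimilarities, so
Ward never reproduces even a perfectly ultrametric input exactly — the
other four methods do. Dendrograms are exported as ultrametric trees whose
branch lengths are height differences, so tip-to-tip cophenetic distance
equals the merge distance and total tree length is well-defined.

## Supertree assembly

Source topologies with overlapping taxa can be combined into a supertree by
matrix representation with parsimony: Baum–Ragan coding (one binary
character per internal non-root clade; members 1, other taxa of that tree
0, absent taxa ?) followed by a parsimony search. Scoring is Fitch counting
with '?' unconstrained; the search uses random-addition-order greedy
insertion and NNI hill climbing over several restarts, deterministic given
the seed. NNI (rather than SPR/TBR) is a deliberate desk-scale choice: it
is exhaustively testable and sufficient at the tens-of-taxa sizes the
package targets. MRP yields topology only, so supertrees are returned with
unit branch lengths and an arbitrary rooting.

## The four comparison statistics

1. **Mantel test** between the phylogeny's cophenetic (patristic) distances
   and the Gower distances: Pearson r over unordered pairs, null built by
   jointly permuting rows/columns of the second matrix, 999 permutations by
   default, one-sided (greater) because the question is concordance.
   Permutation p-values use the add-one convention (1+k)/(1+m); permuted
   statistics within 1e-12 of the observed value count as ties, since
   symmetric tip permutations tie exactly in real arithmetic but can differ
   in the last bit across summation orders. An exhaustive mode enumerates
   all n! permutations (identity included) for exact small-n work.

2. **Topological difference (TD) and RTD.** TD is the symmetric difference
   of the two trees' non-trivial unrooted bipartition sets;
   RTD = TD / (2n − 6) maps it to [0, 1] for binary trees. The 2n − 6
   denominator is kept verbatim for multifurcating trees, where fewer
   splits exist and RTD consequently understates conflict; TD counts only
   the splits actually present.

3. **Branch length score (BLS)**, the Kuhner–Felsenstein branch score over
   the union of both trees' splits (trivial tip branches included), with
   both trees first rescaled to total length 1. Both the square-root value
   (bounded by √2 on normalised trees) and the raw squared sum (bounded
   by 2) are reported, because published values of this statistic are not
   always attributable to one convention.

4. **Phylogenetic signal of functional identity.** A species' functional
   identity is summarised by Brownian motion simulated along the functional
   dendrogram (root state 0, σ² = 1 — immaterial, as the statistics are
   scale-invariant): species clustered together receive correlated values.
   Signal on the *phylogeny* is then measured with Moran's I under
   inverse-patristic proximities and Abouheif's C_mean, i.e. Moran's I
   under the Abouheif proximity (reciprocal of the product of direct-
   descendant counts of the internal nodes on the inter-tip path; topology
   only). Both weight matrices are row-normalised; with equal weights
   Moran's I equals the null expectation −1/(n − 1) exactly. Significance
   is by tip permutation, one-sided. Because one Brownian draw is a random
   variable, the default aggregates 100 replicate draws (mean statistic,
   median per-replicate p, all per-replicate values exposed); a
   single-replicate mode reproduces the one-realisation design.

5. **Singularity.** Evolutionary distinctiveness (fair proportion): each
   branch's length is split evenly among its descendant tips and summed
   along each species' root path. ED sums to the total tree length — an
   identity the tests enforce to 1e-9 on thousands of random trees,
   polytomies included. ED on the phylogeny is phylogenetic singularity
   (PS); on the functional dendrogram, functional singularity (FS); their
   association is a two-sided Pearson test. FS is also binned into
   empirical quartiles (ties to the lower bin) for reporting. Because a
   supertree's rooting is arbitrary, ED accepts an `exclude_root_edge`
   flag; the dendrogram side is naturally rooted.

## Synthetic data

The generator emulates the analysis' inputs at study scale: an ultrametric
pure-birth (Yule) phylogeny (default birth rate 1; waiting time Exp(k·λ)
with k extant lineages, one extra waiting time to the present so terminal
branches are positive) and a mixed trait table. The default schema has ten
traits in a 5 habitat / 3 trophic / 2 behavior partition with mixed kinds,
mirroring marine-predator trait databases. Every trait derives from a
latent per-trait scalar; categorical and binary traits are quantile
thresholds of that latent value, so one process controls signal across
kinds. Three regimes span the evolutionary hypotheses of interest:
`conservative` (latent = Brownian tip values on the phylogeny; niche
conservatism), `shuffled` (each column independently permuted; the null)
and `convergent` (values set by an environment grouping drawn independently
of the tree, 3 groups by default, centers ~ N(0, 2·√(σ²·height)) with
within-group noise a quarter of that scale — phylogenetically distant
species share states). Missing values are injected independently per cell;
the mask is redrawn (up to 1000 times, then one random species is cleared)
so at least one fully observed species always remains.

What the generator does *not* emulate: trait–trait correlation structure,
non-Brownian trait evolution (OU, rate shifts), extinction, and
phylogenetically structured missingness (real "NA"s concentrate in poorly
studied clades). Passing tests therefore demonstrate correctness of the
machinery and its statistical calibration under these idealised conditions,
not robustness of scientific conclusions to violations of them.

## Numerical choices and problem sizes

- All randomness flows through explicit integer seeds; derived seeds come
  from `numpy` SeedSequence spawning, and identical configurations
  reproduce reports byte for byte.
- Label alignment between any two structures is always by species name;
  mismatches are errors, never silent reordering.
- Gower symmetry is enforced exactly by averaging the matrix with its
  transpose (accumulation order otherwise leaves ~1e-17 asymmetry that the
  distance-matrix container would reject).
- Dendrogram branch lengths clamp tiny negative slack (fp round-off on
  monotone linkages) to zero.
- The test suite validates at desk scale chosen to finish in minutes:
  1000 Yule trees (n up to 200) for ED conservation, 500 random 8-taxon
  pairs against a brute-force split comparator, exhaustive permutation
  oracles at n = 5–6, 10⁴ Brownian replicates for simulator calibration,
  500 scenario replicates (n = 50) for C_mean power and type-I rates, all
  15 five-taxon topologies against exhaustive parsimony enumeration, and
  200 random matrices against a naive O(n³) UPGMA.

## Known limitations

- The MRP search is heuristic; NNI with restarts can miss the global
  optimum on large or highly conflicting inputs. Scores are exact.
- Ward method selection compares Ward objective heights against raw
  distances, which slightly penalises Ward in the cophenetic correlation —
  inherent to the Ward.D2 convention.
- RTD's fixed 2n − 6 denominator makes values from trees with many
  polytomies conservative relative to binary trees of the same size.
- The Pearson PS~FS test assumes approximate bivariate normality; ED
  distributions are right-skewed on imbalanced trees, so small p-values
  near the threshold deserve a permutation check (the Mantel machinery can
  be reused for that).
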