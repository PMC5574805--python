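# phylofunc

Phylogeny-versus-function concordance analysis for a clade: does the
evolutionary tree of a group of species predict how those species are
organised functionally, and are phylogenetically singular species also
functionally singular? These questions decide whether phylogenetic
diversity can stand in for functional diversity — and whether conservation
prioritisation can target one list of species or needs two.

The package is aimed at ecologists and evolutionary biologists working
with a species × trait table (mixed quantitative / categorical / binary
traits, with missing values) and a phylogeny, at the scale of tens to a
few hundred species.

## What it computes

Given a rooted phylogeny and a trait table, `phylofunc` builds a
functional dendrogram and runs four comparisons, each under five models
(all traits; the NA-excluded subdatabase; habitat, trophic and behavioral
trait groups):

1. **Distance concordance** — Mantel test between patristic distances
   d(i,j) on the phylogeny and Gower distances
   G(i,j) = Σₖ wᵢⱼₖ δᵢⱼₖ / Σₖ wᵢⱼₖ on the traits (999 permutations,
   one-sided).
2. **Tree distance** — topological difference TD (Penny–Hendy symmetric
   difference of bipartition sets), its relative form
   RTD = TD/(2n−6) ∈ [0,1], and the Kuhner–Felsenstein branch length score
   BLS = √Σₛ (ℓ₁(s) − ℓ₂(s))² on trees normalised to total length 1.
3. **Phylogenetic signal** — Brownian "functional identity" simulated on
   the functional dendrogram, scored on the phylogeny with Moran's *I*
   (inverse-patristic weights) and Abouheif's C_mean (topology-only
   Abouheif proximity); both lie near −1/(n−1) without signal and approach
   1 under strong niche conservatism.
4. **Singularity** — fair-proportion evolutionary distinctiveness
   ED(i) = Σ_{branches b above i} ℓ(b)/n_desc(b) on both trees
   (phylogenetic singularity PS, functional singularity FS), their Pearson
   correlation, and FS quartile bins.

The functional dendrogram uses Gower distances and the hierarchical
clustering method (single, complete, UPGMA, WPGMA, Ward) that maximises
cophenetic correlation with the input distances. An MRP supertree module
(Baum–Ragan coding + Fitch parsimony with NNI search) assembles a
phylogeny from overlapping source topologies when no single tree exists.
A synthetic-data generator produces Yule phylogenies and trait tables with
tunable signal (conservative / shuffled / convergent), so the whole
pipeline can be exercised and calibrated without external data.

See `docs/methods.md` for model details, assumptions and limitations.

## Worked example

Simulate a 40-species scenario with conservative (Brownian) traits and 10%
missing values, then run the full analysis:

```sh
phylofunc simulate --n-species 40 --seed 7 --missing-rate 0.1 --out demo
cat > demo/run.yaml <<'YAML'
seed: 11
n_perm: 999
n_brownian_replicates: 100
YAML
phylofunc run --tree demo/tree.nwk --traits demo/traits.csv \
    --schema demo/schema.yaml --config demo/run.yaml --out demo/out
```

`demo/out/` then contains `report.json` plus four TSV summaries. With the
seeds above, the Mantel table reads

```
model	statistic	p_value
full	0.709392	0.001
na_excluded	0.825261	0.001
habitat	0.469726	0.001
trophic	0.589217	0.001
behavior	0.458198	0.001
```

— phylogenetic and functional distances are strongly and significantly
correlated in every model, as expected when traits evolve by Brownian
motion on the tree. The signal table confirms it at the tree level
(C_mean 0.25 for the full model, p = 0.012; strongest for the trophic and
behavioral groups):

```
model	moran_i	moran_p	cmean	cmean_p
full	0.168057	0.008	0.253526	0.012
na_excluded	0.0539016	0.0745	0.128078	0.148
trophic	0.215966	0.003	0.355978	0.0015
```

and the singularity table shows PS and FS positively associated for the
full model (r = 0.346, p = 0.029). Note that even here RTD stays high
(0.78–1.00): exact topology matching is a much stricter criterion than
distance or signal concordance, so a large RTD alone does not demonstrate
functional non-conservatism. On `--signal-mode shuffled` data all four
steps drop to their null expectations.

Each subcommand is also available on its own (`functree`, `supertree`,
`compare`, `signal`, `singularity`), and everything is importable as a
library (`import phylofunc`).

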