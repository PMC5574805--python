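"""End-to-end phylogeny-versus-function concordance analysis.

Given a phylogeny and a mixed-type trait table, the pipeline runs five
models — the full trait set, the NA-excluded subdatabase, and the habitat,
trophic and behavioral trait groups — and for each one executes the four
analytical steps:

1. Gower distances -> clustering-method selection -> functional dendrogram,
   plus a Mantel test of the phylogenetic cophenetic distances against the
   Gower distances;
2. topological difference, RTD and branch-length score between the
   (normalized) phylogeny and functional tree;
3. phylogenetic signal of Brownian functional identity (Moran's I and
   Abouheif's C_mean with permutation p-values);
4. evolutionary distinctiveness on both trees (PS, FS), their Pearson
   correlation, and FS quartile bins.

Species present in only one input, or left with no observed trait by a
model, are pruned for that model and recorded in its manifest. All
randomness flows from the single seed in :class:`RunConfig`, so re-running
with the same configuration reproduces every number bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .clustering import METHODS, cophenetic_correlation, select_clustering
from .phylosignal import functional_identity_signal
from .singularity import (evolutionary_distinctiveness, quartile_bins,
                          singularity_correlation)
from .stats import mantel_test
from .traits import GROUPS, TraitTable, drop_na_species, split_by_group
from .tree import PhyloTree, cophenetic_matrix, normalize_tree, write_newick
from .treecmp import compare_trees

__all__ = ["RunConfig", "run_full_analysis", "write_report", "MODELS"]

logger = logging.getLogger("phylofunc")

#: The five analysis models, in report order.
MODELS = ("full", "na_excluded", "habitat", "trophic", "behavior")


@dataclass
class RunConfig:
    seed: int = 0
    n_perm: int = 999
    n_brownian_replicates: int = 100
    clustering_methods: tuple[str, ...] = METHODS
    models: tuple[str, ...] = MODELS

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("clustering_methods", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _model_table(traits: TraitTable, model: str) -> TraitTable:
    if model == "full":
        return traits
    if model == "na_excluded":
        return drop_na_species(traits)
    if model in GROUPS:
        return split_by_group(traits, model)
    raise ValueError(f"unknown model {model!r}")


def _derived_seed(base: int, *key: int) -> int:
    return int(np.random.SeedSequence([base, *key]).generate_state(1)[0]
               % 2**31)


def run_full_analysis(phylo: PhyloTree, traits: TraitTable,
                      config: RunConfig | None = None) -> dict:
    """Run the four analytical steps under every configured model.

    Returns a JSON-serializable report dictionary keyed by model name, with
    a ``manifest`` per model describing the species actually analysed.
    """
    config = config or RunConfig()
    shared = sorted(set(phylo.tip_labels) & set(traits.species))
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} species shared between tree and table; "
            "need >= 4"
        )
    report: dict = {
        "config": asdict(config),
        "n_input_tree_tips": phylo.n_tips,
        "n_input_table_species": traits.n_species,
        "n_shared_species": len(shared),
        "models": {},
    }
    base_table = TraitTable(traits.data.loc[shared], traits.schema,
                            validate=False)
    for mi, model in enumerate(config.models):
        t0 = time.perf_counter()
        try:
            report["models"][model] = _run_model(
                phylo, base_table, model, mi, config
            )
        except Exception as exc:
            raise RuntimeError(f"model {model!r} failed: {exc}") from exc
        logger.info("model %s done in %.2fs (seed %d)", model,
                    time.perf_counter() - t0, config.seed)
    return report


def _prune_undefined_pairs(table: TraitTable) -> tuple[TraitTable, list[str]]:
    """Drop species until every pair shares at least one observed trait.

    Greedy: repeatedly remove the species involved in the most undefined
    pairs (ties broken by label). Subdatabase models can otherwise leave
    pairs with no common observed trait, whose Gower distance is undefined.
    """
    obs = (~table.missing_mask.values).astype(int)
    keep = list(range(obs.shape[0]))
    dropped_idx = []
    while True:
        shared = obs[keep] @ obs[keep].T
        np.fill_diagonal(shared, 1)
        bad_counts = (shared == 0).sum(axis=1)
        if not bad_counts.any():
            break
        worst = int(np.lexsort((keep, -bad_counts))[0])
        dropped_idx.append(keep.pop(worst))
    if not dropped_idx:
        return table, []
    dropped = sorted(table.data.index[dropped_idx])
    kept_table = TraitTable(table.data.iloc[sorted(keep)], table.schema,
                            validate=False)
    return kept_table, dropped


def _run_model(phylo: PhyloTree, traits: TraitTable, model: str,
               mi: int, config: RunConfig) -> dict:
    table = _model_table(traits, model)
    table, dropped = _prune_undefined_pairs(table)
    species = sorted(table.species)
    if len(species) < 4:
        raise ValueError(f"model retains only {len(species)} species")
    tree = phylo.prune_to(species)

    # step 1: functional dendrogram + Mantel
    gower = table.gower_distance()
    selection = select_clustering(gower, config.clustering_methods)
    functree = selection.tree
    phylo_d = cophenetic_matrix(tree)
    mantel = mantel_test(phylo_d, gower, n_perm=config.n_perm,
                         seed=_derived_seed(config.seed, mi, 1))

    # step 2: tree distances on normalized trees
    cmp_res = compare_trees(normalize_tree(tree), normalize_tree(functree),
                            normalize=False)

    # step 3: phylogenetic signal of Brownian functional identity
    moran, cmean = functional_identity_signal(
        tree, functree, n_replicates=config.n_brownian_replicates,
        n_perm=config.n_perm, seed=_derived_seed(config.seed, mi, 3),
    )

    # step 4: singularities
    ps = evolutionary_distinctiveness(tree, tree_id="phylogenetic")
    fs = evolutionary_distinctiveness(functree, tree_id="functional")
    cor = singularity_correlation(ps, fs)
    bins = quartile_bins(fs)

    return {
        "manifest": {
            "n_species": len(species),
            "species": species,
            "dropped_undefined_pairs": dropped,
            "n_traits": len(table.traits),
            "traits": list(table.traits),
        },
        "clustering": {
            "selected_method": selection.method,
            "cophenetic_correlations": {
                m: round(r, 12) for m, r in selection.correlations.items()
            },
            "functional_tree_newick": write_newick(functree),
        },
        "mantel": mantel.to_dict(),
        "tree_comparison": {
            "td": cmp_res.td,
            "rtd": cmp_res.rtd,
            "bls": cmp_res.bls,
            "bls_squared": cmp_res.bls_squared,
            "n": cmp_res.n,
        },
        "signal": {
            "moran_i": moran.to_dict(),
            "abouheif_cmean": cmean.to_dict(),
        },
        "singularity": {
            "correlation": cor.to_dict(),
            "ps": {s: ps.scores[s] for s in species},
            "fs": {s: fs.scores[s] for s in species},
            "fs_quartile": bins,
        },
    }


# -- report serialization --------------------------------------------------

_TABLES = {
    "table2_mantel.tsv": ("mantel", ["statistic", "p_value"]),
    "table3_tree_comparison.tsv": ("tree_comparison",
                                   ["td", "rtd", "bls", "bls_squared", "n"]),
    "table5_singularity.tsv": ("singularity.correlation",
                               ["statistic", "p_value"]),
}


def _dig(d: dict, dotted: str):
    for part in dotted.split("."):
        d = d[part]
    return d


def write_report(report: dict, outdir) -> None:
    """Write report.json plus Tables-2-to-5-shaped TSV summaries."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    models = report["models"]
    for fname, (key, cols) in _TABLES.items():
        lines = ["model\t" + "\t".join(cols)]
        for model, res in models.items():
            section = _dig(res, key)
            lines.append(model + "\t" +
                         "\t".join(_fmt(section[c]) for c in cols))
        (outdir / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
    lines = ["model\tmoran_i\tmoran_p\tcmean\tcmean_p"]
    for model, res in models.items():
        sig = res["signal"]
        lines.append("\t".join([
            model,
            _fmt(sig["moran_i"]["observed"]), _fmt(sig["moran_i"]["p_value"]),
            _fmt(sig["abouheif_cmean"]["observed"]),
            _fmt(sig["abouheif_cmean"]["p_value"]),
        ]))
    (outdir / "table4_signal.tsv").write_text("\n".join(lines) + "\n",
                                              encoding="utf-8")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
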