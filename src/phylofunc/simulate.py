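"""Synthetic phylogenies and trait tables with tunable phylogenetic signal.

The generator produces the two inputs the concordance analysis consumes — an
ultrametric pure-birth (Yule) phylogeny and a mixed-type trait table — with
control over how strongly traits track the tree:

* ``conservative``: every trait derives from Brownian motion along the
  phylogeny (niche conservatism; strong expected concordance);
* ``shuffled``: each trait's values are independently permuted across
  species, destroying all signal (the null);
* ``convergent``: trait values are set by an environment grouping drawn
  independently of the tree, so phylogenetically distant species share
  states (evolutionary convergence; mismatch despite low within-group
  trait variance).

Categorical and binary traits are quantile-thresholded versions of the same
latent Brownian (or environment-driven) value, so one latent process
controls signal across all trait kinds. The default schema mirrors a
marine-predator trait set: five habitat traits, three trophic traits and
two behavioral traits of mixed kinds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .phylosignal import brownian_simulate_many
from .traits import TraitSpec, TraitTable
from .tree import PhyloTree, parse_newick

__all__ = [
    "ScenarioConfig",
    "default_trait_schema",
    "simulate_yule_tree",
    "simulate_trait_table",
    "inject_missing",
    "simulate_scenario",
]

SIGNAL_MODES = ("conservative", "shuffled", "convergent")


def default_trait_schema() -> dict[str, TraitSpec]:
    """Ten mixed-kind traits in the 5 habitat / 3 trophic / 2 behavior
    partition typical of marine megafauna trait databases."""
    return {
        "depth_range": TraitSpec("quantitative", "habitat"),
        "migration": TraitSpec("binary", "habitat"),
        "shelf_slope": TraitSpec("categorical", "habitat"),
        "offshore_coastal": TraitSpec("categorical", "habitat"),
        "water_preference": TraitSpec("categorical", "habitat"),
        "water_column": TraitSpec("categorical", "trophic"),
        "trophic_level": TraitSpec("quantitative", "trophic"),
        "max_size": TraitSpec("quantitative", "trophic"),
        "nocturnal": TraitSpec("binary", "behavior"),
        "schooling": TraitSpec("binary", "behavior"),
    }


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario."""

    seed: int
    n_species: int = 50
    birth_rate: float = 1.0
    signal_mode: str = "conservative"
    sigma2: float = 1.0
    missing_rate: float = 0.0
    n_categories: int = 3     # levels per categorical trait
    n_env_groups: int = 3     # environments in convergent mode
    schema: dict[str, TraitSpec] = field(default_factory=default_trait_schema)

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.signal_mode not in SIGNAL_MODES:
            raise ValueError(f"signal_mode must be one of {SIGNAL_MODES}")
        if not self.schema:
            raise ValueError("schema must contain at least one trait")

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["schema"] = {k: {"kind": v.kind, "group": v.group}
                         for k, v in self.schema.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["schema"] = {k: TraitSpec(**v) for k, v in raw["schema"].items()}
        return cls(**raw)


class _YNode:
    __slots__ = ("children", "birth", "end", "label")

    def __init__(self, birth: float):
        self.children: list["_YNode"] = []
        self.birth = birth
        self.end: float | None = None
        self.label: str | None = None


def simulate_yule_tree(n: int, birth_rate: float = 1.0,
                       seed: int | None = None) -> PhyloTree:
    """Pure-birth tree grown to ``n`` tips; ultrametric, tips sp0001... .

    Starting from two lineages, the waiting time to the next speciation
    with k extant lineages is Exponential(k * birth_rate); a uniformly
    chosen lineage then splits. Once n lineages exist, one further
    exponential waiting time elapses before the present, so every terminal
    branch has positive length.
    """
    if n < 2:
        raise ValueError("need n >= 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    t = 0.0
    root = _YNode(0.0)
    root.end = 0.0
    root.children = [_YNode(0.0), _YNode(0.0)]
    active = list(root.children)
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node.end = t
        node.children = [_YNode(t), _YNode(t)]
        active.extend(node.children)
    present = t + rng.exponential(1.0 / (n * birth_rate))
    for i, node in enumerate(active):
        node.end = present
        node.label = f"sp{i + 1:04d}"

    def newick(node: _YNode) -> str:
        length = node.end - node.birth
        if not node.children:
            return f"{node.label}:{length:.12f}"
        inner = ",".join(newick(c) for c in node.children)
        return f"({inner}):{length:.12f}"

    return parse_newick(
        f"({newick(root.children[0])},{newick(root.children[1])});"
    )


# -- trait tables ----------------------------------------------------------


def _discretize(latent: np.ndarray, kind: str, n_categories: int) -> np.ndarray:
    """Threshold a latent value at its empirical quantiles into levels."""
    if kind == "quantitative":
        return latent
    k = 2 if kind == "binary" else max(n_categories, 2)
    edges = np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1])
    codes = np.searchsorted(edges, latent, side="left")
    letters = [chr(ord("A") + i) for i in range(k)]
    return np.array([letters[c] for c in codes], dtype=object)


def simulate_trait_table(tree: PhyloTree, config: ScenarioConfig) -> TraitTable:
    """Mixed-type trait table for the tips of ``tree`` under ``config``.

    Each trait has its own latent scalar per species: Brownian tip values on
    the tree (conservative/shuffled) or environment-group centers plus small
    noise (convergent). Quantitative traits expose the latent value;
    categorical and binary traits expose its quantile-thresholded levels.
    Shuffled mode then permutes each trait column independently. Missing
    values are injected at ``config.missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    species = list(tree.tip_labels)
    n = len(species)
    n_traits = len(config.schema)
    columns: dict[str, np.ndarray] = {}
    if config.signal_mode in ("conservative", "shuffled"):
        labels, latents = brownian_simulate_many(
            tree, sigma2=config.sigma2, root_state=0.0,
            seed=int(rng.integers(2**31)), n_replicates=n_traits,
        )
        order = [labels.index(s) for s in species]
        latents = latents[:, order]
    else:  # convergent: environments drawn independently of the tree
        depth = _tree_height(tree)
        scale = np.sqrt(config.sigma2 * depth)
        env = rng.integers(config.n_env_groups, size=n)
        latents = np.empty((n_traits, n))
        for k in range(n_traits):
            centers = rng.normal(0.0, 2.0 * scale, size=config.n_env_groups)
            latents[k] = centers[env] + rng.normal(0.0, 0.25 * scale, size=n)
    for k, (name, spec) in enumerate(config.schema.items()):
        col = _discretize(latents[k], spec.kind, config.n_categories)
        if config.signal_mode == "shuffled":
            col = col[rng.permutation(n)]
        columns[name] = col
    df = pd.DataFrame(columns, index=pd.Index(species, name="species"))
    table = TraitTable(df, config.schema, validate=False)
    if config.missing_rate > 0:
        table = inject_missing(table, config.missing_rate,
                               seed=int(rng.integers(2**31)))
    return table


def _tree_height(tree: PhyloTree) -> float:
    h = 0.0
    depths = {id(tree.dendropy_tree.seed_node): 0.0}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            depths[id(node)] = depths[id(node.parent_node)] + node.edge.length
            h = max(h, depths[id(node)])
    return h if h > 0 else 1.0


def inject_missing(table: TraitTable, rate: float,
                   seed: int | None = None) -> TraitTable:
    """Mask each cell independently with probability ``rate``.

    At least one fully observed species is guaranteed: the mask is redrawn
    (up to 1000 times) if none survives; as a last resort one rng-chosen
    species is unmasked.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return table
    rng = np.random.default_rng(seed)
    shape = table.data.shape
    for _ in range(1000):
        mask = rng.random(shape) < rate
        if (~mask).all(axis=1).any():
            break
    else:
        mask[rng.integers(shape[0])] = False
    data = table.data.mask(pd.DataFrame(mask, index=table.data.index,
                                        columns=table.data.columns))
    return TraitTable(data, table.schema, validate=False)


def simulate_scenario(config: ScenarioConfig) -> tuple[PhyloTree, TraitTable]:
    """Convenience: one Yule tree plus a matching trait table.

    The tree and table get independent substreams of ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_species, config.birth_rate,
                              seed=int(rng.integers(2**31)))
    table_cfg = ScenarioConfig(**{**asdict_plain(config),
                                  "seed": int(rng.integers(2**31))})
    return tree, simulate_trait_table(tree, table_cfg)


def asdict_plain(config: ScenarioConfig) -> dict:
    d = asdict(config)
    d["schema"] = dict(config.schema)  # keep TraitSpec objects
    return d
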