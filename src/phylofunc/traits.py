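"""Mixed-type functional trait tables and the Gower distance.

A trait table holds one row per species and one column per functional trait.
Each trait has a declared *kind* (quantitative, categorical or binary) and a
*group* (habitat, trophic or behavior), supplied as a schema because trait
typing is study-specific configuration, not something inferable from a CSV.

Missing values ("NA" or empty cells) are first-class: the Gower distance
drops a trait from a pair's weighted mean whenever either species lacks it,
and analyses can be repeated on the NA-excluded subdatabase or on per-group
subdatabases to probe the influence of missingness and trait choice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from skbio import DistanceMatrix

__all__ = [
    "TraitSpec",
    "TraitTable",
    "SchemaError",
    "GowerError",
    "read_schema",
    "write_schema",
    "read_trait_table",
    "drop_na_species",
    "split_by_group",
    "trait_correlation_screen",
    "gower_distance",
]

KINDS = ("quantitative", "categorical", "binary")
GROUPS = ("habitat", "trophic", "behavior")


class SchemaError(ValueError):
    """Schema missing, malformed, or inconsistent with the data."""


class GowerError(ValueError):
    """A species pair shares no observed trait: its distance is undefined."""


@dataclass(frozen=True)
class TraitSpec:
    """Declared kind and group of one trait."""

    kind: str
    group: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown trait kind {self.kind!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"unknown trait group {self.group!r}")


class TraitTable:
    """Species x traits table with explicit missing mask and typed schema.

    ``data`` is a pandas DataFrame indexed by species label; quantitative
    columns are float (NaN = missing), categorical/binary columns are object
    (None/NaN = missing). ``schema`` maps every column to a TraitSpec.
    """

    def __init__(self, data: pd.DataFrame, schema: dict[str, TraitSpec],
                 validate: bool = True):
        if set(data.columns) != set(schema):
            missing = sorted(set(data.columns) - set(schema))
            extra = sorted(set(schema) - set(data.columns))
            raise SchemaError(
                f"schema/data mismatch: columns without schema {missing}, "
                f"schema entries without column {extra}"
            )
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise SchemaError(f"duplicate species rows: {dupes}")
        data = data.copy()
        for name, spec in schema.items():
            if spec.kind == "quantitative":
                col = pd.to_numeric(data[name], errors="coerce")
                bad = col.isna() & data[name].notna()
                if validate and bad.any():
                    where = sorted(data.index[bad])
                    raise SchemaError(
                        f"non-numeric value under quantitative trait "
                        f"{name!r} for species {where}"
                    )
                data[name] = col.astype(float)
            else:
                data[name] = data[name].astype(object).where(
                    data[name].notna(), other=np.nan
                )
                if validate and spec.kind == "binary":
                    levels = data[name].dropna().unique()
                    if len(levels) > 2:
                        raise SchemaError(
                            f"binary trait {name!r} has {len(levels)} levels"
                        )
        self.data = data
        self.schema = dict(schema)

    # -- accessors ---------------------------------------------------------

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_species(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def __repr__(self):  # pragma: no cover
        return (f"TraitTable(n_species={self.n_species}, "
                f"n_traits={len(self.traits)})")

    # convenience delegates
    def drop_na_species(self) -> "TraitTable":
        return drop_na_species(self)

    def split_by_group(self, group: str) -> "TraitTable":
        return split_by_group(self, group)

    def gower_distance(self) -> DistanceMatrix:
        return gower_distance(self)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species", na_rep="NA")


# -- schema I/O ------------------------------------------------------------


def read_schema(path) -> dict[str, TraitSpec]:
    """Load a YAML schema mapping trait -> {kind, group}."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("schema file must be a mapping trait -> {kind, group}")
    out = {}
    for name, entry in raw.items():
        try:
            out[name] = TraitSpec(kind=entry["kind"], group=entry["group"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"bad schema entry for {name!r}: {entry!r}") from exc
    return out


def write_schema(schema: dict[str, TraitSpec], path) -> None:
    raw = {k: {"kind": v.kind, "group": v.group} for k, v in schema.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_trait_table(path, schema) -> TraitTable:
    """Read a CSV/TSV trait table (header row of trait names, one row per
    species, "NA" or empty = missing) under a declared schema.

    ``schema`` may be a dict of TraitSpec or a path to a YAML schema file.
    Unparseable cells under a quantitative trait raise, rather than being
    silently coerced to missing.
    """
    if not isinstance(schema, dict):
        schema = read_schema(schema)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=object,
                     na_values=["NA", ""], keep_default_na=False,
                     skipinitialspace=True)
    df.index = df.index.astype(str)
    return TraitTable(df, schema)


# -- subdatabases ----------------------------------------------------------


def drop_na_species(table: TraitTable) -> TraitTable:
    """The NA-excluded subdatabase: species with zero missing values."""
    keep = ~table.missing_mask.any(axis=1)
    if not keep.any():
        raise ValueError("dropping NA species leaves an empty table")
    return TraitTable(table.data.loc[keep], table.schema, validate=False)


def split_by_group(table: TraitTable, group: str) -> TraitTable:
    """Restrict to the traits of one group (habitat/trophic/behavior).

    All species are retained, even those with no observed trait left in the
    group; the Gower distance will flag such species if asked for distances.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown trait group {group!r}; expected one of {GROUPS}")
    cols = [t for t, s in table.schema.items() if s.group == group]
    if not cols:
        raise ValueError(f"no traits in group {group!r}")
    schema = {t: table.schema[t] for t in cols}
    return TraitTable(table.data[cols], schema, validate=False)


# -- trait correlation screen ---------------------------------------------


def _cramers_v(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    tab = pd.crosstab(a, b)
    chi2, p, _, _ = stats.chi2_contingency(tab)
    n = tab.values.sum()
    k = min(tab.shape) - 1
    v = float(np.sqrt(chi2 / (n * k))) if k > 0 and n > 0 else np.nan
    return v, float(p)


def trait_correlation_screen(table: TraitTable, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise association screen across all traits.

    Test per pair of kinds: Spearman rank correlation (quant-quant),
    Cramer's V with a chi-squared p-value (categorical/binary pairs), and
    Kruskal-Wallis (quantitative vs categorical/binary). Pairs with fewer
    than 3 complete observations, or a degenerate grouping, are reported as
    untestable rather than raising.

    Returns a DataFrame with one row per unordered trait pair:
    trait_a, trait_b, test, statistic, p_value, flagged, testable.
    """
    if len(table.traits) < 2:
        raise ValueError("correlation screen needs >= 2 traits")
    rows = []
    for ta, tb in itertools.combinations(table.traits, 2):
        ka, kb = table.schema[ta].kind, table.schema[tb].kind
        sub = table.data[[ta, tb]].dropna()
        a, b = sub[ta], sub[tb]
        stat = p = np.nan
        testable = len(sub) >= 3
        test = "untestable"
        if testable:
            try:
                if ka == "quantitative" and kb == "quantitative":
                    test = "spearman"
                    stat, p = stats.spearmanr(a.astype(float), b.astype(float))
                elif ka != "quantitative" and kb != "quantitative":
                    test = "cramers_v"
                    if a.nunique() < 2 or b.nunique() < 2:
                        raise ValueError("degenerate contingency table")
                    stat, p = _cramers_v(a, b)
                else:
                    test = "kruskal_wallis"
                    if ka == "quantitative":
                        x, g = a.astype(float), b
                    else:
                        x, g = b.astype(float), a
                    groups = [x[g == lvl].values for lvl in g.unique()]
                    if len(groups) < 2 or any(len(v) == 0 for v in groups):
                        raise ValueError("degenerate grouping")
                    stat, p = stats.kruskal(*groups)
            except ValueError:
                testable, test = False, "untestable"
                stat = p = np.nan
        rows.append({
            "trait_a": ta, "trait_b": tb, "test": test,
            "statistic": float(stat) if np.isfinite(stat) else np.nan,
            "p_value": float(p) if np.isfinite(p) else np.nan,
            "flagged": bool(testable and p < alpha),
            "testable": testable,
        })
    return pd.DataFrame(rows)


# -- Gower distance --------------------------------------------------------


def gower_distance(table: TraitTable) -> DistanceMatrix:
    """Gower's general coefficient of dissimilarity for mixed traits.

    d(i,j) = sum_k w_ijk * delta_ijk / sum_k w_ijk where per-trait
    delta is |x_i - x_j| / range for quantitative traits (range over the
    observed values of this table) and a 0/1 mismatch for categorical or
    binary traits; w_ijk = 0 whenever either value is missing. Entries lie
    in [0, 1]. Quantitative traits of zero range carry no information and
    are dropped with a warning; a pair of species sharing no observed trait
    raises :class:`GowerError`.
    """
    n = table.n_species
    if n < 2:
        raise ValueError("Gower distance needs >= 2 species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for name, spec in table.schema.items():
        col = table.data[name]
        obs = col.notna().values
        w = np.outer(obs, obs).astype(float)
        if spec.kind == "quantitative":
            x = col.values.astype(float)
            observed = x[obs]
            rng = float(observed.max() - observed.min()) if obs.any() else 0.0
            if rng == 0.0:
                warnings.warn(
                    f"quantitative trait {name!r} has zero range; dropped",
                    stacklevel=2,
                )
                continue
            xs = np.where(obs, x, 0.0)
            delta = np.abs(xs[:, None] - xs[None, :]) / rng
        else:
            vals = col.values.astype(object)
            delta = (vals[:, None] != vals[None, :]).astype(float)
        num += np.where(w > 0, delta, 0.0) * w
        den += w
    off = ~np.eye(n, dtype=bool)
    if (den[off] == 0).any():
        ii, jj = np.where((den == 0) & off)
        pairs = sorted({tuple(sorted((table.species[i], table.species[j])))
                        for i, j in zip(ii, jj)})
        raise GowerError(
            f"species pairs share no observed trait: {pairs[:10]}"
        )
    with np.errstate(invalid="ignore"):
        d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against fp accumulation order
    return DistanceMatrix(d, ids=list(table.species))


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    """Export a distance matrix as a square labeled TSV."""
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="species"
    )
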