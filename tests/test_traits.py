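"""Trait-table ingestion, subdatabases, correlation screen, Gower distance."""

import numpy as np
import pandas as pd
import pytest

from phylofunc import (GowerError, ScenarioConfig, SchemaError, TraitSpec,
                       TraitTable, drop_na_species, gower_distance,
                       inject_missing, read_trait_table, simulate_scenario,
                       split_by_group, trait_correlation_screen, write_schema)
from phylofunc.traits import read_schema


@pytest.fixture
def csv_file(tmp_path):
    p = tmp_path / "traits.csv"
    p.write_text(
        "species,size,color\n"
        "s1,1.5,red\n"
        "s2,NA,blue\n"
        "s3,3.0,\n"
    )
    return p


SCHEMA2 = {
    "size": TraitSpec("quantitative", "trophic"),
    "color": TraitSpec("categorical", "habitat"),
}


class TestIO:
    def test_na_and_empty_become_missing(self, csv_file):
        t = read_trait_table(csv_file, SCHEMA2)
        assert t.missing_mask.values.sum() == 2
        assert t.missing_mask.loc["s2", "size"]
        assert t.missing_mask.loc["s3", "color"]

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("species,size,color\ns1,1,red\ns1,2,blue\n")
        with pytest.raises(SchemaError, match="duplicate"):
            read_trait_table(p, SCHEMA2)

    def test_schema_missing_column_named(self, csv_file):
        with pytest.raises(SchemaError, match="color"):
            read_trait_table(csv_file, {"size": SCHEMA2["size"]})

    def test_unparseable_quantitative_cell_is_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,size,color\ns1,big,red\ns2,2,blue\n")
        with pytest.raises(SchemaError, match="non-numeric"):
            read_trait_table(p, SCHEMA2)

    def test_schema_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "schema.yaml"
        write_schema(SCHEMA2, path)
        assert read_schema(path) == SCHEMA2

    def test_binary_with_three_levels_rejected(self):
        df = pd.DataFrame({"b": ["x", "y", "z"]},
                          index=pd.Index(["s1", "s2", "s3"], name="species"))
        with pytest.raises(SchemaError, match="levels"):
            TraitTable(df, {"b": TraitSpec("binary", "behavior")})


class TestSubdatabases:
    def test_drop_na_keeps_complete_species(self, rng):
        cfg = ScenarioConfig(seed=3, n_species=20, missing_rate=0.3)
        _, table = simulate_scenario(cfg)
        complete = (~table.missing_mask.any(axis=1)).sum()
        sub = drop_na_species(table)
        assert sub.n_species == complete
        assert not sub.missing_mask.values.any()
        assert sub.traits == table.traits

    def test_drop_na_identity_when_complete(self, mixed_table):
        full = TraitTable(mixed_table.data.dropna(), mixed_table.schema,
                          validate=False)
        assert drop_na_species(full).species == full.species

    def test_drop_na_empty_result_is_error(self):
        df = pd.DataFrame({"x": [np.nan, np.nan]},
                          index=pd.Index(["a", "b"], name="species"))
        t = TraitTable(df, {"x": TraitSpec("quantitative", "habitat")},
                       validate=False)
        with pytest.raises(ValueError, match="empty"):
            drop_na_species(t)

    def test_group_partition(self):
        schema = ScenarioConfig(seed=0).schema
        by_group = {g: [t for t, s in schema.items() if s.group == g]
                    for g in ("habitat", "trophic", "behavior")}
        assert len(by_group["habitat"]) == 5
        assert len(by_group["trophic"]) == 3
        assert by_group["behavior"] == ["nocturnal", "schooling"]

    def test_split_by_group(self, mixed_table):
        sub = split_by_group(mixed_table, "behavior")
        assert sub.traits == ("social",)
        assert sub.species == mixed_table.species
        union = set()
        for g in ("habitat", "trophic", "behavior"):
            union |= set(split_by_group(mixed_table, g).traits)
        assert union == set(mixed_table.traits)

    def test_unknown_group(self, mixed_table):
        with pytest.raises(ValueError, match="unknown"):
            split_by_group(mixed_table, "morphology")


class TestCorrelationScreen:
    def test_self_copy_is_flagged(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": x.copy()},
                          index=pd.Index([f"s{i}" for i in range(60)],
                                         name="species"))
        schema = {"a": TraitSpec("quantitative", "habitat"),
                  "b": TraitSpec("quantitative", "habitat")}
        res = trait_correlation_screen(TraitTable(df, schema))
        row = res.iloc[0]
        assert row.statistic == pytest.approx(1.0)
        assert row.p_value < 1e-10 and row.flagged

    def test_quant_vs_own_discretization(self, rng):
        x = rng.normal(size=40)
        lev = np.where(x > np.median(x), "hi", "lo")
        df = pd.DataFrame({"q": x, "c": lev},
                          index=pd.Index([f"s{i}" for i in range(40)],
                                         name="species"))
        schema = {"q": TraitSpec("quantitative", "habitat"),
                  "c": TraitSpec("binary", "habitat")}
        res = trait_correlation_screen(TraitTable(df, schema))
        assert res.iloc[0].test == "kruskal_wallis"
        assert res.iloc[0].p_value < 0.01

    def test_type_one_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        flags = 0
        n_tables = 500
        for _ in range(n_tables):
            df = pd.DataFrame(
                {"a": rng.normal(size=200), "b": rng.normal(size=200)},
                index=pd.Index([f"s{i}" for i in range(200)], name="species"),
            )
            schema = {"a": TraitSpec("quantitative", "habitat"),
                      "b": TraitSpec("quantitative", "habitat")}
            res = trait_correlation_screen(TraitTable(df, schema), alpha=0.05)
            flags += int(res.iloc[0].flagged)
        assert 0.03 <= flags / n_tables <= 0.07

    def test_short_trait_untestable(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan],
                           "b": [2.0, 1.0, 4.0]},
                          index=pd.Index(["x", "y", "z"], name="species"))
        schema = {"a": TraitSpec("quantitative", "habitat"),
                  "b": TraitSpec("quantitative", "habitat")}
        res = trait_correlation_screen(TraitTable(df, schema, validate=False))
        assert not res.iloc[0].testable


class TestGower:
    def test_hand_worked_mixed_case(self, mixed_table):
        dm = gower_distance(mixed_table)
        # s1 vs s2: size |0-5|/10=0.5, color mismatch 1, social mismatch 1
        assert dm["s1", "s2"] == pytest.approx((0.5 + 1 + 1) / 3)
        # s1 vs s3: color missing -> weight 0; size 1.0, social 1
        assert dm["s1", "s3"] == pytest.approx((1.0 + 1.0) / 2)
        # s2 vs s3: size 0.5, social match 0
        assert dm["s2", "s3"] == pytest.approx(0.5 / 2)

    def test_identical_rows_give_zero(self):
        df = pd.DataFrame({"q": [1.0, 1.0], "c": ["x", "x"]},
                          index=pd.Index(["a", "b"], name="species"))
        schema = {"q": TraitSpec("quantitative", "habitat"),
                  "c": TraitSpec("categorical", "habitat")}
        with pytest.warns(UserWarning, match="zero range"):
            dm = gower_distance(TraitTable(df, schema))
        assert dm["a", "b"] == 0.0

    def test_all_binary_mismatch_gives_one(self):
        df = pd.DataFrame(
            {f"b{k}": ["x", "y"] for k in range(4)},
            index=pd.Index(["a", "b"], name="species"),
        )
        schema = {f"b{k}": TraitSpec("binary", "behavior") for k in range(4)}
        assert gower_distance(TraitTable(df, schema))["a", "b"] == 1.0

    def test_single_quant_trait(self):
        df = pd.DataFrame({"q": [0.0, 5.0, 10.0]},
                          index=pd.Index(["s1", "s2", "s3"], name="species"))
        dm = gower_distance(
            TraitTable(df, {"q": TraitSpec("quantitative", "habitat")})
        )
        assert dm["s1", "s2"] == pytest.approx(0.5)

    def test_affine_rescaling_invariance(self, rng):
        cfg = ScenarioConfig(seed=9, n_species=15)
        _, table = simulate_scenario(cfg)
        base = gower_distance(table).data
        data = table.data.copy()
        data["trophic_level"] = data["trophic_level"] * 37.0 - 4.2
        rescaled = gower_distance(TraitTable(data, table.schema,
                                             validate=False)).data
        np.testing.assert_allclose(base, rescaled, atol=1e-12)

    def test_no_shared_trait_pair_is_error(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 2.0]},
                          index=pd.Index(["s1", "s2"], name="species"))
        schema = {"a": TraitSpec("quantitative", "habitat"),
                  "b": TraitSpec("quantitative", "habitat")}
        # single-observation columns also trigger zero-range warnings first
        with pytest.warns(UserWarning, match="zero range"):
            with pytest.raises(GowerError, match="s1"):
                gower_distance(TraitTable(df, schema, validate=False))

    def test_drop_na_then_gower_never_errors(self):
        for seed in range(5):
            cfg = ScenarioConfig(seed=seed, n_species=15, missing_rate=0.4)
            _, table = simulate_scenario(cfg)
            sub = drop_na_species(table)
            if sub.n_species >= 2:
                dm = gower_distance(sub)
                assert (dm.data >= 0).all() and (dm.data <= 1).all()
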