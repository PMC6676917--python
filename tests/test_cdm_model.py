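"""Schema manifest, dataset loading, conformance validation, catalog loading."""
import pandas as pd
import pytest

from cdmdq.cdm_model import (CatalogError, CheckInstance, DatasetError,
                             catalog_stats, load_catalog, load_cdm_dataset,
                             load_schema_manifest, make_check_id,
                             serialize_catalog, validate_conformance,
                             write_cdm_dataset)


def test_manifest_shape(manifest):
    assert len(manifest) >= 189
    assert set(f.table_name for f in manifest.fields) == set(manifest.tables)
    # primary keys are non-nullable; value sets only on categoricals
    for f in manifest.fields:
        if f.semantic_type == "primary_key":
            assert not f.nullable
        if f.value_set is not None:
            assert f.semantic_type == "categorical"


def test_dataset_roundtrip_and_typing(clean_small, manifest, tmp_path):
    write_cdm_dataset(clean_small, tmp_path, manifest)
    ds = load_cdm_dataset(tmp_path, manifest, site="rt")
    assert ds.row_counts == clean_small.row_counts
    p = ds.tables["person"]
    assert str(p["time_of_birth"].dtype).startswith("datetime64")
    assert str(p["person_id"].dtype) == "Int64"
    # datetime format contract
    one = tmp_path / "one"
    one.mkdir()
    for t in manifest.tables:
        df = pd.read_csv(tmp_path / f"{t}.csv", nrows=0)
        df.to_csv(one / f"{t}.csv", index=False)
    person_cols = [f.field_name for f in manifest.fields_of("person")]
    row = {c: "" for c in person_cols}
    row.update(person_id="1", time_of_birth="2010-05-01T00:00:00",
               year_of_birth="2010", month_of_birth="5", day_of_birth="1")
    pd.DataFrame([row]).to_csv(one / "person.csv", index=False)
    ds1 = load_cdm_dataset(one, manifest)
    assert ds1.tables["person"]["time_of_birth"].iloc[0] == \
        pd.Timestamp("2010-05-01 00:00:00")


def test_missing_table_file_is_named(manifest, tmp_path):
    with pytest.raises(DatasetError, match="table file absent: person"):
        load_cdm_dataset(tmp_path, manifest)


def test_unparseable_cell_has_coordinates(clean_small, manifest, tmp_path):
    write_cdm_dataset(clean_small, tmp_path, manifest)
    path = tmp_path / "person.csv"
    lines = path.read_text().splitlines()
    header = lines[0].split(",")
    i = header.index("time_of_birth")
    row1 = lines[1].split(",")
    row1[i] = "not-a-date"
    path.write_text("\n".join([lines[0], ",".join(row1)] + lines[2:]) + "\n")
    with pytest.raises(DatasetError, match="person.time_of_birth"):
        load_cdm_dataset(tmp_path, manifest)


def test_conformance_clean_and_violations(clean_small, manifest):
    assert validate_conformance(clean_small, manifest).ok
    ds = clean_small.copy()
    # duplicate primary key
    p = ds.tables["person"]
    p.loc[p.index[1], "person_id"] = p["person_id"].iloc[0]
    rep = validate_conformance(ds, manifest)
    assert len(rep.by_kind("duplicate_key")) == 1
    # dangling required FK
    ds2 = clean_small.copy()
    v = ds2.tables["visit_occurrence"]
    v.loc[v.index[0], "person_id"] = 10 ** 9
    rep2 = validate_conformance(ds2, manifest)
    assert len(rep2.by_kind("dangling_fk")) >= 1


def test_conformance_matches_bruteforce_oracle(manifest):
    """Referential violations agree with a nested-loop scan on a tiny dataset."""
    from cdmdq.synth import SynthProfile, generate_clean
    ds = generate_clean(SynthProfile(n_persons=10, seed=2), manifest)
    v = ds.tables["visit_occurrence"]
    for i in list(v.index[:3]):
        v.loc[i, "person_id"] = 5000 + i
    persons = list(ds.tables["person"]["person_id"])
    expected = sum(1 for pid in v["person_id"] if pid not in persons)
    rep = validate_conformance(ds, manifest)
    got = sum(x.row_count for x in rep.by_kind("dangling_fk")
              if x.table == "visit_occurrence")
    assert got == expected == 3


def test_catalog_invariants(catalog, manifest):
    stats = catalog_stats(catalog)
    # coverage counts partition the manifest's fields
    assert (stats.fields_with_one + stats.fields_with_two
            + stats.fields_with_three_plus + stats.fields_uncovered
            == len(manifest))
    assert sum(stats.category_counts.values()) == stats.total_checks
    # a pair check in the Table-1 style loads as a valid instance
    cid = make_check_id("PreBirth", (("visit_occurrence", "visit_start_date"),
                                     ("person", "time_of_birth")))
    check = catalog.check(cid)
    assert check.lower_threshold == 0 and check.upper_threshold == 0


def test_catalog_serialize_roundtrip(catalog, manifest, tmp_path):
    out = tmp_path / "cat.csv"
    serialize_catalog(catalog, out)
    cat2 = load_catalog(out, manifest)
    assert len(cat2) == len(catalog)
    for c1, c2 in zip(catalog.checks, cat2.checks):
        assert c1.check_id == c2.check_id
        assert c1.lower_threshold == c2.lower_threshold
        assert c1.upper_threshold == c2.upper_threshold
        assert dict(c1.params) == dict(c2.params)


def test_catalog_errors(manifest, tmp_path):
    with pytest.raises(CatalogError):
        CheckInstance(check_id="x", type_alias="MissData",
                      targets=(("person", "gender_concept_id"),),
                      lower_threshold=10, upper_threshold=5)
    bad = tmp_path / "bad.csv"
    bad.write_text("type_alias,targets,lower_threshold,upper_threshold,params\n"
                   "MissData,person.no_such_field,0,10,\n")
    with pytest.raises(CatalogError, match="no_such_field"):
        load_catalog(bad, manifest)
    bad.write_text("type_alias,targets,lower_threshold,upper_threshold,params\n"
                   "NoSuchAlias,person.gender_concept_id,0,10,\n")
    with pytest.raises(CatalogError, match="NoSuchAlias"):
        load_catalog(bad, manifest)


def test_empty_catalog_stats(manifest):
    from cdmdq.cdm_model import Catalog, load_check_types
    cat = Catalog(check_types=load_check_types(), checks=[], manifest=manifest)
    stats = catalog_stats(cat)
    assert stats.total_checks == 0 and stats.check_types == 0
    assert all(v == 0 for v in stats.category_counts.values())
    assert stats.fields_uncovered == len(manifest)
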