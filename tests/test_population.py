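import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riskeq import (
    ValidationError,
    annualize,
    build_design,
    dxgroup_indicator_matrix,
    read_population,
    read_scheme,
    write_population,
    write_scheme,
)
from riskeq.population import drop_empty_columns

from conftest import make_person


@pytest.mark.parametrize(
    "raw,fraction,expected_spending,expected_weight",
    [
        (100.0, 0.25, 400.0, 0.25),  # three insured months quadruple spending
        (500.0, 1.0, 500.0, 1.0),
        (0.0, 0.5, 0.0, 0.5),
    ],
)
def test_annualize(raw, fraction, expected_spending, expected_weight):
    spending, weight = annualize(raw, fraction)
    assert spending == expected_spending
    assert weight == expected_weight
    assert weight * spending == raw  # totals are conserved


@pytest.mark.parametrize("fraction", [0.0, -0.1, 1.2])
def test_annualize_rejects_bad_fraction(fraction):
    with pytest.raises(ValidationError):
        annualize(100.0, fraction)


def test_annualize_rejects_negative_spending():
    with pytest.raises(ValidationError):
        annualize(-1.0, 0.5)


def test_design_matrix_cell_by_cell(tiny_scheme, three_records):
    design = build_design(
        three_records,
        tiny_scheme,
        extra=dxgroup_indicator_matrix(three_records,
                                       tiny_scheme.dxgroup_catalogue),
    )
    # columns: 4 age-gender, 2 pcg (reference "none" omitted), 5 dxgroups
    assert design.columns == (
        "age_gender:M|1-17", "age_gender:M|18+",
        "age_gender:F|1-17", "age_gender:F|18+",
        "pcg:mild", "pcg:severe",
        "dx:dx1", "dx:dx2", "dx:dx3", "dx:dx4", "dx:dx5",
    )
    expected = np.array(
        [
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0],
            [0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 0],
        ],
        dtype=float,
    )
    np.testing.assert_array_equal(design.toarray(), expected)
    np.testing.assert_array_equal(design.y, [1000.0, 2400.0, 800.0])
    np.testing.assert_array_equal(design.w, [1.0, 0.5, 0.25])


def test_reference_person_has_only_age_gender_column(tiny_scheme):
    rec = make_person()
    design = build_design([rec], tiny_scheme)
    row = design.toarray()[0]
    assert row.sum() == 1.0
    assert row[design.column_index("age_gender:M|18+")] == 1.0


def test_age_gender_block_partitions_rows(small_population):
    config, records, _ = small_population
    scheme = config.scheme()
    design = build_design(records[:2000], scheme, validate=False)
    block = [j for j, c in enumerate(design.columns)
             if c.startswith("age_gender:")]
    rowsums = np.asarray(design.matrix[:, block].sum(axis=1)).ravel()
    np.testing.assert_array_equal(rowsums, np.ones(2000))
    # weighted column total over the block equals total weighted persons
    total = float(design.matrix[:, block].T @ design.w @ np.ones(len(block)))
    assert total == pytest.approx(design.w.sum())


def test_build_design_deterministic(tiny_scheme, three_records):
    d1 = build_design(three_records, tiny_scheme)
    d2 = build_design(three_records, tiny_scheme)
    assert d1.columns == d2.columns
    assert (d1.matrix != d2.matrix).nnz == 0


def test_multi_qualification_count_column(tiny_scheme, three_records):
    # two of person b's dxgroups mapped to the same DCG column give count 2
    counts = np.array([[0.0], [2.0], [1.0]])
    design = build_design(three_records, tiny_scheme, extra=(["dcg:D1"], counts))
    assert design.toarray()[1, design.column_index("dcg:D1")] == 2.0


def test_drop_empty_columns(tiny_scheme, three_records):
    labels, mat = dxgroup_indicator_matrix(three_records,
                                           tiny_scheme.dxgroup_catalogue)
    kept, filtered = drop_empty_columns(labels, mat)
    assert kept == ["dx:dx1", "dx:dx3"]
    assert filtered.shape == (3, 2)


def test_population_round_trip(tmp_path, tiny_scheme, three_records):
    path = tmp_path / "pop.csv"
    write_population(three_records, path, tiny_scheme)
    back = read_population(path, tiny_scheme)
    assert back == three_records


def test_scheme_round_trip(tmp_path, tiny_scheme):
    path = tmp_path / "scheme.json"
    write_scheme(tiny_scheme, path)
    assert read_scheme(path) == tiny_scheme


def test_read_reports_row_number_for_bad_fraction(tmp_path, tiny_scheme):
    path = tmp_path / "pop.csv"
    write_population(
        [make_person("a"), make_person("b")], path, tiny_scheme
    )
    text = path.read_text().replace("b,1.0", "b,1.2")
    path.write_text(text)
    with pytest.raises(ValidationError, match="row 2"):
        read_population(path, tiny_scheme)


def test_unregistered_dxgroup_is_listed(tmp_path, tiny_scheme):
    path = tmp_path / "pop.csv"
    write_population([make_person("a", dxgroups=("dx1",))], path, tiny_scheme)
    path.write_text(path.read_text().replace("dx1", "dx99"))
    with pytest.raises(ValidationError, match="dx99"):
        read_population(path, tiny_scheme)


def test_duplicate_person_id_rejected(tmp_path, tiny_scheme):
    path = tmp_path / "pop.csv"
    write_population([make_person("a"), make_person("a")], path, tiny_scheme)
    with pytest.raises(ValidationError, match="duplicate"):
        read_population(path, tiny_scheme)


def test_missing_column_rejected(tmp_path, tiny_scheme):
    path = tmp_path / "pop.csv"
    write_population([make_person("a")], path, tiny_scheme)
    text = path.read_text().replace("pcg", "not_pcg")
    path.write_text(text)
    with pytest.raises(ValidationError, match="pcg"):
        read_population(path, tiny_scheme)


def test_age_zero_rejected(tiny_scheme):
    rec = make_person(band="0")
    with pytest.raises(ValidationError, match="aged 0"):
        build_design([rec], tiny_scheme)


def test_missing_classification_rejected(tiny_scheme):
    rec = make_person()
    object.__setattr__(rec, "adjuster_flags", {})
    with pytest.raises(ValidationError, match="pcg"):
        build_design([rec], tiny_scheme)


_ids = st.text(alphabet="abcdefgh", min_size=1, max_size=6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(0.01, 1.0), st.floats(0, 1e5),
            st.sampled_from(["1-17", "18+"]), st.sampled_from(["M", "F"]),
            st.sampled_from(["none", "mild", "severe"]),
            st.sets(st.sampled_from(["dx1", "dx2", "dx3", "dx4", "dx5"]),
                    max_size=3),
        ),
        min_size=1, max_size=8,
    )
)
def test_round_trip_random_records(tmp_path_factory, tiny_scheme, data):
    records = [
        make_person(f"p{i}", round(frac, 6), round(spend, 6), band, gender,
                    pcg, dx)
        for i, (frac, spend, band, gender, pcg, dx) in enumerate(data)
    ]
    path = tmp_path_factory.mktemp("roundtrip") / "pop.csv"
    write_population(records, path, tiny_scheme)
    assert read_population(path, tiny_scheme) == records
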