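import pytest

from riskeq import (
    Classification,
    GeneratorConfig,
    PersonRecord,
    RiskAdjusterScheme,
    generate_population,
)


@pytest.fixture(scope="session")
def tiny_scheme() -> RiskAdjusterScheme:
    """Two age bands x two genders, one pharmacy block, five dxgroups."""
    return RiskAdjusterScheme(
        (
            Classification(
                "age_gender",
                ("M|1-17", "M|18+", "F|1-17", "F|18+"),
                reference=None,
            ),
            Classification("pcg", ("mild", "severe")),
        ),
        dxgroup_catalogue=("dx1", "dx2", "dx3", "dx4", "dx5"),
    )


def make_person(pid="p1", fraction=1.0, spending=100.0, band="18+",
                gender="M", pcg="none", dxgroups=(), conditions=()):
    return PersonRecord(
        person_id=pid,
        insured_fraction=fraction,
        spending_annualized=spending,
        age_band=band,
        gender=gender,
        adjuster_flags={"pcg": pcg},
        dxgroups=frozenset(dxgroups),
        conditions=frozenset(conditions),
    )


@pytest.fixture
def three_records():
    """Hand-built toy population used for cell-by-cell oracles."""
    return [
        make_person("a", 1.0, 1000.0, "1-17", "M"),
        make_person("b", 0.5, 2400.0, "18+", "F", pcg="severe",
                    dxgroups=("dx1", "dx3")),
        make_person("c", 0.25, 800.0, "18+", "M", pcg="mild",
                    dxgroups=("dx3",)),
    ]


@pytest.fixture(scope="session")
def small_population():
    """A modest generated population shared by read-only tests."""
    config = GeneratorConfig(n_persons=20_000, seed=5)
    records, truth = generate_population(config)
    return config, records, truth
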