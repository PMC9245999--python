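import io

import pytest
from hypothesis import HealthCheck, settings

import ystrpop as y

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def agcu_panel():
    return y.load_agcu_y30_panel()


@pytest.fixture
def toy_panel():
    return [
        y.LocusDef("DYS391", 1),
        y.LocusDef("DYS390", 1),
        y.LocusDef("DYS385a/b", 2),
    ]


def make_table(toy_panel, rows):
    """rows: list of (sample, pop, [cell strings per locus])."""
    buf = io.StringIO()
    buf.write("SampleID\tPopulationID\t" + "\t".join(l.name for l in toy_panel) + "\n")
    for sid, pop, cells in rows:
        buf.write("\t".join([sid, pop, *cells]) + "\n")
    buf.seek(0)
    return y.read_haplotype_table(buf, toy_panel)


@pytest.fixture
def toy_table(toy_panel):
    return make_table(
        toy_panel,
        [
            ("S1", "popA", ["10", "22", "13,14"]),
            ("S2", "popA", ["10", "23", "14,13"]),
            ("S3", "popB", ["11", "22", "13,17.2"]),
            ("S4", "popB", ["12", "24", "15,16"]),
        ],
    )
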