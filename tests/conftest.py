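import pytest

from plastomarker.allele_profiler import recruit_reads, tabulate_alleles
from plastomarker.synthetic_data import make_cz11_fixture


@pytest.fixture(scope="session")
def cz11_fixture():
    """Fragment, per-species read sets and expected totals for the published
    cz11 allele table embedded in a synthetic 600 bp context."""
    return make_cz11_fixture()


@pytest.fixture(scope="session")
def cz11_tables(cz11_fixture):
    """Allele tables profiled from the cz11 fixture (computed once)."""
    fragment, readsets, expected = cz11_fixture
    tables = {}
    for label, rs in readsets.items():
        recruited = recruit_reads(fragment, rs)
        tables[label] = tabulate_alleles(recruited, fragment)
    return tables
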