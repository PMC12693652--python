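import pytest

from cambd.motifs import dedup_windows
from cambd.reference import (
    load_codon_grid,
    load_ddg_table,
    load_iptm_table,
    load_isoform_windows,
    load_substitution_plan,
)

#: printed per-position nucleotide-conservation star counts for the
#: 18-codon window grid (***, **, *, blank -> 3, 2, 1, 0)
PRINTED_STARS = (3, 2, 1, 2, 3, 2, 1, 2, 2, 2, 3, 2, 0, 2, 1, 1, 1, 2)


@pytest.fixture(scope="session")
def codon_grid():
    return load_codon_grid()


@pytest.fixture(scope="session")
def isoform_windows():
    return load_isoform_windows()


@pytest.fixture(scope="session")
def window_groups(isoform_windows):
    return dedup_windows(isoform_windows)


@pytest.fixture(scope="session")
def substitution_plan():
    return load_substitution_plan()


@pytest.fixture(scope="session")
def iptm_table():
    return load_iptm_table()


@pytest.fixture(scope="session")
def ddg_table():
    return load_ddg_table()
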