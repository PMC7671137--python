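import math
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from chaenopsid import characters, phylo
from chaenopsid.parsimony import TipStateAssignment


@pytest.fixture(scope="session")
def catalogue():
    return characters.load_catalog()


@pytest.fixture(scope="session")
def counts_df():
    return characters.read_count_table()


@pytest.fixture(scope="session")
def profiles(counts_df):
    return characters.profiles_from_counts(counts_df)


@pytest.fixture(scope="session")
def composite():
    return phylo.assemble_composite()


@pytest.fixture(scope="session")
def jaw_matrix(catalogue):
    return characters.read_matrix(
        characters.fixture_path("jaw_states.tsv"), catalogue
    )


@pytest.fixture(scope="session")
def jaw_assignments(catalogue, jaw_matrix):
    alphabet = catalogue["M-IIb"].state_labels
    male = TipStateAssignment(
        jaw_matrix.sex_assignment("male", "M-IIb"), alphabet=alphabet
    )
    female = TipStateAssignment(
        jaw_matrix.sex_assignment("female", "M-IIb"), alphabet=alphabet
    )
    return male, female


def matches_printed(computed: float, printed: float, tol: float = 0.05) -> bool:
    """Match a recomputed statistic against a one-decimal printed value.

    The survey's print rounding is inconsistent (some cells round half up,
    at least one truncates), so accept either an absolute difference of at
    most ``tol`` or an exact truncation to the printed precision.
    """
    if math.isnan(printed) and computed is None:
        return True
    if computed is None or math.isnan(printed):
        return False
    if abs(computed - printed) <= tol + 1e-12:
        return True
    return math.floor(computed * 10) / 10 == round(printed, 1)
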