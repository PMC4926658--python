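import pytest

from lepiprime import Alignment, load_bundled_primers, load_marker_panel


@pytest.fixture(scope="session")
def primer_table():
    return load_bundled_primers()


@pytest.fixture(scope="session")
def marker_panel():
    """All 38 rows of the bundled marker-statistics panel."""
    return load_marker_panel()


@pytest.fixture
def toy_alignment():
    """4-taxon, 10-column alignment with a hand-counted site-class breakdown.

    Columns: 4 conserved, 3 singleton-variable, 3 parsimony-informative.
    """
    return Alignment(
        ("t1", "t2", "t3", "t4"),
        (
            "ACGTACGTAC",
            "ACGTTCGTAC",
            "ACTTACCAAC",
            "ACTAACCAGC",
        ),
    )


@pytest.fixture
def conserved_alignment():
    row = ("ACGT" * 150)
    return Alignment(("a", "b", "c"), (row, row, row))
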