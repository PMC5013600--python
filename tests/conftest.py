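import pytest

from stratodec import Area, Geography, Stratum, read_newick


@pytest.fixture
def geo2():
    """Two areas X, Y; single all-allowing stratum."""
    return Geography(areas=[Area(0, "X"), Area(1, "Y")])


@pytest.fixture
def geo3():
    """Three areas X, Y, Z; single all-allowing stratum."""
    return Geography(areas=[Area(0, "X"), Area(1, "Y"), Area(2, "Z")])


@pytest.fixture
def geo3_strat():
    """Three areas; area X (bit 0) disallowed at ages 1.5 Myr and older."""
    return Geography(
        areas=[Area(0, "X"), Area(1, "Y"), Area(2, "Z")],
        strata=[Stratum(1.5, 0.0, 0b111), Stratum(float("inf"), 1.5, 0b110)],
    )


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")
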