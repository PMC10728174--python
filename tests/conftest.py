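import pytest

from imutseq import default_pool, subset_pool


@pytest.fixture(scope="session")
def pool():
    """The packaged 25-locus default panel."""
    return default_pool()


@pytest.fixture(scope="session")
def small_pool(pool):
    """A 6-locus slice of the panel (2 HR, 2 NHEJ, 2 UNCUT) for heavy runs."""
    return subset_pool(pool, ["HR01", "HR02", "NHEJ01", "NHEJ02", "UNCUT01", "UNCUT02"])
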