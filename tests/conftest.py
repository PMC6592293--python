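import pytest

from pancyst.clamp import ClampAssay, ClampTarget
from pancyst.fixture import load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 46-case surgical reference cohort."""
    return load_table1()


@pytest.fixture()
def assay():
    """A clamp assay with a clean 3-cycles-per-decade control ladder."""
    return ClampAssay(
        target=ClampTarget.KRAS_12_13,
        ct_with_clamp=30.0,
        ct_without_clamp=28.0,
        controls={100.0: 2.0, 10.0: 5.0, 1.0: 8.0, 0.0: 13.0},
    )
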