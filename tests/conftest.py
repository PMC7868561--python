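import pytest

from circtah.simulate import SyntheticConfig, generate_dataset
from circtah.worked_example import generate_worked_example


@pytest.fixture(scope="session")
def worked_ds():
    return generate_worked_example()


@pytest.fixture(scope="session")
def ds_default():
    """Default-scale dataset (about 400 circRNAs) with genome sequence."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def ds_noisefree():
    return generate_dataset(
        SyntheticConfig(seed=7, noise=0.0, generate_sequence=False)
    )


@pytest.fixture(scope="session")
def ds_large():
    """About 2,000 circRNAs, stochastic counts, no genome sequence."""
    return generate_dataset(
        SyntheticConfig(seed=7, n_genes=1050, generate_sequence=False)
    )


@pytest.fixture(scope="session")
def ds_large_noisefree():
    return generate_dataset(
        SyntheticConfig(seed=7, n_genes=1050, noise=0.0, generate_sequence=False)
    )


@pytest.fixture(scope="session")
def ds_multiline():
    """Four cell lines for the cell-specificity analyses."""
    return generate_dataset(
        SyntheticConfig(
            seed=19,
            cell_lines=("CL1", "CL2", "CL3", "CL4"),
            generate_sequence=False,
        )
    )
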