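import numpy as np
import pandas as pd
import pytest

from conjfdr.simulate import make_worked_fixture, simulate_pair, SimConfig
from conjfdr.sumstats import harmonize_pair


@pytest.fixture(scope="session")
def worked_bundle():
    return make_worked_fixture()


@pytest.fixture(scope="session")
def worked_pair(worked_bundle):
    return harmonize_pair(worked_bundle.sumstats1, worked_bundle.sumstats2)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest simulated bundle shared by read-only tests."""
    return simulate_pair(SimConfig(n_snps=2000, n_blocks=400, seed=11))


def write_sumstats(path, records, header="SNP CHR BP A1 A2 Z P"):
    """Write a whitespace-delimited sumstats file from row tuples."""
    cols = header.split()
    df = pd.DataFrame(records, columns=cols)
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def sumstats_writer(tmp_path):
    def _write(name, records, header="SNP CHR BP A1 A2 Z P"):
        return write_sumstats(tmp_path / name, records, header)

    return _write
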