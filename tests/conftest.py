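import numpy as np
import pytest
from hypothesis import settings

from alkscan.model import ALK, FW, GenotypeTable, PopulationMap
from alkscan.simulate import SimConfig, generate_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic fixture set (seed 1), shared across tests."""
    return generate_fixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The default fixture written to disk once per session."""
    out = tmp_path_factory.mktemp("fixture")
    generate_fixture(SimConfig(seed=1), out)
    return out


def make_table(dosage, pos=None, chrom="chr1", n_alk=None):
    """GenotypeTable from a raw dosage matrix; first n_alk columns are ALK."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    n_alk = n_alk if n_alk is not None else n_samples // 2
    samples = [f"A{i}" for i in range(n_alk)] + \
              [f"F{i}" for i in range(n_samples - n_alk)]
    popmap = PopulationMap({s: (ALK if s.startswith("A") else FW)
                            for s in samples})
    pos = np.asarray(pos if pos is not None else np.arange(n_sites),
                     dtype=np.int64)
    return GenotypeTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        is_snp=np.ones(n_sites, dtype=bool),
        dosage=dosage,
        samples=samples,
        popmap=popmap,
    )
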