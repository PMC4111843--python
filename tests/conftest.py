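import numpy as np
import pytest

from mhcbench.io import (
    BindingCollection,
    Dataset,
    DatasetKey,
    Measurement,
    build_collection,
)


def make_dataset(peptides, ic50s, allele="HLA-A*02:01", species="human"):
    """Handy constructor for a Dataset from parallel peptide/IC50 lists."""
    length = len(peptides[0])
    ms = [
        Measurement(species, allele, length, p, "exact", float(x))
        for p, x in zip(peptides, ic50s)
    ]
    return Dataset(DatasetKey(allele, length), ms)


def make_collection(datasets, label="test"):
    ms = [m for ds in datasets for m in ds.measurements]
    return build_collection(ms, label)


def random_peptides(rng, n, length=9, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """n unique random peptides."""
    out = set()
    letters = np.array(list(alphabet))
    while len(out) < n:
        out.add("".join(rng.choice(letters, size=length)))
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240714)


@pytest.fixture
def small_dataset(rng):
    peps = random_peptides(rng, 50)
    ic50s = 10 ** rng.uniform(0, 5, size=50)
    return make_dataset(peps, ic50s)
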