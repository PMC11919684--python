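import numpy as np
import pytest

from compss.fixtures import FamilySpec, make_family, make_structure


@pytest.fixture(scope="session")
def family():
    """Small synthetic family with injected defects, fixed seed."""
    return make_family(FamilySpec(length=60, n_train=8, n_test=6,
                                  n_candidates=30, defect_fraction=0.5,
                                  seed=11))


@pytest.fixture(scope="session")
def clean_family():
    """Family with no injected defects."""
    return make_family(FamilySpec(length=50, n_train=6, n_test=5,
                                  n_candidates=12, defect_fraction=0.0,
                                  seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def helix():
    return make_structure("MKVLDAGHERSTWYNQCIFP", confidence_profile=90.0)


@pytest.fixture
def toy_fasta(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(">a first\nMKV\n>b\nMKVL\nDAG\n")
    return p
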