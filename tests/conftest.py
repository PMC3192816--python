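import numpy as np
import pytest

import ribotraffic as rt
from ribotraffic.core import MRNASpecies, TranslationSystem
from ribotraffic.io import packaged_path


@pytest.fixture(scope="session")
def table():
    return rt.load_packaged_trna_table()


@pytest.fixture(scope="session")
def code():
    return rt.load_packaged_codon_map()


@pytest.fixture(scope="session")
def packaged_orfs(code):
    return rt.read_orf_fasta(packaged_path("synthetic_orfs.fasta"), code)


@pytest.fixture(scope="session")
def mrna_a_system(table, packaged_orfs):
    """45 copies of the 110-codon mRNA A-like fixture, yeast-proportioned
    tRNA pools, initiation well above the predicted critical rate."""
    seq = next(s for s in packaged_orfs if s.name == "YDR382W_synthetic")
    mrnas = [seq.to_mrna(45)]
    cfg = rt.SystemConfig.from_defaults(sum(m.copy_number * m.length for m in mrnas))
    return rt.build_system(rt.load_packaged_trna_table(), mrnas, cfg, alpha=1.0)


def uniform_system(L=100, m=20, T_tot=2000, k=10.0, V=100.0, K=3.0, alpha=0.02,
                   beta=50.0, w=9, infinite_recharge=False):
    """Mono-codon validation system: k = kappa*T at full charging."""
    mrna = MRNASpecies("uniform", np.full(L, 1), m)
    return TranslationSystem(
        mrnas=[mrna], T=[T_tot], V=[V], K=[K], kappa=k / T_tot, alpha=alpha,
        beta=beta, w=w, infinite_recharge=infinite_recharge, labels=["t1"],
    )


@pytest.fixture
def mono():
    return uniform_system
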