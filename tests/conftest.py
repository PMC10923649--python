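import pytest

from plastrec.recombinator import enumerate_conformers
from plastrec.synthetic_data import ToySpec, make_toy_plastome, splice_conformer


@pytest.fixture(scope="session")
def toy_small():
    """Desk-scale toy matching the worked partition example
    (|A| 111, |B| 20, |C| 69, arm 11, SSC 150, IR 200)."""
    return make_toy_plastome(ToySpec(seed=5))


@pytest.fixture(scope="session")
def toy_mid():
    """Larger toy for junction and depth work (regions comfortably exceed
    read length and flanks)."""
    spec = ToySpec(len_a=900, len_b=60, len_c=700, arm_len=11,
                   len_ssc=900, len_ir=400, seed=9, name="midtoy")
    return make_toy_plastome(spec)


@pytest.fixture(scope="session")
def toy_mid_conformers(toy_mid):
    return enumerate_conformers(toy_mid.structure, toy_mid.partition,
                                with_metrics=False)


@pytest.fixture(scope="session")
def toy_mid_atype(toy_mid):
    return splice_conformer(toy_mid.structure.sequence.residues,
                            toy_mid.partition, "A-type",
                            ir_len=toy_mid.spec.len_ir)
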