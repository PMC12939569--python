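import pytest

from collapep import ProteinChain, ReferenceDB, ReferencePeptide, compile_rules


@pytest.fixture(scope="session")
def trypsin_rule():
    table = compile_rules(
        {"trypsin": {"ec": "3.4.21.4", "specs": [{"p1": "KR"}], "exceptions": [{"p1prime": "P"}]}}
    )
    return table["trypsin"]


@pytest.fixture(scope="session")
def glu_c_rule():
    # V8 protease: cleaves after E
    return compile_rules({"glu-c": {"specs": [{"p1": "E"}]}})["glu-c"]


@pytest.fixture
def small_db():
    return ReferenceDB(
        [
            ReferencePeptide("AK", "ACE inhibitor"),
            ReferencePeptide("AV", "ACE inhibitor"),
            ReferencePeptide("VY", "ACE inhibitor", ic50_um=5.2),
            ReferencePeptide("GPL", "DPP-IV inhibitor"),
        ]
    )


@pytest.fixture
def collagen_chain():
    return ProteinChain(id="a1", residues="GAPGPPGAVGAVGPKGAR")
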