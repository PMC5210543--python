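import pytest
from hypothesis import settings

from tdscore.ontology import load_ontology

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

ASTHMA_TSV = """\
child_id\tparent_id\tchild_label\tis_root_flag
EFO:0009687\t\trespiratory system disease\t1
EFO:0000270\tEFO:0009687\tasthma\t0
EFO:0004591\tEFO:0000270\tchildhood onset asthma\t0
"""


@pytest.fixture
def asthma_ontology(tmp_path):
    """Three-term subclass chain: childhood onset asthma < asthma <
    respiratory system disease (a therapeutic-area root)."""
    path = tmp_path / "asthma.tsv"
    path.write_text(ASTHMA_TSV)
    return load_ontology(path)


def make_record(**overrides):
    """A well-formed known-drug evidence record, overridable per test."""
    raw = {
        "evidence_id": "ev:1",
        "target_id": "ENSG00000000001",
        "disease_id": "EFO:0000270",
        "datasource": "chembl",
        "datatype": "drugs",
        "payload": {"max_phase": 4},
    }
    raw.update(overrides)
    return raw
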