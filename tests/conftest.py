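import pytest

from mlnqa.lexicon import load_default_diagnosis_lexicon, load_default_site_lexicon
from mlnqa.report_io import ReportRecord


@pytest.fixture(scope="session")
def dx_lex():
    return load_default_diagnosis_lexicon()


@pytest.fixture(scope="session")
def site_lex():
    return load_default_site_lexicon()


def make_record(**kw) -> ReportRecord:
    defaults = dict(
        specimen_id="SP000001",
        patient_pseudo_id="PT000001",
        sps_id="S1",
        pathologist_id="P1",
        received_date="2015-06-01",
        source_text="EBUS FNA lymph node, station 7.",
        diagnosis_text="Benign lymphocytes.",
        consult_text="",
        addenda=[],
    )
    defaults.update(kw)
    return ReportRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record
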