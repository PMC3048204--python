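import numpy as np
import pytest

from roma_dx.cohort import (
    Cohort,
    DiagnosisClass,
    FigoStage,
    Grade,
    HistologyGroup,
    MenopausalStatus,
    PathologyLabel,
    PatientRecord,
)
from roma_dx import synth


def make_record(
    id="P001",
    age=50.0,
    status=MenopausalStatus.POST,
    ca125=30.0,
    he4=60.0,
    diagnosis=DiagnosisClass.BENIGN,
    histology=HistologyGroup.CYSTADENOMA_FIBROMA,
    figo=FigoStage.NOT_APPLICABLE,
    grade=Grade.NOT_APPLICABLE,
    **flags,
):
    return PatientRecord(
        id=id,
        age=age,
        menopausal_status=status,
        ca125=ca125,
        he4=he4,
        diagnosis=diagnosis,
        pathology=PathologyLabel(histology, figo, grade),
        **flags,
    )


@pytest.fixture
def small_cohort():
    """Five subjects: 3 benign (2 pre, 1 post), 2 malignant EOC (post)."""
    return Cohort(
        [
            make_record(id="B1", status=MenopausalStatus.PRE, ca125=12.0, he4=40.0),
            make_record(id="B2", status=MenopausalStatus.PRE, ca125=20.0, he4=50.0,
                        histology=HistologyGroup.ENDOMETRIOSIS),
            make_record(id="B3", status=MenopausalStatus.POST, ca125=15.0, he4=55.0),
            make_record(id="M1", status=MenopausalStatus.POST, ca125=500.0, he4=250.0,
                        diagnosis=DiagnosisClass.MALIGNANT, histology=HistologyGroup.EOC,
                        figo=FigoStage.III, grade=Grade.G3),
            make_record(id="M2", status=MenopausalStatus.POST, ca125=90.0, he4=120.0,
                        diagnosis=DiagnosisClass.MALIGNANT, histology=HistologyGroup.METASTATIC),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort at seed 42 (228 benign / 161 malignant)."""
    return synth.generate_cohort(synth.default_config(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
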