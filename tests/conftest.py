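from datetime import date

import numpy as np
import pytest

from vfstack.grid import build_grid
from vfstack.normative import VFExam, annotate_exam, synthetic_reference


@pytest.fixture(scope="session")
def grid():
    return build_grid("OD")


@pytest.fixture(scope="session")
def norm(grid):
    return synthetic_reference(grid)


def make_exam(norm, td=None, age=60.0, patient_id="P1", eye="OD",
              test_date=date(2020, 1, 1), fpr=0.05, label=None, **kw):
    """Exam with a prescribed TD map (defaults to a normal field)."""
    td = np.zeros(52) if td is None else np.asarray(td, dtype=float)
    sens = np.maximum(norm.expected_sensitivity(age) + td, 0.0)
    exam = VFExam(patient_id=patient_id, eye=eye, test_date=test_date,
                  age=age, gender=0, race=0, follow_up=1.0, fpr=fpr,
                  sensitivities=sens, label=label, **kw)
    return annotate_exam(exam, norm)


@pytest.fixture()
def exam_factory(norm):
    def _make(**kw):
        return make_exam(norm, **kw)
    return _make
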