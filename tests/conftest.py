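import numpy as np
import pytest

import fibrotex as fx
from fibrotex.pipeline import subject_feature_table


@pytest.fixture(scope="session")
def cohort46():
    """A full 46-subject synthetic cohort with its per-subject feature table.

    Session-scoped: feature extraction over 230 ROIs is the expensive step
    and several statistical tests share it.
    """
    records = fx.generate_cohort(n_subjects=46, seed=11)
    table = subject_feature_table(records)
    return records, table


@pytest.fixture(scope="session")
def reticular_stack():
    """One standardized transform stack of a clearly fibrotic (severity 3) ROI."""
    roi = fx.generate_reticular_roi(fx.SyntheticParams(severity=3.0, seed=5))
    return fx.build_transform_stack(roi)
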