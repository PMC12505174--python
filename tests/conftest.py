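import numpy as np
import pytest

from glomorph.mask_io import Calibration
from glomorph.phantom_generator import generate_cohort
from glomorph.pipeline import featurize_mask_set
from glomorph.subtype_classifier import feature_matrix

COHORT_N = 700
COHORT_SEED = 11


@pytest.fixture
def calib():
    return Calibration(nm_per_pixel=2.0, image_width=256, image_height=256)


@pytest.fixture(scope="session")
def measured_cohort():
    """Balanced 7-class phantom cohort, measured end to end (expensive; shared).

    Returns (feature matrix X, labels y, truths, records).
    """
    cohort = generate_cohort(COHORT_N, seed=COHORT_SEED)
    rows, labels, truths, recs = [], [], [], []
    for ms, tr in cohort:
        rec, feats = featurize_mask_set(ms)
        rows.append(feats)
        labels.append(tr.subtype)
        truths.append(tr)
        recs.append(rec)
    X = feature_matrix(rows)
    y = np.asarray(labels)
    return X, y, truths, recs
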