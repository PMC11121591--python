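import numpy as np
import pandas as pd
import pytest

from radgenmap.genomics import default_panel, score_genes
from radgenmap.synthetic import (
    CohortConfig,
    PlantedLink,
    TextureParams,
    generate_cohort,
)
from radgenmap.texture import RoiImage, extract_features


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_roi(rng, size=8, levels=4):
    """Small random quantised ROI with a random (non-trivial) mask."""
    q = rng.integers(1, levels + 1, size=(size, size))
    mask = rng.random((size, size)) < 0.8
    while mask.sum() < 4:
        mask = rng.random((size, size)) < 0.8
    q = q * mask
    return q


@pytest.fixture(scope="session")
def small_cohort():
    """15-patient cohort mirroring the 3 x 5 study structure, tiny images."""
    cfg = CohortConfig(n_per_group=5, image_size=32, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_tables(small_cohort):
    """Feature table, gene scores and metadata derived from the small cohort."""
    images = [img for p in small_cohort for img in p.images.values()]
    features = extract_features(images)
    panel = default_panel()
    segments = [s for p in small_cohort for s in p.segments]
    scores = score_genes(segments, panel, sample_ids=[p.patient_id for p in small_cohort])
    metadata = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in small_cohort],
            "grade_group": [p.grade_group for p in small_cohort],
            "qc_score": [p.qc_score for p in small_cohort],
        }
    )
    return features, scores, metadata
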