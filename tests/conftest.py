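import numpy as np
import pandas as pd
import pytest

from usradiomics.features import ExtractionConfig, RadiomicsExtractor
from usradiomics.synthetic import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_roi(rng, size=8, n_levels=6):
    """Random small discretized ROI (levels 1..n_levels, non-trivial mask)."""
    from usradiomics.datatypes import DiscretizedROI

    while True:
        mask = rng.random((size, size)) < 0.7
        if mask.sum() >= 4:
            break
    levels = np.zeros((size, size), dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedROI(levels=levels, mask=mask, n_levels=int(levels.max()), bin_width=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """22-lesion cohort with 3 readers on the first 8 lesions (session cache)."""
    records, truth = generate_cohort(
        12, 10, seed=77, n_readers=3, reproducibility_subset=8
    )
    return records, truth


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    """Features of the small cohort on a reduced (fast) image bank."""
    records, _ = small_cohort
    config = ExtractionConfig(log_sigmas=(2.0,), wavelet=None)
    extractor = RadiomicsExtractor(config)
    table = extractor.transform(records)
    table["split"] = "train"
    return table
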