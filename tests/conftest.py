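import numpy as np
import pytest

from kernrad.annotate import segment_subject
from kernrad.features import extract_table
from kernrad.phantom import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """24-subject phantom cohort with segmented patches and the truth table."""
    cfg = PhantomConfig(n_subjects=24, seed=11)
    images, truth = generate_cohort(cfg)
    patches, masks = [], []
    for im in images:
        patch, mask = segment_subject(im.annotated, im.original,
                                      source_id=im.subject_id)
        patches.append(patch.pixels)
        masks.append(mask)
    return {"config": cfg, "images": images, "truth": truth,
            "patches": patches, "masks": masks}


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """670-column feature table for the 24-subject cohort."""
    return extract_table(
        small_cohort["patches"], small_cohort["masks"],
        index=small_cohort["truth"]["subject_id"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def disk_mask():
    """Digital disk of radius 20 inside a 64x64 grid."""
    yy, xx = np.mgrid[0:64, 0:64]
    return (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
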