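import numpy as np
import pytest

from testaclust import preprocess as pp
from testaclust import synthetic as syn
from testaclust.pipeline import planted_study_config, run_pipeline


@pytest.fixture(scope="session")
def planted_images():
    """60 images: 20 per class of the well-separated triple, master seed 1."""
    from testaclust._seeds import derive_seed

    spec = [(wc, 20, ov) for wc, _, ov in syn.well_separated_triple()]
    images = syn.generate_dataset(spec, seed=derive_seed(1, "generate"))
    return images


@pytest.fixture(scope="session")
def planted_truth(planted_images):
    return [img.truth.label for img in planted_images]


@pytest.fixture(scope="session")
def planted_features(planted_images):
    """Feature matrices for the planted set under the study's 8x8 pixel grid."""
    config = pp.PreprocessConfig(downsample_side=8)
    reps = [pp.compute_representations(img, config) for img in planted_images]
    return {rep: pp.feature_matrix(reps, rep, config)
            for rep in ("grayscale", "threshold", "colored")}


@pytest.fixture(scope="session")
def planted_report():
    """One full pipeline run on the planted study (master seed 1)."""
    return run_pipeline(planted_study_config(master_seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
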