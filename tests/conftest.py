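import warnings

import numpy as np
import pytest

import pombex as px

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def wildtype_scene():
    """Standard short-rod scene used across tests (fixed seed)."""
    return px.generate_scene(px.scene_preset("wildtype", seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """Small, quick scene for unit-level checks."""
    return px.generate_scene(px.SceneSpec(shape=(256, 256), n_cells=8,
                                          seed=5))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Piecewise-constant scene (no noise, no texture)."""
    return px.generate_scene(px.SceneSpec(shape=(256, 256), n_cells=6,
                                          noise_sigma=0.0, seed=2))


@pytest.fixture(scope="session")
def validation_model():
    """Validator trained once on the synthetic labelled set."""
    labeled = px.make_validation_training_set(seed=0)
    return px.train_validators(labeled, seed=0)


@pytest.fixture(scope="session")
def labeled_training_set():
    return px.make_validation_training_set(seed=0)


def run_pipeline_stages(scene, config=None):
    """Run preprocessing + correction manually, returning the corrected
    image and region statistics (helper for stage-level tests)."""
    from pombex import focus as F
    from pombex import preprocess as P
    from pombex.config import PipelineConfig

    config = config or PipelineConfig()
    trans = P.shading_correct(scene.images.trans, config.shading_radius)
    background = P.detect_background(trans)
    fluor = [P.shading_correct(f, config.shading_radius)
             for f in scene.images.fluor]
    nuclei, centroids = P.detect_nuclei(fluor, config.min_nucleus_area)
    masks = P.build_region_masks(trans, background, nuclei, centroids)
    mu_n, mu_b = P.region_means(trans, masks)
    delta = config.resolve_target_contrast(np.ptp(trans))
    corrected = F.global_contrast_adjust(trans, mu_n, mu_b, delta)
    mu_n, mu_b = P.region_means(corrected, masks)
    return corrected, masks, mu_n, mu_b
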