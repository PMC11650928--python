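import numpy as np
import pytest

from patchid.synthetic_sharks import (
    IndividualSpec,
    RenderConfig,
    make_population,
    render,
    write_dataset,
)

# small geometry used across tests: body must fit a 160x160 frame
TEST_BODY_LENGTH = 100.0
TEST_IMAGE_SIZE = (160, 160)


@pytest.fixture
def adult_spec():
    return IndividualSpec(
        shark_id="HO_900",
        life_stage="adult",
        base_seed=42,
        n_spots=20,
        spot_radius_range=(2.5, 4.0),
        body_length=TEST_BODY_LENGTH,
        drift_rate=0.0,
    )


@pytest.fixture
def neonate_spec():
    return IndividualSpec(
        shark_id="HO_901",
        life_stage="neonate",
        base_seed=43,
        n_spots=20,
        spot_radius_range=(1.8, 2.6),
        body_length=TEST_BODY_LENGTH,
        drift_rate=0.08,
    )


@pytest.fixture
def render_cfg():
    return RenderConfig(image_size=TEST_IMAGE_SIZE, view_angle=8.0, gamma=1.1,
                        blur_sigma=0.3, noise_sd=2.0, render_seed=5)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A written-to-disk synthetic dataset: 2 adults, 1 juvenile, 1 neonate."""
    out = tmp_path_factory.mktemp("dataset")
    population = make_population(2, 1, 1, seed=11, body_length=TEST_BODY_LENGTH)
    manifest = write_dataset(
        population,
        baseline_replicates=3,
        time_steps=2,
        out_dir=out,
        seed=12,
        image_size=TEST_IMAGE_SIZE,
    )
    return {"root": out, "manifest": manifest, "population": population}


@pytest.fixture
def rendered_sample(adult_spec, render_cfg):
    return render(adult_spec, 0, render_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
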