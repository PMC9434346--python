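import pytest

from retquant.synthetic import (LesionSpec, SceneSpec, generate_cohort,
                                generate_scene)


@pytest.fixture(scope="session")
def desk_spec():
    """Noise-free desk-scale spec with one lesion of each class."""
    spec = SceneSpec.desk(speckle_sigma=0.0, ez_gap_fraction=0.25,
                          elm_gap_fraction=0.25)
    lesions = (
        LesionSpec("IRF", "ellipse", (52.0, 150.0), (7.0, 20.0), 0.08),
        LesionSpec("SRF", "ellipse", (90.0, 320.0), (5.0, 25.0), 0.16),
        LesionSpec("SHRM", "ellipse", (88.0, 420.0), (4.0, 18.0), 0.78),
        LesionSpec("PED", "dome", (float(spec.retina_bottom), 240.0),
                   (10.0, 35.0), 0.62),
    )
    return SceneSpec.desk(speckle_sigma=0.0, ez_gap_fraction=0.25,
                          elm_gap_fraction=0.25, lesion_specs=lesions)


@pytest.fixture(scope="session")
def desk_scene(desk_spec):
    return generate_scene(desk_spec, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free desk cohort shared across training-based tests."""
    spec = SceneSpec.desk(speckle_sigma=0.0)
    return generate_cohort(8, seed=3, scene_spec=spec)
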