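import numpy as np
import pytest

from coapvc.phantom import (
    InjectionModel,
    PhantomSpec,
    TubeSpec,
    default_frame_schedule,
    generate_input_function,
    render_dynamic_image,
)


@pytest.fixture(scope="session")
def injection():
    return InjectionModel()


@pytest.fixture(scope="session")
def arterial(injection):
    """Fine arterial ground-truth curve on a long horizon (for AUC checks)."""
    return generate_input_function(injection, 10.0, t_end_s=600.0)


@pytest.fixture(scope="session")
def single_tube_spec():
    """Small phantom with one 9.5 mm tube: fast to render, background 1.4."""
    return PhantomSpec(
        tube_bank=(TubeSpec(9.5, (50.0, 50.0), "artery"),),
        fov_mm=(100.0, 100.0, 60.0),
    )


@pytest.fixture(scope="session")
def single_tube_rendered(single_tube_spec):
    return render_dynamic_image(single_tube_spec)


@pytest.fixture(scope="session")
def default_rendered():
    """The full default phantom (four arteries + vein, background 1.4)."""
    spec = PhantomSpec()
    image, truth = render_dynamic_image(spec)
    return spec, image, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
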