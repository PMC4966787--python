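import numpy as np
import pytest
from hypothesis import settings

from feulgen import (
    Population,
    SlideSpec,
    estimate_white_reference,
    measure_nuclei,
    render_slide,
    render_standard_smear,
    segment_nuclei,
    transmittance_to_od,
)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_spec():
    """50 well-separated diploid ellipses with every noise source off."""
    return SlideSpec(
        populations=[Population(6.0, 0.6, 50, "ellipse")],
        noise_sd=0.0,
        texture_noise_cv=0.0,
        area_noise_cv=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def noiseless_render(noiseless_spec):
    return render_slide(noiseless_spec)


@pytest.fixture(scope="session")
def default_batch():
    """A standard smear + diploid slide rendered with default noise,
    segmented and measured — the shared end-to-end fixture."""
    smear, smear_truth = render_standard_smear(120, seed=202)
    slide, slide_truth = render_slide(SlideSpec(
        populations=[Population(6.0, 0.6, 120, "ellipse")], seed=203))

    def measure(image):
        od = transmittance_to_od(
            image, white_reference=estimate_white_reference(image))
        return od, measure_nuclei(od, segment_nuclei(od))

    od_smear, smear_meas = measure(smear)
    od_slide, slide_meas = measure(slide)
    return {
        "smear": smear, "smear_truth": smear_truth, "smear_meas": smear_meas,
        "slide": slide, "slide_truth": slide_truth, "slide_meas": slide_meas,
        "od_slide": od_slide,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
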