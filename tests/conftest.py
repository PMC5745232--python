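import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ifscreen import OpticsParams, SegmentationParams, place_cells, render_field
from ifscreen.synthetic import (
    cancer_population,
    feeder_population,
    generate_plate,
    scenario,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def small_optics():
    return OpticsParams(image_size=(256, 256))


@pytest.fixture
def make_field():
    """Factory: render a mixed field with known ground truth."""

    def _make(
        n_cancer=0,
        n_feeder=0,
        seed=0,
        noiseless=False,
        image_size=(256, 256),
        min_sep_factor=0.75,
        well="A1",
        site=0,
    ):
        pops = {"cancer": cancer_population(), "feeder": feeder_population()}
        rng = np.random.default_rng(seed)
        placements = place_cells(
            {"cancer": n_cancer, "feeder": n_feeder},
            pops,
            image_size,
            rng,
            min_sep_factor=min_sep_factor,
        )
        optics = OpticsParams(image_size=image_size)
        field = render_field(
            placements, optics, rng, well=well, site=site, noiseless=noiseless
        )
        return field, placements

    return _make


@pytest.fixture(scope="session")
def tiny_plate(tmp_path_factory):
    """One small simulated plate on disk, shared across interface tests."""
    out = tmp_path_factory.mktemp("plate") / "tiny"
    cfg = scenario("tiny", seed=11)
    result = generate_plate(cfg, out)
    return out, result
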