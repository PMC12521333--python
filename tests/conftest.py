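import numpy as np
import pytest

from cxraer.datatypes import measurements_to_frame
from cxraer.normalize import NormalizeConfig, normalize_radiograph
from cxraer.phantom import PhantomSpec, generate_phantom
from cxraer.segments import measure_image

#: reduced raw canvas used by replicate-heavy simulations; segment areas stay
#: in the hundreds of pixels so MPI noise is ~sigma/20
SMALL = dict(canvas_w=320, canvas_h=240)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL)


@pytest.fixture(scope="session")
def small_norm_cfg() -> NormalizeConfig:
    # match the canvas to the raw size: MPI/FHPI are placement-invariant
    return NormalizeConfig(canvas_w=SMALL["canvas_w"], canvas_h=SMALL["canvas_h"])


@pytest.fixture(scope="session")
def measure_frame():
    """Callable: phantom spec + seed -> long-format measurement frame."""

    def _run(spec: PhantomSpec, seed: int, cfg: NormalizeConfig | None = None):
        bundle = generate_phantom(spec, seed=seed)
        norm = normalize_radiograph(bundle.image, bundle.annotations, cfg)
        return measurements_to_frame(measure_image(norm)), bundle

    return _run
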