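import numpy as np
import pytest

from tmascreen import StainMatrix


@pytest.fixture(scope="session")
def stains() -> StainMatrix:
    return StainMatrix()


@pytest.fixture(scope="session")
def rendered_core(stains):
    """One unambiguous proficient-tumour core rendered at full
    resolution, with its ground truth."""
    from tmascreen.synthetic_tma import render_core, scenario_tumour_proficient

    rng = np.random.default_rng(42)
    tile, cells = render_core(scenario_tumour_proficient(), stains, 0.5, rng)
    return tile, cells


@pytest.fixture(scope="session")
def small_tma(stains):
    """A 3x5 TMA at 2 um/px: 2 blanks, 13 tissue cores."""
    from tmascreen.synthetic_tma import (
        TMASimSpec,
        render_tma,
        scenario_blank,
        scenario_normal_proficient,
        scenario_tumour_deficient,
        scenario_tumour_proficient,
    )

    scenarios = (
        [scenario_tumour_proficient() for _ in range(5)]
        + [scenario_blank(), scenario_normal_proficient(), scenario_normal_proficient(),
           scenario_tumour_deficient(), scenario_tumour_deficient()]
        + [scenario_normal_proficient() for _ in range(4)]
        + [scenario_blank()]
    )
    spec = TMASimSpec(scenarios=scenarios, rows=3, cols=5, pixel_size=2.0, seed=9)
    image, cells, cores = render_tma(spec, stains)
    return spec, image, cells, cores
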