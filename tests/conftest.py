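import numpy as np
import pytest
from hypothesis import settings

import phagoscreen as ps
from phagoscreen import hits, screen

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_screen():
    """One full default screen (489 compounds, planted inhibitors/toxics)."""
    cfg = ps.ScreenSimConfig(seed=1)
    fields, truth = ps.simulate_screen(cfg)
    return cfg, fields, truth


@pytest.fixture(scope="session")
def default_wells(default_screen):
    _, fields, _ = default_screen
    return screen.toxicity_filter(screen.summarize_wells(screen.overseg_filter(fields)))


@pytest.fixture(scope="session")
def default_results(default_wells):
    return hits.compound_results(default_wells)


@pytest.fixture(scope="session")
def null_screen():
    """Screen with no planted effects: every compound is null."""
    cfg = ps.ScreenSimConfig(
        n_compounds=360, inhibitor_fraction=0.0, activator_fraction=0.0,
        toxic_fraction=0.0, seed=5,
    )
    fields, truth = ps.simulate_screen(cfg)
    return cfg, fields, truth


@pytest.fixture(scope="session")
def rendered_field():
    """A 10-cell field with 20 internal puncta plus its ground truth."""
    spec = ps.simulate.random_field_spec(n_cells=10, puncta_count=20, seed=4)
    image, labels, puncta = ps.render_field(spec)
    return spec, image, labels, puncta


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
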