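import numpy as np
import pytest

from stainbench.synth import (
    CANONICAL_HE,
    LabStainProfile,
    PanelVariation,
    make_lab_profile,
    make_panel,
    make_tissue,
    render_slide,
)


@pytest.fixture(scope="session")
def clean_slide():
    """A slide rendered under the canonical balanced profile (no unevenness,
    no tint): exactly two-stain Beer-Lambert data plus quantization."""
    tissue = make_tissue(192, 192, 60, seed=5)
    return render_slide(tissue, LabStainProfile(CANONICAL_HE))


@pytest.fixture(scope="session")
def shared_pair():
    """One tissue rendered by the balanced lab (reference) and by a jittered
    lab without unevenness or tint (source)."""
    tissue = make_tissue(160, 160, 60, seed=1)
    ref = render_slide(tissue, LabStainProfile(CANONICAL_HE))
    prof = make_lab_profile((160, 160), 42, PanelVariation(unevenness=0.0, tint=0.0))
    src = render_slide(tissue, prof)
    return tissue, prof, ref, src


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(n_labs=6, height=160, width=160, nucleus_count=40, seed=3)


@pytest.fixture(scope="session")
def default_panel():
    """The full-size study-condition panel: 20 labs, 512x512, spread 0.2."""
    return make_panel(seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
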