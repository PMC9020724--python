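import numpy as np
import pandas as pd
import pytest

from specphos.simulate import PanelConfig, generate_panel
from specphos.spectra import SpectrumSet, WavelengthGrid


@pytest.fixture(scope="session")
def small_panel():
    """12 accessions x 2 blocks x 1 plant, default noise; ~144 spectra."""
    return generate_panel(PanelConfig(
        n_accessions=12, n_blocks=2, plants_per_accession_per_treatment=1,
        seed=7,
    ))


@pytest.fixture(scope="session")
def default_panel():
    """Full-size panel at the default study conditions (172 x 3 x 3 x 3)."""
    return generate_panel(PanelConfig(seed=7))


@pytest.fixture()
def toy_set():
    """Two flat spectra on the full device grid."""
    grid = WavelengthGrid()
    meta = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "accession_id": ["a1", "a2"],
        "treatment": ["P100", "P5"],
        "block": [1, 1],
        "replicate": [0, 0],
    })
    refl = pd.DataFrame(
        np.vstack([np.full(len(grid), 0.3),
                   np.linspace(0.1, 0.5, len(grid))]),
        columns=grid.columns(),
    )
    return SpectrumSet(grid, pd.concat([meta, refl], axis=1))
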