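import numpy as np
import pytest

import fdcret as f

# Published CR2-C3dg constants and retention anchors used across the tests:
# BLI kinetic fit k_on = 616,154 M^-1 s^-1, k_off = 0.15 s^-1; equilibrium
# K_D = 317 nM; IC half-life 1.2 h at 250 CR2/um^2 and 1.5 d at 375 CR2/um^2.
BLI_KON = 616154.0
BLI_KOFF = 0.15
BLI_KD_EQ = 317e-9
ANCHOR_DENSITIES = (250.0, 375.0)
ANCHOR_HALF_LIVES_S = (1.2 * 3600.0, 1.5 * 86400.0)
CONCENTRATION_SERIES_M = tuple(np.geomspace(0.023e-6, 2.9e-6, 8))


@pytest.fixture(scope="session")
def calibrated():
    """Model calibrated to the two half-life anchors (shared: it is the
    most expensive computation in the suite)."""
    return f.calibrate_rebinding(
        ANCHOR_DENSITIES, ANCHOR_HALF_LIVES_S, k_off=BLI_KOFF
    )
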