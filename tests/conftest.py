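import numpy as np
import pytest

from zfscreen.endpoints import ENDPOINT_NAMES, endpoints_table
from zfscreen.normalization import fit_reference
from zfscreen.simulate import SimulationConfig, simulate_larva


def make_profile(light, dark, accl=(), conc=0.0, chemical="chem", bin_width=2.0):
    """Assemble a LocomotorProfile from raw phase bin lists."""
    from zfscreen.endpoints import LocomotorProfile

    light = list(map(float, light))
    dark = list(map(float, dark))
    accl = list(map(float, accl))
    n = len(accl) + len(light) + len(dark)
    phases = np.array(
        ["acclimation"] * len(accl) + ["light"] * len(light) + ["dark"] * len(dark),
        dtype=object,
    )
    return LocomotorProfile(
        larva_id="L", plate_id="P", chemical=chemical, concentration=conc,
        bin_starts=np.arange(n) * bin_width, phases=phases,
        distances=np.array(accl + light + dark), bin_width=bin_width,
    )


@pytest.fixture(scope="session")
def vehicle_pool():
    """641 simulated vehicle-control larvae (the historical-pool size)."""
    cfg = SimulationConfig()
    rng = np.random.default_rng(7)
    profiles = [simulate_larva(cfg, 0.0, rng, larva_id=f"c{i}") for i in range(641)]
    return endpoints_table(profiles)


@pytest.fixture(scope="session")
def reference(vehicle_pool):
    """Frozen vehicle Box-Cox reference shared across the suite."""
    return fit_reference(vehicle_pool, list(ENDPOINT_NAMES))
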