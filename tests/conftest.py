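import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


#: Fitted constants of the wild-type and truncated enzyme used as synthetic
#: ground truth throughout: Michaelis constants in mM, Vmax in specific
#: activity units, Ki in mM.
WT_MM_PEP = {"vmax": 77.0, "km": 0.066}
WT_MM_ADP = {"vmax": 75.0, "km": 0.024}
WT_BIBI = {"vmax": 106.0, "ka": 0.031, "kb": 0.023}
OXALATE_C = {"vmax": 77.0, "km": 0.066, "ki": 0.044}
OXALATE_MT = {"vmax": 77.0, "km": 0.024, "ki": 0.044, "alpha": 0.5}
AMP_C_PEP = {"vmax": 77.0, "km": 0.066, "ki": 3.3}
AMP_C_ADP = {"vmax": 75.0, "km": 0.024, "ki": 3.3}
TRUNC_HILL_PEP = {"vmax": 8.8, "k05": 3.15, "n": 1.7}

#: DSC reference values: (Tm in deg C, calorimetric enthalpy in cal/mol).
DSC_WT = (79.2, 230946.6)
DSC_TRUNCATED = (78.4, 46845.8)
#: Sharpness (van't Hoff enthalpy) of the cooperative unfolding unit.
DSC_VANT_HOFF = 230946.6


@pytest.fixture
def mg_constants():
    from enzkin.speciation import BindingConstants
    return BindingConstants(kd_metal_adp=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
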