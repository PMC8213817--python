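import numpy as np
import pytest

import slbfet as sf

# printed study constants used as generating truth across the suite
K1_TRUE = 1.64e7          # M^-1 s^-1
KM1_TRUE = 1.02e-2        # s^-1
KEQ_TRUE = KM1_TRUE / K1_TRUE
VMAX_TRUE_MV = 9.38
D_TRUE = 1.43             # um^2/s
BLEACH_RADIUS_UM = 25.0


@pytest.fixture
def kinetic_params() -> sf.KineticParams:
    """Canonical generating parameters: printed rate constants plus the
    package's fast-injection-transient defaults."""
    return sf.KineticParams(
        k1=K1_TRUE, k_minus1=KM1_TRUE, V_max_mV=VMAX_TRUE_MV,
        V_p_mV=1.0, tau1_s=5.0, tau2_s=10.0, T_s=20.0,
    )


@pytest.fixture
def slb_stack() -> sf.SlabStack:
    """Five-slab SLB on SiO2 under water: head/tail/inter-leaflet gap/
    tail/head, 3 A roughness everywhere."""
    return sf.SlabStack(
        substrate=sf.Medium(rho_e=0.66),
        slabs=[
            sf.Slab(thickness_A=8.0, rho_e=0.45),
            sf.Slab(thickness_A=14.0, rho_e=0.30),
            sf.Slab(thickness_A=3.0, rho_e=0.28),
            sf.Slab(thickness_A=14.0, rho_e=0.30),
            sf.Slab(thickness_A=8.0, rho_e=0.45),
        ],
        ambient=sf.Medium(rho_e=0.334),
    )


@pytest.fixture
def slb_avidin_stack(slb_stack) -> sf.SlabStack:
    """Nine-slab SLB + bound avidin: a thin hydration water layer and
    three protein slabs above the bilayer."""
    extra = [
        sf.Slab(thickness_A=5.0, rho_e=0.334),    # DIW gap
        sf.Slab(thickness_A=12.0, rho_e=0.42),
        sf.Slab(thickness_A=18.0, rho_e=0.44),
        sf.Slab(thickness_A=12.0, rho_e=0.40),
    ]
    return sf.SlabStack(
        substrate=slb_stack.substrate,
        slabs=list(slb_stack.slabs) + extra,
        ambient=slb_stack.ambient,
    )
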