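import numpy as np
import pytest

import aerodep as ad


@pytest.fixture(scope="session")
def default_mesh():
    """The default synthetic mouth-throat geometry (shared, read-only)."""
    return ad.build_synthetic_airway()


@pytest.fixture(scope="session")
def field_18(default_mesh):
    return ad.continuity_flow(default_mesh, ad.FlowSpec(flow_lpm=18.0))


@pytest.fixture(scope="session")
def field_45(default_mesh):
    return ad.continuity_flow(default_mesh, ad.FlowSpec(flow_lpm=45.0))


def pich_sedimentation_de(kappa):
    """Closed-form gravitational deposition in a horizontal tube with
    Poiseuille flow; kappa = 3 v_s L / (8 R u_mean)."""
    k13 = kappa ** (1.0 / 3.0)
    root = np.sqrt(1.0 - k13 ** 2)
    return (2.0 / np.pi) * (2.0 * kappa * root - k13 * root
                            + np.arcsin(k13))
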