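import numpy as np
import pytest

from ampersim import (
    DimensionlessParams,
    GeometrySpec,
    Shape,
    SolverConfig,
    build_problem,
)
from ampersim.config import resolve_config
from ampersim.meshing import generate_mesh

# study layout: b1=2, b2=4, b4=14, b5=16, unit cell radius 1
SLAB_B = dict(b1=2.0, b2=4.0, b4=14.0, b5=16.0)


def slab_geometry(b3: float = 9.0) -> GeometrySpec:
    """Fully open cell (alpha=0): a three-slab stack, radially uniform."""
    return GeometrySpec(Shape.CYLINDER, 1.0, 1.0, SLAB_B["b1"], SLAB_B["b2"], b3,
                        SLAB_B["b4"], SLAB_B["b5"])


def slab_mesh(h=0.5, n_r=2, **kw):
    return generate_mesh(slab_geometry(kw.pop("b3", 9.0)), h=h, n_r_inner=n_r,
                         n_r_outer=n_r, **kw)


def slab_params(sigma2, S0=1.0, b3=9.0, D2=3.0, D3=6.0):
    return DimensionlessParams(sigma2=sigma2, S0=S0, D2=D2, D3=D3,
                               geometry=slab_geometry(b3))


@pytest.fixture(scope="session")
def open_cell_mesh():
    return slab_mesh(h=0.5, n_r=2)


@pytest.fixture(scope="session")
def fast_base():
    """Fast-profile base configuration at the study operating point."""
    return resolve_config(
        {"profile": "fast", "geometry": {"shape": "cylinder", "alpha": 0.93, "gamma": 0.5}}
    )


@pytest.fixture(scope="session")
def oracle_config():
    """Matched time-stepping policy for 1-D / 2-D comparisons."""
    return SolverConfig(dt=0.01, dt_max=0.25, dt_growth=1.05, t_max=400.0)
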