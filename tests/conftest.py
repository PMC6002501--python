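import warnings

import numpy as np
import pytest

from stimfem.geometry import BoxSpec, bipolar_spec, build_geometry
from stimfem.mesh import mesh_model
from stimfem.fem import (ContactSource, FemOperator, MaterialLibrary,
                         SourceConfiguration, solve_case)
from stimfem.cases import FiberBank, ModelContext, CaseSpec, run_case

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def geom():
    return build_geometry(bipolar_spec(), BoxSpec())


@pytest.fixture(scope="session")
def coarse_mesh(geom):
    return mesh_model(geom, "coarse")


@pytest.fixture(scope="session")
def coarse_op(coarse_mesh):
    return FemOperator(coarse_mesh, order=2)


@pytest.fixture(scope="session")
def materials():
    return MaterialLibrary()


@pytest.fixture(scope="session")
def syscache():
    return {}


@pytest.fixture(scope="session")
def gold_solution(coarse_mesh, coarse_op, geom, materials, syscache):
    """Gold standard: thin Pt contacts, silicone substrate, 1 mA point source."""
    cfg = SourceConfiguration(sources=(ContactSource("pcs", 1.0),
                                       ContactSource("inactive_floating")))
    return solve_case(coarse_mesh, materials, cfg, geometry=geom,
                      operator=coarse_op, system_cache=syscache)


@pytest.fixture(scope="session")
def fiber_bank():
    return FiberBank()


@pytest.fixture(scope="session")
def coarse_ctx():
    return ModelContext(resolution="coarse")


@pytest.fixture(scope="session")
def gold_report(coarse_ctx, fiber_bank):
    """Gold-standard monopolar thresholds for all nine combinations."""
    return run_case(CaseSpec(case_id="gold"), coarse_ctx, fiber_bank)


def solve_with(mesh, op, geom, materials, sources, cache=None, **kw):
    cfg = SourceConfiguration(sources=sources, **kw.pop("config_kw", {}))
    return solve_case(mesh, materials, cfg, geometry=geom, operator=op,
                      system_cache=cache, **kw)
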