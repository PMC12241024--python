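"""Shared fixtures: materials, stacks, and cached FE solutions.

The FE runs used by several test modules are session-scoped so each
configuration is solved once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import staplecomp as sc


@pytest.fixture(scope="session")
def tissue_material() -> sc.OgdenMaterial:
    """The porcine-colon three-term Ogden fit (constants given in Pa)."""
    return sc.OgdenMaterial.from_pa()


@pytest.fixture(scope="session")
def neo_hookean() -> sc.OgdenMaterial:
    """Single-term alpha=2 material: responses reduce to neo-Hookean forms."""
    return sc.OgdenMaterial(terms=((2.0, 2.0),))


@pytest.fixture(scope="session")
def stack_2_2() -> sc.TissueStack:
    return sc.TissueStack(t_upper=2.0, t_lower=2.0)


@pytest.fixture(scope="session")
def fem_frictionless(tissue_material, stack_2_2):
    """Frictionless full-contact FE run of the full load program.

    This is the configuration whose exact solution is homogeneous
    incompressible uniaxial compression; it anchors the engine against the
    closed form.
    """
    mesh = sc.build_mesh(stack_2_2, 0.5)
    program = sc.LoadProgram.for_stack(stack_2_2)
    options = sc.SolverOptions(mode="frictionless")
    results = sc.run_fem(tissue_material, stack_2_2, None, program, mesh, options)
    return mesh, program, results


@pytest.fixture(scope="session")
def fem_bonded(tissue_material, stack_2_2):
    """Bonded-contact FE run with the default asymmetric footprints.

    Run to 35% compression: past the onset of the contact-driven layer
    asymmetry while the axisymmetric relief-gap surrogate still behaves
    like the distributed hole pattern it stands in for (beyond this the
    annular gaps exaggerate the extrusion asymmetry of the real 3D holes).
    """
    mesh = sc.build_mesh(stack_2_2, 0.4)
    fps = sc.default_footprints(stack_2_2)
    program = sc.LoadProgram(total_travel=1.4)
    results = sc.run_fem(tissue_material, stack_2_2, fps, program, mesh)
    return mesh, program, results
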