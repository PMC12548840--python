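"""Shared fixtures: templates, trials and meshes built once per session."""

import numpy as np
import pytest

from lumbarlift.config import load_action_templates, load_material_table
from lumbarlift.femodel import (
    LumbarGeometryParams,
    assign_materials,
    build_geometry,
    mesh_geometry,
)
from lumbarlift.fesolver import assemble_system
from lumbarlift.synthgen import generate_trial

ACTIONS = ("DL", "SLDL", "TBDL")


@pytest.fixture(scope="session")
def templates():
    return load_action_templates()


@pytest.fixture(scope="session")
def material_table():
    return load_material_table()


@pytest.fixture(scope="session")
def noisefree_trials(templates):
    return {a: generate_trial(templates[a].with_noise(0.0)) for a in ACTIONS}


@pytest.fixture(scope="session")
def default_trials(templates):
    return {a: generate_trial(templates[a]) for a in ACTIONS}


@pytest.fixture(scope="session")
def tiny_mesh(material_table):
    mesh = mesh_geometry(build_geometry(LumbarGeometryParams.tiny()))
    return assign_materials(mesh, material_table)


@pytest.fixture(scope="session")
def tiny_system(tiny_mesh):
    return assemble_system(tiny_mesh)


@pytest.fixture(scope="session")
def coarse_mesh(material_table):
    """Default desk-scale (5 mm) lumbar mesh with bound materials."""
    mesh = mesh_geometry(build_geometry(LumbarGeometryParams.coarse()))
    return assign_materials(mesh, material_table)


@pytest.fixture(scope="session")
def coarse_fields(coarse_mesh):
    """Solved stress fields for the three default load cases (1425 N +
    first-peak moment) on the default mesh."""
    from lumbarlift.femodel import build_load_case
    from lumbarlift.fesolver import solve_static

    system = assemble_system(coarse_mesh)
    fields = {}
    for action, moment in (("DL", 749.0), ("SLDL", 893.0), ("TBDL", 640.0)):
        case = build_load_case(coarse_mesh, action, moment)
        _, field, _ = solve_static(system, case)
        fields[action] = field
    return fields


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
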