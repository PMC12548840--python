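"""Solver benchmarks: element oracle, patch test, composite column, orderings."""

import numpy as np
import pytest

from lumbarlift.errors import QueryError, SingularSystemError
from lumbarlift.femodel import (
    LumbarMesh,
    MaterialSpec,
    assign_materials,
    box_mesh,
    build_load_case,
    composite_column_mesh,
)
from lumbarlift.fesolver import (
    assemble_system,
    peak_stress_by_part,
    solve_static,
    von_mises,
)


def _bind(mesh, **materials):
    mesh.materials = {
        part: MaterialSpec(part, *materials.get(part, materials.get("block")))
        for part in mesh.part_names
    }
    return mesh


def _top_pressure_forces(mesh, p):
    """Consistent nodal loads for uniform pressure on the top surface."""
    z_top = mesh.nodes[:, 2].max()
    F = np.zeros_like(mesh.nodes)
    faces = _surface_faces(mesh)
    for tri in faces:
        pts = mesh.nodes[tri]
        if np.allclose(pts[:, 2], z_top):
            area = 0.5 * np.linalg.norm(
                np.cross(pts[1] - pts[0], pts[2] - pts[0])
            )
            F[tri, 2] -= p * area / 3.0
    return F


def _surface_faces(mesh):
    tets = mesh.tets
    faces = np.vstack(
        [tets[:, [0, 2, 1]], tets[:, [0, 1, 3]], tets[:, [1, 2, 3]], tets[:, [0, 3, 2]]]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


class TestElementLevel:
    def test_single_tet_stiffness_matches_symbolic_oracle(self):
        # independent route: symbolic shape functions, differentiation and
        # exact integration of the strain energy with sympy
        import sympy as sp

        verts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        x, y, z = sp.symbols("x y z")
        A = sp.Matrix([[1, *v] for v in verts])
        N = [sp.Matrix([1, x, y, z]).dot(A.inv().col(i)) for i in range(4)]
        E_, nu_ = 1.0, 0.0
        D = sp.Matrix(np.diag([1, 1, 1, 0.5, 0.5, 0.5]) * E_)
        B = sp.zeros(6, 12)
        for a in range(4):
            gx, gy, gz = (sp.diff(N[a], v) for v in (x, y, z))
            c = 3 * a
            B[0, c], B[1, c + 1], B[2, c + 2] = gx, gy, gz
            B[3, c], B[3, c + 1] = gy, gx
            B[4, c + 1], B[4, c + 2] = gz, gy
            B[5, c], B[5, c + 2] = gz, gx
        vol = sp.Rational(1, 6)
        K_expected = np.array((B.T * D * B * vol).evalf(), dtype=float)

        mesh = LumbarMesh(
            nodes=np.array(verts, dtype=float),
            tets=np.array([[0, 1, 2, 3]]),
            tet_part=np.array([0]),
            part_names=["block"],
            part_class={"block": "block"},
            lines=np.zeros((0, 2), dtype=int),
            line_part=np.zeros(0, dtype=int),
            ligament_area_mm2=1.0,
        )
        _bind(mesh, block=(1.0, 0.0))
        K = assemble_system(mesh).K.toarray()
        assert np.max(np.abs(K - K_expected)) < 1e-12

    def test_assembled_operator_symmetric(self, tiny_system):
        K = tiny_system.K
        asym = abs(K - K.T).max()
        assert asym <= 1e-9 * abs(K).max()

    def test_von_mises_zero_for_hydrostatic_state(self):
        assert von_mises(np.array([-7.0, -7.0, -7.0, 0.0, 0.0, 0.0])) == 0.0

    def test_von_mises_uniaxial(self):
        assert von_mises(np.array([5.0, 0, 0, 0, 0, 0])) == pytest.approx(5.0)


class TestPatchAndInvariants:
    def test_uniform_pressure_patch_test(self):
        mesh = _bind(box_mesh(10.0, 10.0, 10.0, 2.5), block=(100.0, 0.0))
        system = assemble_system(mesh)
        p = 2.0
        F = _top_pressure_forces(mesh, p)
        u, field, _ = solve_static(
            system, forces=F.ravel(), fixed_nodes=mesh.boundary_nodes("bottom")
        )
        # nu = 0: the uniaxial state sigma_zz = -p is exact; interior vm = p
        cent = field.centroids
        interior = np.all((cent > 2.5) & (cent < 7.5), axis=1)
        assert np.allclose(field.von_mises[interior], p, rtol=0.01)

    def test_linearity_exact(self, tiny_mesh, tiny_system):
        case1 = build_load_case(tiny_mesh, "DL", 749.0, vertical_load_N=1425.0)
        case2 = build_load_case(tiny_mesh, "DL", 2 * 749.0, vertical_load_N=2 * 1425.0)
        _, f1, _ = solve_static(tiny_system, case1)
        _, f2, _ = solve_static(tiny_system, case2)
        assert np.allclose(f2.von_mises, 2 * f1.von_mises, rtol=1e-10)

    def test_zero_load_zero_field(self, tiny_mesh, tiny_system):
        u, field, _ = solve_static(
            tiny_system,
            forces=np.zeros(tiny_system.ndof),
            fixed_nodes=tiny_mesh.boundary_nodes("bottom"),
        )
        assert np.allclose(u, 0) and np.allclose(field.von_mises, 0)

    def test_equilibrium_reactions_balance_loads(self, tiny_mesh, tiny_system):
        case = build_load_case(tiny_mesh, "DL", 749.0)
        _, _, report = solve_static(tiny_system, case)
        applied = np.array([0.0, 0.0, -case.vertical_load_N])
        assert np.allclose(report.reaction_force_N, -applied, rtol=1e-6, atol=1e-5)

    def test_mesh_refinement_monotone_energy(self):
        # displacement FEM underestimates energy; refining releases it
        energies = []
        for edge in (5.0, 2.5, 1.25):
            mesh = _bind(box_mesh(10.0, 10.0, 10.0, edge), block=(100.0, 0.3))
            system = assemble_system(mesh)
            F = _top_pressure_forces(mesh, 2.0)
            u, _, _ = solve_static(
                system, forces=F.ravel(), fixed_nodes=mesh.boundary_nodes("bottom")
            )
            energies.append(0.5 * float(F.ravel() @ u.ravel()))
        assert energies[0] < energies[1] < energies[2]

    def test_disconnected_part_raises_singularity(self):
        m1 = box_mesh(5.0, 5.0, 5.0, 2.5)
        n = m1.n_nodes
        nodes = np.vstack([m1.nodes, m1.nodes + [20.0, 0, 0]])
        tets = np.vstack([m1.tets, m1.tets + n])
        mesh = LumbarMesh(
            nodes=nodes,
            tets=tets,
            tet_part=np.concatenate([np.zeros(len(m1.tets), int), np.ones(len(m1.tets), int)]),
            part_names=["a", "b"],
            part_class={"a": "a", "b": "b"},
            lines=np.zeros((0, 2), dtype=int),
            line_part=np.zeros(0, dtype=int),
            ligament_area_mm2=1.0,
        )
        _bind(mesh, a=(100.0, 0.0), b=(100.0, 0.0))
        system = assemble_system(mesh)
        forces = np.zeros(system.ndof)
        forces[-1] = 1.0
        fixed = np.flatnonzero(np.abs(nodes[:, 2]) < 1e-9)
        fixed = fixed[fixed < n]  # only the first block is held
        with pytest.raises(SingularSystemError):
            solve_static(system, forces=forces, fixed_nodes=fixed)


@pytest.fixture(scope="module")
def solved_composite():
    E1, E2 = 400.0, 100.0
    mesh = _bind(composite_column_mesh(), core=(E1, 0.0), shell=(E2, 0.0))
    system = assemble_system(mesh)
    # uniform axial shortening of the top surface (load control follows
    # by linear rescaling)
    top = mesh.boundary_nodes("top")
    prescribed = {int(nid): (0.0, 0.0, -0.1) for nid in top}
    u, field, _ = solve_static(
        system, fixed_nodes=mesh.boundary_nodes("bottom"), prescribed=prescribed
    )
    areas = {p: mesh.part_volume(p) / 20.0 for p in ("core", "shell")}
    return mesh, field, {"core": E1, "shell": E2}, areas, u, system


class TestCompositeColumnOracle:
    @pytest.fixture()
    def solved(self, solved_composite):
        return solved_composite

    def test_stress_shares_follow_modulus_ratio(self, solved):
        mesh, field, E, areas, _, _ = solved
        strain = 0.1 / 20.0
        for part in ("core", "shell"):
            mid = _mid_elements(mesh, part)
            assert np.allclose(field.von_mises[mid], E[part] * strain, rtol=0.02)

    def test_load_sharing_closed_form(self, solved):
        mesh, field, E, areas, u, system = solved
        # total axial force from reactions at the bottom
        Kf = system.K @ np.ravel(u)
        bottom = mesh.boundary_nodes("bottom")
        Fz = Kf.reshape(-1, 3)[bottom, 2].sum()
        total_EA = sum(E[p] * areas[p] for p in E)
        for part in ("core", "shell"):
            sigma_pred = abs(Fz) * E[part] / total_EA
            mid = _mid_elements(mesh, part)
            assert np.allclose(field.von_mises[mid], sigma_pred, rtol=0.02)


def _mid_elements(mesh, part):
    idx = mesh.elements_of_part(part)
    cz = mesh.tet_centroids()[idx, 2]
    return idx[(cz > 5.0) & (cz < 15.0)]


class TestLumbarOrderings:
    """Orderings the model reproduces on the default desk-scale mesh."""

    @pytest.fixture()
    def fields(self, coarse_fields):
        return coarse_fields

    def test_l5_cortical_is_the_peak_vertebra(self, fields):
        for field in fields.values():
            l5 = peak_stress_by_part(field, "L5_cortical")
            for v in ("L1", "L2", "L3", "L4"):
                assert l5 >= peak_stress_by_part(field, f"{v}_cortical")

    def test_cortical_exceeds_cancellous_everywhere(self, fields):
        for field in fields.values():
            assert peak_stress_by_part(field, "cortical") > peak_stress_by_part(
                field, "cancellous"
            )

    def test_action_risk_gradient(self, fields):
        def disc_peak(field):
            return max(
                peak_stress_by_part(field, f"L4-L5_{c}")
                for c in ("nucleus", "annulus_inner", "annulus_middle", "annulus_outer")
            )

        for probe in (
            lambda f: peak_stress_by_part(f, "L5_cortical"),
            lambda f: peak_stress_by_part(f, "L5_cancellous"),
            disc_peak,
        ):
            assert probe(fields["SLDL"]) > probe(fields["DL"]) > probe(fields["TBDL"])

    def test_unknown_part_query_raises(self, fields):
        with pytest.raises(QueryError):
            peak_stress_by_part(fields["DL"], "L6_cortical")
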