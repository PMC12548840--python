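"""Static linear-elastic solve on the labeled tetrahedral mesh.

Linear 4-node (constant-strain) tetrahedra for the solids and 2-node truss
elements for the ligaments, assembled into a sparse symmetric stiffness
and solved by direct sparse factorisation.  Element Cauchy stresses come
from the constant displacement gradients; the reported intensity measure
is the von Mises equivalent stress

    sigma_vm = sqrt(1/2 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2])

computed from the stress tensor components.  Units: mm / N / MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .errors import QueryError, SingularSystemError, SolverError
from .femodel import LoadCase, LumbarMesh, nodal_forces

#: Voigt order used throughout: xx, yy, zz, xy, yz, zx (engineering shears).
VOIGT = ("xx", "yy", "zz", "xy", "yz", "zx")


def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix (engineering shear strains)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def tet_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Shape-function gradients and volumes for all tets, vectorised."""
    p = nodes[tets]
    J = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix
    detJ = np.linalg.det(J)
    vol = np.abs(detJ) / 6.0
    Jinv = np.linalg.inv(J)
    # gradients of N1..N3 are rows of J^-T; N0 = 1 - sum
    g123 = np.transpose(Jinv, (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)
    return grads, vol


def tet_B(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices, (m, 6, 12)."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


@dataclass
class FESystem:
    """Assembled operator: global stiffness plus stress-recovery data."""

    mesh: LumbarMesh
    K: sp.csr_matrix
    B: np.ndarray  # (m, 6, 12)
    D: np.ndarray  # (m, 6, 6) per-element elasticity
    vol: np.ndarray

    @property
    def ndof(self) -> int:
        return 3 * self.mesh.n_nodes


def assemble_system(mesh: LumbarMesh) -> FESystem:
    """Assemble the symmetric stiffness from tets and ligament trusses."""
    if not mesh.materials:
        raise SolverError("mesh has no bound materials; run assign_materials first")
    nodes, tets = mesh.nodes, mesh.tets
    grads, vol = tet_gradients(nodes, tets)
    B = tet_B(grads)

    E = np.empty(mesh.n_tets)
    nu = np.empty(mesh.n_tets)
    for pid, name in enumerate(mesh.part_names):
        mask = mesh.tet_part == pid
        if not mask.any():
            continue
        mat = mesh.materials[name]
        E[mask] = mat.elastic_modulus_MPa
        nu[mask] = mat.poisson_ratio
    D = np.array([isotropic_D(e, n) for e, n in zip(E, nu)])

    Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol)  # (m, 12, 12)
    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    ndof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    if len(mesh.lines):
        K = K + _truss_stiffness(mesh)
    K.sum_duplicates()
    return FESystem(mesh=mesh, K=K, B=B, D=D, vol=vol)


def _truss_stiffness(mesh: LumbarMesh) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    A = mesh.ligament_area_mm2
    for (n1, n2), pid in zip(mesh.lines, mesh.line_part):
        mat = mesh.materials[mesh.part_names[pid]]
        d = mesh.nodes[n2] - mesh.nodes[n1]
        L = np.linalg.norm(d)
        u = d / L
        k = mat.elastic_modulus_MPa * A / L
        kb = k * np.outer(u, u)
        ke = np.block([[kb, -kb], [-kb, kb]])
        dofs = np.concatenate([3 * n1 + np.arange(3), 3 * n2 + np.arange(3)])
        rows.append(np.repeat(dofs, 6))
        cols.append(np.tile(dofs, 6))
        vals.append(ke.ravel())
    ndof = 3 * mesh.n_nodes
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()


@dataclass
class StressField:
    """Per-element Cauchy stress (Voigt, MPa) and von Mises scalar."""

    stress: np.ndarray  # (m, 6)
    von_mises: np.ndarray  # (m,)
    centroids: np.ndarray  # (m, 3) mm
    mesh: LumbarMesh

    def part_values(self, part: str) -> np.ndarray:
        idx = self.mesh.elements_of_part(part)
        if len(idx) == 0:
            raise QueryError(f"part {part!r} has no elements")
        return self.von_mises[idx]


@dataclass
class SolveReport:
    """Diagnostics of one static solve."""

    dof: int
    residual_norm: float
    peak_displacement_mm: float
    part_peak_MPa: dict
    reaction_force_N: np.ndarray


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt components."""
    s = np.atleast_2d(stress)
    sx, sy, sz, txy, tyz, tzx = s.T
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return vm if stress.ndim == 2 else float(vm[0])


def solve_static(
    system: FESystem,
    loadcase: LoadCase | None = None,
    forces: np.ndarray | None = None,
    fixed_nodes: np.ndarray | None = None,
    prescribed: dict | None = None,
    rtol: float = 1e-8,
):
    """Direct sparse solve; returns (displacements, StressField, SolveReport).

    Either a :class:`LoadCase` or explicit ``forces``/``fixed_nodes`` may be
    given; ``prescribed`` maps node index -> (ux, uy, uz) in mm for
    non-homogeneous Dirichlet conditions.
    """
    mesh = system.mesh
    if loadcase is not None:
        F = nodal_forces(mesh, loadcase).ravel()
        fixed = np.asarray(loadcase.fixed_nodes)
    else:
        F = np.zeros(system.ndof) if forces is None else np.asarray(forces, dtype=float).ravel()
        fixed = np.asarray(fixed_nodes) if fixed_nodes is not None else np.array([], dtype=int)

    u = np.zeros(system.ndof)
    fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel() if len(fixed) else np.array([], dtype=int)
    if prescribed:
        extra = []
        for node, vals in prescribed.items():
            for k in range(3):
                u[3 * node + k] = vals[k]
                extra.append(3 * node + k)
        fixed_dofs = np.unique(np.concatenate([fixed_dofs, np.asarray(extra, dtype=int)]))
    if len(fixed_dofs) == 0:
        raise SingularSystemError("no constrained degrees of freedom")
    _check_connectivity(mesh, np.unique(fixed_dofs // 3))

    free = np.setdiff1d(np.arange(system.ndof), fixed_dofs, assume_unique=False)
    K = system.K
    rhs = F[free] - K[free][:, fixed_dofs] @ u[fixed_dofs]
    Kff = K[free][:, free]
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            uf = spla.spsolve(Kff.tocsc(), rhs)
        except spla.MatrixRankWarning as exc:
            raise SingularSystemError(
                "stiffness is singular: some parts are unconstrained"
            ) from exc
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError("solver produced non-finite displacements")
    u[free] = uf

    res = float(np.linalg.norm(Kff @ uf - rhs))
    scale = float(np.linalg.norm(rhs))
    rel = res / scale if scale > 0 else res
    if scale > 0 and rel > rtol:
        raise SolverError(f"relative residual {rel:.2e} exceeds {rtol:.0e}")

    ue = u.reshape(-1, 3)[mesh.tets].reshape(mesh.n_tets, 12)
    strain = np.einsum("mij,mj->mi", system.B, ue)
    stress = np.einsum("mij,mj->mi", system.D, strain)
    field = StressField(
        stress=stress,
        von_mises=von_mises(stress),
        centroids=mesh.tet_centroids(),
        mesh=mesh,
    )
    reactions = (K @ u - F).reshape(-1, 3)[fixed] if len(fixed) else np.zeros((0, 3))
    report = SolveReport(
        dof=len(free),
        residual_norm=rel,
        peak_displacement_mm=float(np.abs(u).max()),
        part_peak_MPa={p: float(field.part_values(p).max()) for p in mesh.part_names
                       if len(mesh.elements_of_part(p))},
        reaction_force_N=reactions.sum(axis=0),
    )
    return u.reshape(-1, 3), field, report


def _check_connectivity(mesh: LumbarMesh, constrained_nodes: np.ndarray) -> None:
    """Every connected component must touch the constrained set.

    Disconnected, unconstrained parts carry rigid-body modes that a sparse
    factorisation may not flag reliably; detect them combinatorially.
    """
    edges = np.vstack(
        [mesh.tets[:, [0, 1]], mesh.tets[:, [0, 2]], mesh.tets[:, [0, 3]]]
        + ([mesh.lines] if len(mesh.lines) else [])
    )
    n = mesh.n_nodes
    graph = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)
    held = np.zeros(n_comp, dtype=bool)
    held[labels[constrained_nodes]] = True
    if not held.all():
        free_part = int(np.flatnonzero(~held)[0])
        raise SingularSystemError(
            f"mesh component {free_part} has no constrained nodes (rigid-body modes)"
        )


def peak_stress_by_part(field: StressField, part: str) -> float:
    """Maximum element von Mises stress within one part or part class.

    ``part`` may be a full part name (``"L5_cortical"``) or a part class
    (``"cortical"``), in which case the peak is over all parts of the class.
    """
    mesh = field.mesh
    if part in mesh.part_names:
        return float(field.part_values(part).max())
    names = mesh.parts_of_class(part)
    if not names:
        raise QueryError(f"no part or class named {part!r}")
    vals = [field.part_values(n).max() for n in names if len(mesh.elements_of_part(n))]
    if not vals:
        raise QueryError(f"class {part!r} has no elements")
    return float(max(vals))
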