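"""Parametric L1-L5 geometry, tetrahedral meshing, materials and load cases.

Subject-specific CT geometry is not part of this package; the lumbar
column is idealised as five stacked elliptical vertebral bodies separated
by discs, with

* a cortical shell (1 mm inward offset) around a cancellous core in each
  vertebra,
* each disc split into a central nucleus pulposus and three concentric
  annulus-fibrosus layers,
* a 0.5 mm cartilaginous endplate above and below each disc,
* six ligament groups as 2-node truss chains on the outer surface.

The mesh is a structured extrusion: a polar template of ring/sector nodes
is scaled to each level's ellipse, stacked in z and each triangular prism
is split into three tetrahedra with globally consistent face diagonals, so
all part interfaces share nodes (tied/binding contact).  Working units are
millimetres, newtons and MPa throughout the FE chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import TorqueSeries, first_peak_torque
from .errors import (
    GeometryError,
    MaterialBindingError,
    MeshingError,
    ModelError,
    ParameterError,
)

VERTEBRAE = ("L5", "L4", "L3", "L2", "L1")  # stacked bottom -> top
DISCS = ("L4-L5", "L3-L4", "L2-L3", "L1-L2")

#: part-class -> material-table row (names follow the standard lumbar FE
#: material tables: cortical/cancellous bone, three annulus layers, nucleus,
#: cartilaginous endplate, six spinal ligaments).
PART_CLASS_MATERIAL = {
    "cortical": "Cortical bone",
    "cancellous": "Cancellous bone",
    "nucleus": "Nucleus pulposus",
    "annulus_outer": "Outer layer of fibrous ring",
    "annulus_middle": "Fiber ring second layer",
    "annulus_inner": "Fiber ring third layer",
    "endplate": "Cartilaginous endplate",
    "lig_anterior_longitudinal": "Anterior longitudinal",
    "lig_posterior_longitudinal": "Posterior longitudinal ligament",
    "lig_flavum": "Ligamentum flavum",
    "lig_interspinous": "Interspinous ligament",
    "lig_intertransverse": "Intertransvers ligament",
    "lig_supraspinal": "Supraspinal ligament",
}

LIGAMENT_CLASSES = tuple(c for c in PART_CLASS_MATERIAL if c.startswith("lig_"))


@dataclass(frozen=True)
class MaterialSpec:
    """One material-table row: Young's modulus (MPa), Poisson ratio, tag."""

    name: str
    elastic_modulus_MPa: float
    poisson_ratio: float
    constitutive_tag: str = "linear elastic"

    def __post_init__(self) -> None:
        if self.elastic_modulus_MPa <= 0:
            raise ParameterError(f"material {self.name!r}: E must be > 0")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ParameterError(f"material {self.name!r}: nu out of [0, 0.5]")

    def clamped(self, nu_max: float = 0.4999) -> "MaterialSpec":
        """Clamp near-incompressible nu below 0.5 for the displacement solver."""
        if self.poisson_ratio > nu_max:
            return replace(self, poisson_ratio=nu_max)
        return self


@dataclass(frozen=True)
class LumbarGeometryParams:
    """Dimensions of the idealised lumbar column (all in millimetres)."""

    vertebra_depth_mm: float = 32.0  # sagittal (X) full diameter
    vertebra_width_mm: float = 45.0  # coronal (Y) full diameter
    vertebra_height_mm: float = 28.0
    disc_height_mm: float = 10.0
    endplate_thickness_mm: float = 0.5
    cortical_offset_mm: float = 1.0
    nucleus_radius_fraction: float = 0.4
    annulus_layer_fractions: tuple[float, float, float] = (0.2, 0.2, 0.2)
    target_edge_mm: float = 2.0
    ligament_area_mm2: float = 30.0

    def __post_init__(self) -> None:
        dims = (
            self.vertebra_depth_mm,
            self.vertebra_width_mm,
            self.vertebra_height_mm,
            self.disc_height_mm,
            self.endplate_thickness_mm,
            self.cortical_offset_mm,
            self.target_edge_mm,
            self.ligament_area_mm2,
        )
        if any(d <= 0 for d in dims):
            raise ParameterError("all geometry dimensions must be positive")
        if self.cortical_offset_mm >= min(self.semi_axes):
            raise GeometryError("cortical offset must be smaller than the semi-axes")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ParameterError("nucleus fraction must lie in (0, 1)")
        total = self.nucleus_radius_fraction + sum(self.annulus_layer_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                "nucleus fraction plus annulus layer fractions must sum to 1"
            )

    @property
    def semi_axes(self) -> tuple[float, float]:
        return (self.vertebra_depth_mm / 2.0, self.vertebra_width_mm / 2.0)

    @classmethod
    def coarse(cls, **overrides) -> "LumbarGeometryParams":
        """Desk-scale mesh resolution for tests and the default pipeline."""
        overrides.setdefault("target_edge_mm", 5.0)
        return cls(**overrides)

    @classmethod
    def tiny(cls, **overrides) -> "LumbarGeometryParams":
        """Very coarse resolution for fast unit tests."""
        overrides.setdefault("target_edge_mm", 12.0)
        return cls(**overrides)


@dataclass(frozen=True)
class LumbarGeometry:
    """Labeled solid description: the z-stack of levels plus ligament routing."""

    params: LumbarGeometryParams
    levels: tuple  # (part_kind, name, z0, z1) bottom -> top
    total_height_mm: float

    def vertebra_z_span(self, name: str) -> tuple[float, float]:
        for kind, nm, z0, z1 in self.levels:
            if kind == "vertebra" and nm == name:
                return z0, z1
        raise GeometryError(f"no vertebra {name!r} in geometry")


def build_geometry(params: LumbarGeometryParams) -> LumbarGeometry:
    """Stack the five vertebrae, four discs and eight endplates in z."""
    levels = []
    z = 0.0
    for i, vert in enumerate(VERTEBRAE):
        levels.append(("vertebra", vert, z, z + params.vertebra_height_mm))
        z += params.vertebra_height_mm
        if i < len(DISCS):
            disc = DISCS[i]
            ep = params.endplate_thickness_mm
            levels.append(("endplate", f"{disc}_endplate_inferior", z, z + ep))
            z += ep
            levels.append(("disc", disc, z, z + params.disc_height_mm))
            z += params.disc_height_mm
            levels.append(("endplate", f"{disc}_endplate_superior", z, z + ep))
            z += ep
    return LumbarGeometry(params=params, levels=tuple(levels), total_height_mm=z)


@dataclass
class LumbarMesh:
    """Labeled tetrahedral mesh with optional line (truss) elements.

    ``nodes`` are (n, 3) coordinates in mm; ``tets`` (m, 4) node indices;
    ``tet_part`` indexes into ``part_names``; ligaments are 2-node line
    elements with their own part indices.  ``part_class`` maps each part
    name to its material class and ``materials`` (after binding) each part
    name to a :class:`MaterialSpec`.
    """

    nodes: np.ndarray
    tets: np.ndarray
    tet_part: np.ndarray
    part_names: list
    part_class: dict
    lines: np.ndarray
    line_part: np.ndarray
    ligament_area_mm2: float
    materials: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def part_index(self, name: str) -> int:
        try:
            return self.part_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown part {name!r}") from exc

    def elements_of_part(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.tet_part == self.part_index(name))

    def parts_of_class(self, cls: str) -> list:
        return [p for p in self.part_names if self.part_class[p] == cls]

    def census(self) -> dict:
        """Part counts by class, matching the reference model composition."""
        solid = {"cortical": 0, "cancellous": 0, "nucleus": 0, "endplate": 0}
        annulus = 0
        ligament = 0
        for name in self.part_names:
            cls = self.part_class[name]
            if cls in solid:
                solid[cls] += 1
            elif cls.startswith("annulus"):
                annulus += 1
            elif cls.startswith("lig_"):
                ligament += 1
        return {
            "cortical": solid["cortical"],
            "cancellous": solid["cancellous"],
            "nucleus": solid["nucleus"],
            "endplate": solid["endplate"],
            "annulus_layers": annulus,
            "ligament_groups": ligament,
            "nodes": self.n_nodes,
            "tetrahedra": self.n_tets,
            "line_elements": int(len(self.lines)),
        }

    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        return np.abs(
            np.einsum(
                "ij,ij->i",
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                p[:, 3] - p[:, 0],
            )
            / 6.0
        )

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def part_volume(self, name: str) -> float:
        return float(self.tet_volumes()[self.elements_of_part(name)].sum())

    def boundary_nodes(self, which: str) -> np.ndarray:
        """Node indices on the inferior ('bottom') or superior ('top') face."""
        z = self.nodes[:, 2]
        zref = z.min() if which == "bottom" else z.max()
        return np.flatnonzero(np.abs(z - zref) < 1e-9)


# ---------------------------------------------------------------------------
# structured polar template + extrusion


def _ring_radii(params: LumbarGeometryParams) -> np.ndarray:
    """Normalised ring radii: material boundaries plus shell-resolving rings."""
    nf = params.nucleus_radius_fraction
    f1, f2, _ = params.annulus_layer_fractions
    base = [nf / 2.0, nf, nf + f1, nf + f1 + f2, 0.9, 0.93, 0.96, 1.0]
    return np.unique(np.round(np.asarray(base), 9))


def _cross_section_template(params: LumbarGeometryParams, n_theta: int):
    """Unit-disk node layout (centre + rings) and its triangulation."""
    radii = _ring_radii(params)
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    pts = [np.zeros((1, 2))]
    for r in radii:
        pts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
    pts = np.vstack(pts)

    tris = []
    # central fan
    for j in range(n_theta):
        tris.append((0, 1 + j, 1 + (j + 1) % n_theta))
    # ring bands as split quads
    for i in range(len(radii) - 1):
        a0 = 1 + i * n_theta
        b0 = 1 + (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            tris.append((a0 + j, b0 + j, b0 + jn))
            tris.append((a0 + j, b0 + jn, a0 + jn))
    return pts, np.asarray(tris, dtype=np.int64), radii, theta


def _split_prism(bottom: np.ndarray, top: np.ndarray) -> list:
    """Split a triangular prism into three tets with consistent diagonals.

    Uses the smallest-global-index rule so shared quad faces of adjacent
    prisms receive the same diagonal and the mesh stays conforming.
    """
    v = [bottom[0], bottom[1], bottom[2], top[0], top[1], top[2]]
    start = int(np.argmin(v))
    if start >= 3:  # mirror so the anchor vertex lies on the bottom triangle
        v = [v[3], v[5], v[4], v[0], v[2], v[1]]
        start = int(np.argmin(v))
    for _ in range(start):  # rotate anchor to position 0
        v = [v[1], v[2], v[0], v[4], v[5], v[3]]
    if min(v[1], v[5]) < min(v[2], v[4]):
        return [(v[0], v[1], v[2], v[5]), (v[0], v[1], v[5], v[4]), (v[0], v[4], v[5], v[3])]
    return [(v[0], v[1], v[2], v[4]), (v[0], v[4], v[2], v[5]), (v[0], v[4], v[5], v[3])]


def _z_layers(geometry: LumbarGeometry, edge: float) -> tuple[np.ndarray, list]:
    """z planes of the extrusion plus the level owning each element layer."""
    zs = [0.0]
    owners = []
    for kind, name, z0, z1 in geometry.levels:
        n = 1 if kind == "endplate" else max(1, int(round((z1 - z0) / edge)))
        for k in range(n):
            zs.append(z0 + (z1 - z0) * (k + 1) / n)
            owners.append((kind, name))
    return np.asarray(zs), owners


def _classify(kind: str, name: str, xy: np.ndarray, params: LumbarGeometryParams):
    """Part label for element centroids of one z layer."""
    a, b = params.semi_axes
    t = params.cortical_offset_mm
    rho = np.sqrt((xy[:, 0] / a) ** 2 + (xy[:, 1] / b) ** 2)
    labels = np.empty(len(xy), dtype=object)
    if kind == "vertebra":
        shell = (xy[:, 0] / (a - t)) ** 2 + (xy[:, 1] / (b - t)) ** 2 > 1.0
        labels[:] = f"{name}_cancellous"
        labels[shell] = f"{name}_cortical"
    elif kind == "endplate":
        labels[:] = name
    else:  # disc
        nf = params.nucleus_radius_fraction
        f1, f2, _ = params.annulus_layer_fractions
        labels[:] = f"{name}_annulus_outer"
        labels[rho <= nf + f1 + f2] = f"{name}_annulus_middle"
        labels[rho <= nf + f1] = f"{name}_annulus_inner"
        labels[rho <= nf] = f"{name}_nucleus"
    return labels


def _ligament_elements(
    geometry: LumbarGeometry,
    radii: np.ndarray,
    theta: np.ndarray,
    zs: np.ndarray,
    n_theta: int,
):
    """Route the six ligament chains over existing outer-ring nodes.

    Anterior is +X (station 0), posterior -X (station n/2).  Paired chains
    (flavum, interspinous, intertransverse) run on both sides of the
    midline at station offsets, so no two chains share nodes.  The
    posterior longitudinal ligament and flavum bridge each disc between
    endplate-adjacent vertebral nodes; the remaining chains connect
    vertebra mid-height nodes of adjacent levels.
    """
    outer_ring = len(radii) - 1  # index of ring at rho = 1

    def node_at(iz: int, itheta: int) -> int:
        per_layer = 1 + len(radii) * n_theta
        return iz * per_layer + 1 + outer_ring * n_theta + (itheta % n_theta)

    def nearest_z(z: float) -> int:
        return int(np.argmin(np.abs(zs - z)))

    mid_iz = {}
    span = {}
    for kind, name, z0, z1 in geometry.levels:
        if kind == "vertebra":
            mid_iz[name] = nearest_z(0.5 * (z0 + z1))
            span[name] = (nearest_z(z0), nearest_z(z1))

    post = n_theta // 2
    chains = {
        "lig_anterior_longitudinal": ("mid", [0]),
        "lig_supraspinal": ("mid", [post]),
        "lig_interspinous": ("mid", [post - 1, post + 1]),
        "lig_intertransverse": ("mid", [n_theta // 4, 3 * n_theta // 4]),
        "lig_posterior_longitudinal": ("juxta", [post]),
        "lig_flavum": ("juxta", [post - 2, post + 2]),
    }
    lines, line_cls = [], []
    for cls, (mode, stations) in chains.items():
        for it in stations:
            for lower, upper in zip(VERTEBRAE[:-1], VERTEBRAE[1:]):
                if mode == "mid":
                    n1 = node_at(mid_iz[lower], it)
                    n2 = node_at(mid_iz[upper], it)
                else:
                    n1 = node_at(span[lower][1], it)
                    n2 = node_at(span[upper][0], it)
                lines.append((n1, n2))
                line_cls.append(cls)
    return np.asarray(lines, dtype=np.int64), line_cls


def mesh_geometry(
    geometry: LumbarGeometry, target_edge_mm: float | None = None
) -> LumbarMesh:
    """Deterministic structured tetrahedral mesh of the labeled solids."""
    params = geometry.params
    edge = target_edge_mm if target_edge_mm is not None else params.target_edge_mm
    if edge <= 0:
        raise MeshingError("target edge length must be positive")
    a, b = params.semi_axes
    perimeter = np.pi * (a + b)
    n_theta = int(max(8, 4 * round(perimeter / edge / 4.0)))
    pts2d, tris, radii, theta = _cross_section_template(params, n_theta)
    zs, owners = _z_layers(geometry, edge)
    per_layer = len(pts2d)

    nodes = np.empty((len(zs) * per_layer, 3))
    for iz, z in enumerate(zs):
        nodes[iz * per_layer : (iz + 1) * per_layer, 0] = a * pts2d[:, 0]
        nodes[iz * per_layer : (iz + 1) * per_layer, 1] = b * pts2d[:, 1]
        nodes[iz * per_layer : (iz + 1) * per_layer, 2] = z

    part_names: list = []
    part_class: dict = {}
    part_idx: dict = {}

    def part_id(label: str, kind: str) -> int:
        if label not in part_idx:
            part_idx[label] = len(part_names)
            part_names.append(label)
            if kind == "vertebra":
                part_class[label] = "cortical" if label.endswith("cortical") else "cancellous"
            elif kind == "endplate":
                part_class[label] = "endplate"
            elif label.endswith("_nucleus"):
                part_class[label] = "nucleus"
            else:
                part_class[label] = "annulus_" + label.rsplit("_", 1)[-1]
        return part_idx[label]

    tets, tet_part = [], []
    for iz, (kind, name) in enumerate(owners):
        lo, hi = iz * per_layer, (iz + 1) * per_layer
        cent = (nodes[lo:hi][tris].mean(axis=1) + nodes[hi : hi + per_layer][tris].mean(axis=1)) / 2.0
        labels = _classify(kind, name, cent[:, :2], params)
        for tri, lab in zip(tris, labels):
            pid = part_id(str(lab), kind)
            for tet in _split_prism(tri + lo, tri + hi):
                tets.append(tet)
                tet_part.append(pid)
    tets = np.asarray(tets, dtype=np.int64)
    tet_part = np.asarray(tet_part, dtype=np.int64)

    # enforce positive signed volumes (orientation only; connectivity fixed)
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    neg = vol6 < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()
    if np.any(np.abs(vol6) < 1e-12):
        bad = int(np.flatnonzero(np.abs(vol6) < 1e-12)[0])
        raise MeshingError(f"degenerate tetrahedron in part {part_names[tet_part[bad]]!r}")

    lines, line_cls = _ligament_elements(geometry, radii, theta, zs, n_theta)
    for cls in LIGAMENT_CLASSES:
        part_id(cls, "ligament")
        part_class[cls] = cls
    line_part = np.asarray([part_idx[c] for c in line_cls], dtype=np.int64)

    mesh = LumbarMesh(
        nodes=nodes,
        tets=tets,
        tet_part=tet_part,
        part_names=part_names,
        part_class=part_class,
        lines=lines,
        line_part=line_part,
        ligament_area_mm2=params.ligament_area_mm2,
    )
    c = mesh.census()
    expected = dict(
        cortical=5, cancellous=5, nucleus=4, endplate=8, annulus_layers=12, ligament_groups=6
    )
    for key, want in expected.items():
        if c[key] != want:
            raise MeshingError(
                f"part census {key}={c[key]} (expected {want}); mesh too coarse "
                "to resolve all parts"
            )
    return mesh


def assign_materials(mesh: LumbarMesh, table) -> LumbarMesh:
    """Bind every part to its (E, nu) row; nucleus nu is clamped to 0.4999."""
    by_name = {m.name: m for m in table}
    materials = {}
    for part in mesh.part_names:
        cls = mesh.part_class[part]
        # benchmark meshes may name a material row directly as the class
        row = PART_CLASS_MATERIAL.get(cls, cls)
        if row not in by_name:
            raise MaterialBindingError(
                f"no material row {row!r} for part {part!r}"
            )
        materials[part] = by_name[row].clamped()
    mesh.materials = materials
    return mesh


# ---------------------------------------------------------------------------
# benchmark meshes (patch tests, composite-column oracles)


def box_mesh(
    lx: float,
    ly: float,
    lz: float,
    edge: float,
    part_fn=None,
) -> LumbarMesh:
    """Structured tetrahedral box via the Kuhn 6-tet cube subdivision.

    ``part_fn(centroid) -> label`` assigns part labels (default a single
    part ``"block"``); the Kuhn split is conforming across the whole grid.
    Used by the solver benchmarks (patch test, composite column).
    """
    if min(lx, ly, lz, edge) <= 0:
        raise MeshingError("box dimensions and edge must be positive")
    nx, ny, nz = (max(1, int(round(l / edge))) for l in (lx, ly, lz))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn: one tet per permutation path from corner 000 to 111
    perms = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = np.array([i, j, k])
                for p in perms:
                    idx = [base.copy()]
                    for axis in p:
                        nxt = idx[-1].copy()
                        nxt[axis] += 1
                        idx.append(nxt)
                    tets.append([nid(*v) for v in idx])
    tets = np.asarray(tets, dtype=np.int64)

    cent = nodes[tets].mean(axis=1)
    labels = (
        np.array([part_fn(c) for c in cent], dtype=object)
        if part_fn is not None
        else np.array(["block"] * len(tets), dtype=object)
    )
    part_names = sorted(set(labels))
    part_idx = {p: i for i, p in enumerate(part_names)}
    tet_part = np.array([part_idx[l] for l in labels], dtype=np.int64)

    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    neg = vol6 < 0
    tets[neg, 2], tets[neg, 3] = tets[neg, 3].copy(), tets[neg, 2].copy()

    return LumbarMesh(
        nodes=nodes,
        tets=tets,
        tet_part=tet_part,
        part_names=list(part_names),
        part_class={p: p for p in part_names},
        lines=np.zeros((0, 2), dtype=np.int64),
        line_part=np.zeros(0, dtype=np.int64),
        ligament_area_mm2=1.0,
    )


def composite_column_mesh(
    width: float = 10.0,
    height: float = 20.0,
    core_half_width: float = 2.5,
    edge: float = 2.5,
    platen: bool = False,
) -> LumbarMesh:
    """Two-material concentric column: square 'core' inside a 'shell'.

    The closed-form load-sharing oracle for this geometry under uniform
    axial strain is sigma_i = F * E_i / (E1 A1 + E2 A2).  With
    ``platen=True`` a one-element 'platen' layer is added on top so a
    force-controlled load approximates the rigid-platen (shared
    displacement) condition of the oracle.
    """
    half = width / 2.0
    total_h = height + (edge if platen else 0.0)

    def part_fn(c):
        if platen and c[2] > height:
            return "platen"
        return (
            "core"
            if (abs(c[0] - half) <= core_half_width and abs(c[1] - half) <= core_half_width)
            else "shell"
        )

    return box_mesh(width, width, total_h, edge, part_fn=part_fn)


@dataclass(frozen=True)
class LoadCase:
    """Boundary conditions for one action: fixed base, loaded L1 surface.

    The vertical compressive load is split evenly over the superior-L1
    endplate nodes; the sagittal (flexion) moment is realised as a linear
    force-couple distribution over the same node set.
    """

    action_id: str
    vertical_load_N: float
    sagittal_moment_Nm: float
    fixed_nodes: np.ndarray
    loaded_nodes: np.ndarray

    def __post_init__(self) -> None:
        if self.vertical_load_N <= 0:
            raise ModelError("vertical load must be positive")
        if self.sagittal_moment_Nm < 0:
            raise ModelError("sagittal moment must be >= 0")
        if len(self.fixed_nodes) == 0 or len(self.loaded_nodes) == 0:
            raise ModelError("fixed and loaded node sets must be non-empty")
        if np.intersect1d(self.fixed_nodes, self.loaded_nodes).size:
            raise ModelError("fixed and loaded node sets overlap")


DEFAULT_VERTICAL_LOAD_N = 1425.0


def build_load_case(
    mesh: LumbarMesh,
    action_id: str,
    torque_source: TorqueSeries | float,
    vertical_load_N: float = DEFAULT_VERTICAL_LOAD_N,
) -> LoadCase:
    """Load case pairing the vertical load with the action's first-peak torque."""
    if isinstance(torque_source, TorqueSeries):
        moment = first_peak_torque(torque_source)
    else:
        moment = float(torque_source)
    return LoadCase(
        action_id=action_id,
        vertical_load_N=vertical_load_N,
        sagittal_moment_Nm=moment,
        fixed_nodes=mesh.boundary_nodes("bottom"),
        loaded_nodes=mesh.boundary_nodes("top"),
    )


def nodal_forces(mesh: LumbarMesh, case: LoadCase) -> np.ndarray:
    """Global (n, 3) nodal force array realising the load case.

    Compression: equal vertical share per loaded node.  Flexion moment
    about the coronal (Y) axis: vertical forces varying linearly with the
    sagittal coordinate x, scaled so the resultant couple equals the
    requested moment exactly and the net force vanishes.
    """
    F = np.zeros_like(mesh.nodes)
    nl = case.loaded_nodes
    F[nl, 2] -= case.vertical_load_N / len(nl)
    x = mesh.nodes[nl, 0]
    dx = x - x.mean()
    denom = float(np.sum(dx**2))
    if denom > 0 and case.sagittal_moment_Nm != 0:
        m_Nmm = case.sagittal_moment_Nm * 1000.0
        # flexion compresses the anterior (+x) fibres
        F[nl, 2] -= m_Nmm / denom * dx
    return F
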