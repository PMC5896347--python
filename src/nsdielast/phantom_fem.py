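"""Plane-strain linear-elasticity phantoms with a circular inclusion.

Generates ground-truth displacement fields for an elastography phantom: a
stiff circular inclusion (optionally containing stiffer sub-inclusions)
embedded in a softer 40 x 40 mm background, compressed from the top by a
prescribed fraction of the domain height with laterally free boundaries.

The solver uses 4-node quadrilaterals on a structured grid with selective
reduced integration (full 2x2 Gauss quadrature for the deviatoric part,
one-point quadrature for the dilatational part), which keeps the element
usable at the near-incompressible Poisson ratio (0.495) used for soft
tissue, where fully integrated quads lock volumetrically.

The inclusion/background interface can be *bonded* (continuous mesh) or
*slip*: interface nodes are duplicated and the two sides are coupled by a
stiff penalty spring along the local (radial) normal plus a tangential
penalty proportional to a friction coefficient. Small coefficients (~0.1)
let the inclusion slide along its boundary; large ones (~1000) recover the
bonded response. This is a linear, reproducible stand-in for frictional
contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import DisplacementField

__all__ = [
    "PhantomSpec",
    "FEMesh",
    "FEMSolution",
    "GeometryError",
    "ResolutionError",
    "SolverError",
    "build_mesh",
    "solve",
    "sample_displacement",
    "sample_strain",
    "random_sub_inclusions",
]

BACKGROUND_ID = 0
INCLUSION_ID = 1

#: normal penalty stiffness = PENALTY_FACTOR * background shear modulus / element size
PENALTY_FACTOR = 1.0e3


class GeometryError(ValueError):
    pass


class ResolutionError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass
class PhantomSpec:
    """Parameterization of one inclusion-phantom experiment.

    Coordinates are (axial, lateral) in mm with the axial coordinate
    increasing with depth from the compressed (top) surface.

    ``sub_inclusions`` holds ``(center_mm, diameter_mm,
    modulus_ratio_vs_inclusion)`` triples describing stiffer secondary
    targets inside the main inclusion (heterogeneous-lesion experiments).
    """

    domain_width_mm: float = 40.0
    domain_height_mm: float = 40.0
    inclusion_center_mm: Tuple[float, float] = (20.0, 20.0)  # (axial, lateral)
    inclusion_diameter_mm: float = 10.0
    modulus_ratio: float = 4.0
    poisson_ratio: float = 0.495
    sub_inclusions: List[Tuple[Tuple[float, float], float, float]] = field(default_factory=list)
    interface: str = "bonded"  # "bonded" or "slip"
    friction_coefficient: Optional[float] = None  # required when interface == "slip"
    applied_compression: float = 0.01
    mesh_resolution_mm: float = 0.25
    seed: int = 0  # records the RNG seed used for random sub-inclusion placement

    def __post_init__(self) -> None:
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.modulus_ratio < 1.0:
            raise ValueError("modulus_ratio must be >= 1")
        if not (0.0 < self.applied_compression <= 0.05):
            raise ValueError("applied_compression must lie in (0, 0.05]")
        if self.mesh_resolution_mm <= 0:
            raise ValueError("mesh_resolution_mm must be positive")
        if self.interface not in ("bonded", "slip"):
            raise ValueError("interface must be 'bonded' or 'slip'")
        if self.interface == "slip":
            if self.friction_coefficient is None or self.friction_coefficient <= 0:
                raise ValueError("slip interface requires friction_coefficient > 0")
        r = self.inclusion_diameter_mm / 2.0
        cy, cx = self.inclusion_center_mm
        if (
            cy - r <= 0.0
            or cx - r <= 0.0
            or cy + r >= self.domain_height_mm
            or cx + r >= self.domain_width_mm
        ):
            raise GeometryError("inclusion must lie strictly inside the domain")
        for (sy, sx), d, ratio in self.sub_inclusions:
            sr = d / 2.0
            if (
                sy - sr <= 0.0
                or sx - sr <= 0.0
                or sy + sr >= self.domain_height_mm
                or sx + sr >= self.domain_width_mm
            ):
                raise GeometryError("sub-inclusion must lie strictly inside the domain")
            if ratio <= 0:
                raise ValueError("sub-inclusion modulus ratio must be positive")


@dataclass
class FEMesh:
    """Structured quadrilateral mesh with per-element material tags.

    ``elements`` is (ne, 4) counterclockwise connectivity; ``material_id``
    is 0 for background, 1 for the inclusion and 2+k for the k-th
    sub-inclusion. ``interface_node_pairs`` lists (background-side node,
    inclusion-side duplicate) pairs; it is empty for bonded interfaces.
    """

    node_coordinates_mm: np.ndarray  # (nn, 2) as (lateral x, axial y)
    elements: np.ndarray  # (ne, 4) int
    material_id: np.ndarray  # (ne,) int
    interface_node_pairs: np.ndarray  # (np, 2) int
    interface_normals: np.ndarray  # (np, 2) unit radial vector (x, y) per pair
    nx: int
    ny: int
    h: float

    @property
    def n_nodes(self) -> int:
        return self.node_coordinates_mm.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]


@dataclass
class FEMSolution:
    """Nodal displacements and element-centroid strains of a solved phantom."""

    nodal_displacements_mm: np.ndarray  # (nn, 2) as (lateral ux, axial uy)
    element_strains: np.ndarray  # (ne, 3) as (exx, eyy, exy) tensor shear


def random_sub_inclusions(
    inclusion_center_mm: Tuple[float, float],
    inclusion_diameter_mm: float,
    n: int = 5,
    sub_diameter_mm: float = 1.5,
    modulus_ratio_vs_inclusion: float = 2.0,
    min_gap_mm: float = 1.0,
    seed: int = 0,
    max_attempts: int = 100_000,
) -> List[Tuple[Tuple[float, float], float, float]]:
    """Place ``n`` secondary inclusions inside the main inclusion.

    Rejection sampling keeps sub-inclusions at least ``min_gap_mm`` apart
    (edge to edge) and at least ``min_gap_mm`` inside the inclusion
    boundary; the draw is reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    cy, cx = inclusion_center_mm
    r_allow = inclusion_diameter_mm / 2.0 - sub_diameter_mm / 2.0 - min_gap_mm
    if r_allow <= 0:
        raise GeometryError("inclusion too small for the requested sub-inclusions")
    min_center_dist = sub_diameter_mm + min_gap_mm
    centers: List[Tuple[float, float]] = []
    for _ in range(max_attempts):
        # uniform in the allowed disc
        rad = r_allow * np.sqrt(rng.random())
        ang = 2 * np.pi * rng.random()
        cand = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
        if all(np.hypot(cand[0] - a, cand[1] - b) >= min_center_dist for a, b in centers):
            centers.append(cand)
            if len(centers) == n:
                break
    else:
        raise GeometryError(
            f"could not place {n} sub-inclusions after {max_attempts} attempts"
        )
    return [(c, sub_diameter_mm, modulus_ratio_vs_inclusion) for c in centers]


def build_mesh(spec: PhantomSpec) -> FEMesh:
    """Build the structured quad mesh and tag elements by material.

    Elements are axis-aligned squares of side ``mesh_resolution_mm``;
    an element belongs to a region when its centroid falls inside that
    region's circle, so the discrete interface follows element edges.  For
    slip interfaces every node adjacent to both inclusion-tagged and
    background-tagged elements is duplicated; the inclusion-side elements
    are rewired to the duplicates and the pair list is returned with the
    radial normal at each pair.
    """
    for (_, d, _) in spec.sub_inclusions:
        if spec.mesh_resolution_mm > d / 3.0:
            raise ResolutionError(
                "mesh_resolution_mm must be at most sub-inclusion diameter / 3"
            )
    h = spec.mesh_resolution_mm
    nx = int(round(spec.domain_width_mm / h))
    ny = int(round(spec.domain_height_mm / h))
    if nx < 2 or ny < 2:
        raise ResolutionError("mesh too coarse for the domain")

    xs = np.linspace(0.0, spec.domain_width_mm, nx + 1)
    ys = np.linspace(0.0, spec.domain_height_mm, ny + 1)
    X, Y = np.meshgrid(xs, ys)  # (ny+1, nx+1)
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(j, i):
        return j * (nx + 1) + i

    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    n00 = nid(jj, ii).ravel()
    n10 = nid(jj, ii + 1).ravel()
    n11 = nid(jj + 1, ii + 1).ravel()
    n01 = nid(jj + 1, ii).ravel()
    elements = np.column_stack([n00, n10, n11, n01]).astype(np.int64)

    cx_e = (xs[:-1] + xs[1:])[None, :] / 2.0 * np.ones((ny, 1))
    cy_e = (ys[:-1] + ys[1:])[:, None] / 2.0 * np.ones((1, nx))
    cx_e = cx_e.ravel()
    cy_e = cy_e.ravel()

    icy, icx = spec.inclusion_center_mm
    r_inc = spec.inclusion_diameter_mm / 2.0
    material = np.zeros(elements.shape[0], dtype=np.int64)
    inside_inc = (cx_e - icx) ** 2 + (cy_e - icy) ** 2 < r_inc**2
    material[inside_inc] = INCLUSION_ID
    for k, ((sy, sx), d, _ratio) in enumerate(spec.sub_inclusions):
        inside_sub = (cx_e - sx) ** 2 + (cy_e - sy) ** 2 < (d / 2.0) ** 2
        material[inside_sub] = 2 + k

    interface_pairs = np.empty((0, 2), dtype=np.int64)
    normals = np.empty((0, 2), dtype=float)
    if spec.interface == "slip":
        # inclusion side = main inclusion plus its sub-inclusions
        inc_side = material >= INCLUSION_ID
        in_inc_elem = np.zeros(nodes.shape[0], dtype=bool)
        in_bg_elem = np.zeros(nodes.shape[0], dtype=bool)
        in_inc_elem[elements[inc_side].ravel()] = True
        in_bg_elem[elements[~inc_side].ravel()] = True
        iface_nodes = np.nonzero(in_inc_elem & in_bg_elem)[0]
        n_old = nodes.shape[0]
        dup_ids = n_old + np.arange(iface_nodes.size)
        nodes = np.vstack([nodes, nodes[iface_nodes]])
        remap = -np.ones(n_old, dtype=np.int64)
        remap[iface_nodes] = dup_ids
        elems_inc = elements[inc_side]
        hit = remap[elems_inc] >= 0
        elems_inc[hit] = remap[elems_inc][hit]
        elements[inc_side] = elems_inc
        interface_pairs = np.column_stack([iface_nodes, dup_ids])
        vec = nodes[iface_nodes] - np.array([icx, icy])
        nrm = np.linalg.norm(vec, axis=1)
        nrm[nrm == 0] = 1.0
        normals = vec / nrm[:, None]

    mesh = FEMesh(
        node_coordinates_mm=nodes,
        elements=elements,
        material_id=material,
        interface_node_pairs=interface_pairs,
        interface_normals=normals,
        nx=nx,
        ny=ny,
        h=h,
    )
    _check_jacobians(mesh)
    return mesh


def _check_jacobians(mesh: FEMesh) -> None:
    # squares: area from the shoelace formula must be positive
    p = mesh.node_coordinates_mm[mesh.elements]  # (ne, 4, 2)
    x, y = p[..., 0], p[..., 1]
    area = 0.5 * np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1)
    if np.any(area <= 0):
        raise GeometryError("non-positive element Jacobian")


def _element_matrices(h: float, nu: float) -> Tuple[np.ndarray, np.ndarray]:
    """Unit stiffness matrices for an h x h square, split by material constant.

    Returns (K_mu, K_lam) such that the element matrix is
    mu * K_mu + lam * K_lam, with the mu part integrated 2x2 and the lam
    (dilatational) part integrated at the centroid only (selective reduced
    integration).
    """
    del nu  # split is independent of nu; kept in signature for clarity
    gauss = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    xi_n = np.array([-1.0, 1.0, 1.0, -1.0])
    eta_n = np.array([-1.0, -1.0, 1.0, 1.0])

    def bmat(xi, eta):
        dN_dxi = 0.25 * xi_n * (1 + eta * eta_n)
        dN_deta = 0.25 * eta_n * (1 + xi * xi_n)
        dN_dx = dN_dxi * 2.0 / h
        dN_dy = dN_deta * 2.0 / h
        B = np.zeros((3, 8))
        B[0, 0::2] = dN_dx
        B[1, 1::2] = dN_dy
        B[2, 0::2] = dN_dy
        B[2, 1::2] = dN_dx
        return B

    D_mu = np.diag([2.0, 2.0, 1.0])
    D_lam = np.zeros((3, 3))
    D_lam[:2, :2] = 1.0

    detJ = (h / 2.0) ** 2
    K_mu = np.zeros((8, 8))
    for xi in gauss:
        for eta in gauss:
            B = bmat(xi, eta)
            K_mu += B.T @ D_mu @ B * detJ
    B0 = bmat(0.0, 0.0)
    K_lam = B0.T @ D_lam @ B0 * (4.0 * detJ)
    return K_mu, K_lam


def _material_constants(spec: PhantomSpec, material_id: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    nu = spec.poisson_ratio
    mu = np.ones(material_id.shape[0])
    mu[material_id == INCLUSION_ID] = spec.modulus_ratio
    for k, (_c, _d, ratio) in enumerate(spec.sub_inclusions):
        mu[material_id == 2 + k] = spec.modulus_ratio * ratio
    lam = 2.0 * mu * nu / (1.0 - 2.0 * nu)
    return mu, lam


def solve(spec: PhantomSpec, mesh: FEMesh) -> FEMSolution:
    """Solve the compression problem on ``mesh``.

    Boundary conditions: the top surface is pushed down by
    ``applied_compression x domain_height`` (axial dof prescribed, lateral
    free), the bottom surface is held axially with free lateral motion (one
    bottom-center node pinned laterally to remove the rigid mode), the
    sides are traction-free.
    """
    nn = mesh.n_nodes
    ndof = 2 * nn
    mu, lam = _material_constants(spec, mesh.material_id)
    K_mu, K_lam = _element_matrices(mesh.h, spec.poisson_ratio)

    ke = mu[:, None, None] * K_mu[None] + lam[:, None, None] * K_lam[None]  # (ne, 8, 8)
    edof = np.empty((mesh.n_elements, 8), dtype=np.int64)
    edof[:, 0::2] = 2 * mesh.elements
    edof[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(edof, 8, axis=1).ravel()
    cols = np.tile(edof, (1, 8)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    if mesh.interface_node_pairs.shape[0]:
        K = K + _penalty_matrix(spec, mesh, ndof)

    u = np.zeros(ndof)
    fixed = np.zeros(ndof, dtype=bool)
    y = mesh.node_coordinates_mm[:, 1]
    x = mesh.node_coordinates_mm[:, 0]
    top = np.isclose(y, 0.0)
    bottom = np.isclose(y, spec.domain_height_mm)
    # axial displacement positive-down: the top surface moves deeper
    u[2 * np.nonzero(top)[0] + 1] = spec.applied_compression * spec.domain_height_mm
    fixed[2 * np.nonzero(top)[0] + 1] = True
    fixed[2 * np.nonzero(bottom)[0] + 1] = True
    bottom_ids = np.nonzero(bottom)[0]
    pin = bottom_ids[np.argmin(np.abs(x[bottom_ids] - spec.domain_width_mm / 2.0))]
    fixed[2 * pin] = True

    free = ~fixed
    K_csc = K.tocsc()
    rhs = -K_csc[:, fixed] @ u[fixed]
    try:
        u[free] = spla.spsolve(K_csc[free][:, free], rhs[free])
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise SolverError(f"stiffness solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise SolverError("singular stiffness system (non-finite displacements)")

    strains = _centroid_strains(mesh, u)
    disp = u.reshape(nn, 2)
    return FEMSolution(nodal_displacements_mm=disp, element_strains=strains)


def _penalty_matrix(spec: PhantomSpec, mesh: FEMesh, ndof: int) -> sp.csr_matrix:
    """Penalty springs coupling duplicated interface node pairs.

    Normal stiffness kn = PENALTY_FACTOR x mu_background / h enforces
    non-penetration; tangential stiffness kt = friction_coefficient x
    mu_background / h (capped at kn) grades the interface from freely
    sliding to effectively bonded.
    """
    h = mesh.h
    kn = PENALTY_FACTOR * 1.0 / h  # background shear modulus normalized to 1
    kt = min(spec.friction_coefficient * 1.0 / h, kn)
    rows, cols, data = [], [], []
    for (a, b), n_vec in zip(mesh.interface_node_pairs, mesh.interface_normals):
        t_vec = np.array([-n_vec[1], n_vec[0]])
        C = kn * np.outer(n_vec, n_vec) + kt * np.outer(t_vec, t_vec)  # 2x2
        dofs = np.array([2 * a, 2 * a + 1, 2 * b, 2 * b + 1])
        block = np.block([[C, -C], [-C, C]])
        for ri in range(4):
            for ci in range(4):
                rows.append(dofs[ri])
                cols.append(dofs[ci])
                data.append(block[ri, ci])
    return sp.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()


def _centroid_strains(mesh: FEMesh, u: np.ndarray) -> np.ndarray:
    h = mesh.h
    xi_n = np.array([-1.0, 1.0, 1.0, -1.0])
    eta_n = np.array([-1.0, -1.0, 1.0, 1.0])
    dN_dx = 0.25 * xi_n * 2.0 / h  # at centroid
    dN_dy = 0.25 * eta_n * 2.0 / h
    ue = u.reshape(-1, 2)[mesh.elements]  # (ne, 4, 2)
    exx = np.einsum("nk,k->n", ue[..., 0], dN_dx)
    eyy = np.einsum("nk,k->n", ue[..., 1], dN_dy)
    exy = 0.5 * (
        np.einsum("nk,k->n", ue[..., 0], dN_dy) + np.einsum("nk,k->n", ue[..., 1], dN_dx)
    )
    return np.column_stack([exx, eyy, exy])


def _locate(mesh: FEMesh, qx: np.ndarray, qy: np.ndarray):
    """Element index and local coords of query points on the structured grid."""
    h = mesh.h
    i = np.clip(np.floor(qx / h).astype(np.int64), 0, mesh.nx - 1)
    j = np.clip(np.floor(qy / h).astype(np.int64), 0, mesh.ny - 1)
    eid = j * mesh.nx + i
    xi = 2.0 * (qx - (i + 0.5) * h) / h
    eta = 2.0 * (qy - (j + 0.5) * h) / h
    return eid, xi, eta


def sample_displacement(
    sol: FEMSolution,
    mesh: FEMesh,
    grid_spacing_mm: float,
    origin_mm: Tuple[float, float] = (0.0, 0.0),
    shape: Optional[Tuple[int, int]] = None,
) -> DisplacementField:
    """Interpolate the FE solution onto a regular grid via shape functions.

    Element-local bilinear interpolation reproduces nodal values exactly and
    honors the displacement discontinuity across slip interfaces.  By
    default the grid covers the meshed domain; an explicit ``origin_mm`` /
    ``shape`` may request any grid, with points outside the domain masked
    invalid (never extrapolated).
    """
    W = mesh.nx * mesh.h
    H = mesh.ny * mesh.h
    oy, ox = origin_mm
    if shape is None:
        ny = int(np.floor((H - oy) / grid_spacing_mm + 1e-9)) + 1
        nx_ = int(np.floor((W - ox) / grid_spacing_mm + 1e-9)) + 1
    else:
        ny, nx_ = shape
    ys = oy + grid_spacing_mm * np.arange(ny)
    xs = ox + grid_spacing_mm * np.arange(nx_)
    QX, QY = np.meshgrid(xs, ys)
    inside = (QX >= 0) & (QX <= W) & (QY >= 0) & (QY <= H)
    u_ax, v_lat = _interp_displacement(sol, mesh, QX, QY)
    u_ax = np.where(inside, u_ax, 0.0)
    v_lat = np.where(inside, v_lat, 0.0)
    return DisplacementField(
        u_axial=u_ax,
        v_lateral=v_lat,
        grid_spacing_mm=(grid_spacing_mm, grid_spacing_mm),
        origin_mm=origin_mm,
        valid_mask=inside,
        state="ground_truth",
    )


def _interp_displacement(sol: FEMSolution, mesh: FEMesh, QX, QY):
    eid, xi, eta = _locate(mesh, np.asarray(QX, float), np.asarray(QY, float))
    xi_n = np.array([-1.0, 1.0, 1.0, -1.0])
    eta_n = np.array([-1.0, -1.0, 1.0, 1.0])
    N = 0.25 * (1 + xi[..., None] * xi_n) * (1 + eta[..., None] * eta_n)  # (..., 4)
    conn = mesh.elements[eid]  # (..., 4)
    ue = sol.nodal_displacements_mm[conn]  # (..., 4, 2)
    ux = np.sum(N * ue[..., 0], axis=-1)
    uy = np.sum(N * ue[..., 1], axis=-1)
    return uy, ux  # (axial, lateral)


def interp_displacement_at_points(
    sol: FEMSolution, mesh: FEMesh, axial_mm: np.ndarray, lateral_mm: np.ndarray
):
    """Shape-function displacement (axial, lateral) at arbitrary points."""
    return _interp_displacement(sol, mesh, np.asarray(lateral_mm), np.asarray(axial_mm))


def sample_strain(sol: FEMSolution, mesh: FEMesh, grid_spacing_mm: float):
    """Ground-truth strain components on a regular grid.

    Strains are taken from shape-function derivatives evaluated at the
    query point inside its containing element. Returns (exx, eyy, exy,
    valid_mask, axial_coords, lateral_coords).
    """
    W = mesh.nx * mesh.h
    H = mesh.ny * mesh.h
    ys = np.arange(0.0, H + grid_spacing_mm / 2.0, grid_spacing_mm)
    xs = np.arange(0.0, W + grid_spacing_mm / 2.0, grid_spacing_mm)
    QX, QY = np.meshgrid(xs, ys)
    eid, xi, eta = _locate(mesh, QX, QY)
    h = mesh.h
    xi_n = np.array([-1.0, 1.0, 1.0, -1.0])
    eta_n = np.array([-1.0, -1.0, 1.0, 1.0])
    dN_dx = 0.25 * xi_n * (1 + eta[..., None] * eta_n) * 2.0 / h
    dN_dy = 0.25 * eta_n * (1 + xi[..., None] * xi_n) * 2.0 / h
    ue = sol.nodal_displacements_mm[mesh.elements[eid]]  # (..., 4, 2)
    exx = np.sum(dN_dx * ue[..., 0], axis=-1)
    eyy = np.sum(dN_dy * ue[..., 1], axis=-1)
    exy = 0.5 * (np.sum(dN_dy * ue[..., 0], axis=-1) + np.sum(dN_dx * ue[..., 1], axis=-1))
    inside = (QX >= 0) & (QX <= W) & (QY >= 0) & (QY <= H)
    return exx, eyy, exy, inside, ys, xs
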