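"""Complete-electrode-model forward solver and sensitivity (Jacobian) matrix.

A first-order (P1) finite-element discretization of the 2D cross-sectional
conduction problem with the complete electrode model (CEM): finite electrode
arcs on the nerve circumference, per-electrode contact impedance, and a
Dirichlet ground node.  The mesh is a structured disk triangulation built
from concentric rings whose node counts are multiples of the electrode
count, so the mesh is exactly invariant under rotation by one electrode
pitch (360/14 degrees) — protocol-rotation properties hold to solver
precision rather than re-meshing tolerance.

The skip-4 injection protocol (14 injection pairs x 14 measurement
electrodes) yields 196 transfer voltages per frame.  Sensitivities are
computed by the adjoint method and can be voxelized onto the coarse square
grid (150 um default) used for image reconstruction.

Notes on the 2D reduction: out of plane, the model is a slab of thickness
``thickness`` (defaults to the electrode ring width); the insulating cuff
decouples the nerve cross-section from the saline bath at cuff level, so the
default mesh contains the nerve disk only.  ``include_exterior=True`` adds
the insulating-cuff annulus and the saline annulus for sensitivity sanity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import (
    CUFF_OPENING_DEG,
    N_ELECTRODES,
    PROTOCOL_SKIP,
    NerveGeometry,
    electrode_angles_deg,
)

REGION_NERVE = 0
REGION_CUFF = 1
REGION_SALINE = 2


class MeshError(RuntimeError):
    """Raised when a mesh cannot be built for the requested geometry."""


class SolverError(RuntimeError):
    """Raised when the CEM system cannot be solved."""


@dataclass
class Mesh:
    """P1 triangle mesh of the nerve cross-section with CEM electrodes."""

    nodes: np.ndarray                  # (N, 2) meters
    elements: np.ndarray               # (M, 3) node indices, CCW
    region: np.ndarray                 # (M,) REGION_* labels
    electrode_edges: list[np.ndarray]  # per electrode: (k, 2) boundary edges
    electrode_angle_deg: np.ndarray    # (L,) arc-center angles
    contact_impedance: np.ndarray      # (L,) Ohm*m^2
    thickness: float                   # out-of-plane slab thickness, m
    ground_node: int
    nerve_radius: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_edges)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def base_conductivity(self, geometry: NerveGeometry,
                          sigma_cuff: float = 1e-4) -> np.ndarray:
        """Per-element conductivity for the given geometry (S/m)."""
        sigma = np.empty(self.n_elements)
        sigma[self.region == REGION_NERVE] = geometry.sigma_nerve
        sigma[self.region == REGION_CUFF] = sigma_cuff
        sigma[self.region == REGION_SALINE] = geometry.sigma_saline
        return sigma


def _ring_counts(target_elements: int, n_sectors: int) -> tuple[int, np.ndarray]:
    """Choose ring count and per-sector node counts for ~target elements.

    Ring i (1-based) sits at radius R*i/m and carries n_sectors*c_i nodes.
    Element count is n_1 (center fan) + sum(n_i + n_{i+1}) over strips; with
    c_i ~ q*i/m the element size is roughly uniform and the total is
    ~ 2*n_sectors*q*m, so m ~ sqrt(target/(2*n_sectors*ratio)).
    """
    # aspect-balanced: arc step ~ radial step when q ~ 2*pi*m / n_sectors
    m = max(3, round(np.sqrt(target_elements / (2.0 * np.pi))))
    q = max(2, round(2.0 * np.pi * m / n_sectors))
    counts = np.maximum(1, np.round(q * np.arange(1, m + 1) / m).astype(int))
    return m, counts


def _strip_triangles(inner: np.ndarray, outer: np.ndarray) -> np.ndarray:
    """Triangulate the annular strip between two concentric node rings.

    Nodes on each ring are ordered by angle starting at 0; both counts are
    multiples of the sector count, and the two-pointer merge below breaks
    ties inner-first, so the pattern repeats identically in every sector.
    """
    na, nb = len(inner), len(outer)
    ang_a = np.arange(na + 1) / na          # normalized angle of next node
    ang_b = np.arange(nb + 1) / nb
    tris = []
    i = j = 0
    while i < na or j < nb:
        if j >= nb or (i < na and ang_a[i + 1] <= ang_b[j + 1]):
            tris.append((inner[i], inner[(i + 1) % na], outer[j % nb]))
            i += 1
        else:
            tris.append((inner[i % na], outer[(j + 1) % nb], outer[j % nb]))
            j += 1
    return np.asarray(tris, dtype=np.int64)


def build_mesh(
    geometry: NerveGeometry,
    mode: str = "2d",
    target_elements: int = 5000,
    n_electrodes: int = N_ELECTRODES,
    electrode_coverage: float = 0.5,
    contact_impedance: float = 1e-3 * (np.pi * 3e-3 / 14 * 0.5 * 3e-3),
    thickness: float = 3e-3,
    include_exterior: bool = False,
) -> Mesh:
    """Build the structured cross-sectional CEM mesh.

    Parameters
    ----------
    electrode_coverage:
        Fraction of the inter-electrode pitch covered by each electrode arc.
    contact_impedance:
        Electrode contact impedance in Ohm*m^2.  The default corresponds to
        1 kOhm lumped impedance times the default electrode contact area.
    include_exterior:
        Also mesh the insulating-cuff annulus and the saline annulus (out to
        the saline outer diameter).  Electrode arcs stay on the nerve
        circumference; the cuff annulus is near-insulating so the saline
        carries essentially no current at cuff level.
    """
    if mode == "3d":
        raise NotImplementedError(
            "only the 2D cross-sectional mode is implemented; the "
            "reconstruction, localization and co-registration stages are all "
            "cross-sectional"
        )
    if mode != "2d":
        raise ValueError(f"unknown mesh mode {mode!r}")
    if target_elements < 500:
        raise ValueError("target_elements must be >= 500")
    if geometry.nerve_diameter <= 0:
        raise MeshError(f"degenerate nerve diameter in {geometry}")
    if not 0 < electrode_coverage < 1:
        raise ValueError("electrode_coverage must be in (0, 1)")

    R = geometry.nerve_radius
    interior_target = target_elements
    if include_exterior:
        # keep roughly the requested density; exterior adds area
        r_out = 0.5 * geometry.saline_outer_diameter
        interior_target = max(500, int(target_elements * R**2 / r_out**2))
    m, counts = _ring_counts(interior_target, n_electrodes)

    nodes = [np.zeros((1, 2))]
    ring_start = [None]  # per ring: (start index, count)
    n_total = 1
    radii = R * np.arange(1, m + 1) / m
    all_counts = list(n_electrodes * counts)
    all_radii = list(radii)

    if include_exterior:
        dr = R / m
        r_cuff_out = 0.5 * geometry.saline_inner_diameter
        r_sal_out = 0.5 * geometry.saline_outer_diameter
        n_cuff = max(2, round((r_cuff_out - R) / dr))
        n_sal = max(2, round((r_sal_out - r_cuff_out) / dr))
        ext_radii = np.concatenate([
            R + (r_cuff_out - R) * np.arange(1, n_cuff + 1) / n_cuff,
            r_cuff_out + (r_sal_out - r_cuff_out) * np.arange(1, n_sal + 1) / n_sal,
        ])
        c_bound = counts[-1]
        for r in ext_radii:
            all_radii.append(r)
            all_counts.append(n_electrodes * max(1, round(c_bound * r / R)))

    ring_info = []
    for r, n_ring in zip(all_radii, all_counts):
        theta = 2.0 * np.pi * np.arange(n_ring) / n_ring
        nodes.append(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
        ring_info.append((n_total, n_ring))
        n_total += n_ring
    nodes = np.vstack(nodes)

    # center fan
    first_start, first_n = ring_info[0]
    fan = np.array([
        (0, first_start + i, first_start + (i + 1) % first_n)
        for i in range(first_n)
    ], dtype=np.int64)
    tris = [fan]  # orientation fixed globally below
    for (s0, n0), (s1, n1) in zip(ring_info[:-1], ring_info[1:]):
        inner = s0 + np.arange(n0)
        outer = s1 + np.arange(n1)
        tris.append(_strip_triangles(inner, outer))
    elements = np.vstack(tris)

    # enforce CCW orientation
    p = nodes[elements]
    signed = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
              - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    if np.any(np.abs(signed) <= 0):
        raise MeshError(f"degenerate element produced for {geometry}")

    cent = nodes[elements].mean(axis=1)
    rc = np.hypot(cent[:, 0], cent[:, 1])
    region = np.full(elements.shape[0], REGION_NERVE, dtype=np.int8)
    if include_exterior:
        region[rc > R * (1 + 1e-9)] = REGION_CUFF
        region[rc > 0.5 * geometry.saline_inner_diameter] = REGION_SALINE

    # electrode arcs: consecutive edges on the nerve-circumference ring
    ring_idx = m - 1  # ring at radius R
    s_b, n_b = ring_info[ring_idx]
    bnodes = s_b + np.arange(n_b)
    bangles = np.degrees(np.arctan2(nodes[bnodes, 1], nodes[bnodes, 0])) % 360.0
    centers = electrode_angles_deg(n_electrodes)
    half_arc = 0.5 * electrode_coverage * (360.0 / n_electrodes)
    electrode_edges = []
    for c in centers:
        edges = []
        for i in range(n_b):
            j = (i + 1) % n_b
            mid = np.degrees(np.arctan2(
                nodes[bnodes[i], 1] + nodes[bnodes[j], 1],
                nodes[bnodes[i], 0] + nodes[bnodes[j], 0])) % 360.0
            d = abs((mid - c + 180.0) % 360.0 - 180.0)
            if d <= half_arc:
                edges.append((bnodes[i], bnodes[j]))
        if not edges:
            raise MeshError(
                "electrode arc contains no boundary edge; increase "
                "target_elements or electrode_coverage")
        electrode_edges.append(np.asarray(edges, dtype=np.int64))

    # ground node: boundary node nearest the cuff opening
    op = np.radians(CUFF_OPENING_DEG)
    d_open = np.hypot(nodes[bnodes, 0] - R * np.cos(op),
                      nodes[bnodes, 1] - R * np.sin(op))
    ground = int(bnodes[np.argmin(d_open)])

    return Mesh(
        nodes=nodes, elements=elements, region=region,
        electrode_edges=electrode_edges, electrode_angle_deg=centers,
        contact_impedance=np.full(n_electrodes, contact_impedance),
        thickness=thickness, ground_node=ground, nerve_radius=R,
    )


# ---------------------------------------------------------------------------
# CEM assembly and solve


def _p1_gradients(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element constant gradients of the three P1 basis functions.

    Returns (grads, areas) with grads of shape (M, 3, 2).
    """
    p = mesh.nodes[mesh.elements]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    twoA = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    grads = np.stack([b, c], axis=2) / twoA[:, None, None]
    return grads, 0.5 * np.abs(twoA)


def _assemble_system(mesh: Mesh, sigma: np.ndarray) -> sp.csc_matrix:
    """CEM system matrix over (node potentials, electrode voltages)."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (mesh.n_elements,):
        raise ValueError("conductivity must be per-element")
    if np.any(sigma <= 0):
        raise ValueError("conductivities must be positive")
    grads, areas = _p1_gradients(mesh)
    t = mesh.thickness
    # stiffness: sum_e sigma*t*A * grad_i . grad_j
    ke = np.einsum("eid,ejd->eij", grads, grads) * (sigma * t * areas)[:, None, None]
    rows = np.repeat(mesh.elements, 3, axis=1).ravel()
    cols = np.tile(mesh.elements, (1, 3)).ravel()
    N, L = mesh.n_nodes, mesh.n_electrodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(N, N)).tocsr()

    r_, c_, v_ = [], [], []
    er_, ec_, ev_ = [], [], []
    dd = np.zeros(L)
    for l, edges in enumerate(mesh.electrode_edges):
        zl = mesh.contact_impedance[l]
        a, b = edges[:, 0], edges[:, 1]
        seg = np.hypot(*(mesh.nodes[b] - mesh.nodes[a]).T)
        w = t / zl
        # 1D mass matrix on each edge: L/6 [[2,1],[1,2]]
        for (i, j, f) in ((a, a, 2.0), (b, b, 2.0), (a, b, 1.0), (b, a, 1.0)):
            r_.append(i); c_.append(j); v_.append(w * seg / 6.0 * f)
        # node-electrode coupling: -(t/z) * integral of phi
        er_.append(np.concatenate([a, b]))
        ec_.append(np.full(2 * len(a), l))
        ev_.append(np.concatenate([-w * seg / 2.0, -w * seg / 2.0]))
        dd[l] = w * seg.sum()
    Mz = sp.coo_matrix((np.concatenate(v_),
                        (np.concatenate(r_), np.concatenate(c_))),
                       shape=(N, N)).tocsr()
    Cne = sp.coo_matrix((np.concatenate(ev_),
                         (np.concatenate(er_), np.concatenate(ec_))),
                        shape=(N, L)).tocsr()
    D = sp.diags(dd)
    S = sp.bmat([[K + Mz, Cne], [Cne.T, D]], format="lil")

    g = mesh.ground_node
    S[g, :] = 0.0
    S[:, g] = 0.0
    S[g, g] = 1.0
    return S.tocsc()


class CEMOperator:
    """Factorized CEM forward operator for one conductivity distribution."""

    def __init__(self, mesh: Mesh, sigma: np.ndarray):
        self.mesh = mesh
        self.sigma = np.asarray(sigma, dtype=float)
        S = _assemble_system(mesh, self.sigma)
        try:
            self._lu = splu(S)
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise SolverError(f"CEM system is singular: {exc}") from exc

    def solve_currents(self, currents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Solve for one or more electrode-current patterns.

        Parameters
        ----------
        currents:
            (L,) or (L, P) array of per-electrode currents in amperes; each
            pattern must sum to zero.

        Returns
        -------
        (node potentials (N, P), electrode voltages (L, P))
        """
        I = np.atleast_2d(np.asarray(currents, dtype=float).T).T
        if I.shape[0] != self.mesh.n_electrodes:
            raise ValueError("current pattern length != electrode count")
        if np.any(np.abs(I.sum(axis=0)) > 1e-12 * np.abs(I).max()):
            raise ValueError("electrode currents must sum to zero")
        N = self.mesh.n_nodes
        rhs = np.zeros((N + I.shape[0], I.shape[1]))
        rhs[N:] = I
        rhs[self.mesh.ground_node] = 0.0
        sol = self._lu.solve(rhs)
        return sol[:N], sol[N:]


def solve_cem(mesh: Mesh, sigma: np.ndarray, injection_pair: tuple[int, int],
              current: float = 200e-6) -> tuple[np.ndarray, np.ndarray]:
    """Solve one pair injection; returns (node potentials, electrode voltages)."""
    a, b = injection_pair
    if a == b:
        raise ValueError("injection electrodes must be distinct")
    I = np.zeros(mesh.n_electrodes)
    I[a], I[b] = current, -current
    u, v = CEMOperator(mesh, sigma).solve_currents(I)
    return u[:, 0], v[:, 0]


def skip_protocol(n_electrodes: int = N_ELECTRODES,
                  skip: int = PROTOCOL_SKIP) -> list[tuple[int, int]]:
    """Skip-k injection pairs in consecutive radial order."""
    return [(k, (k + skip) % n_electrodes) for k in range(n_electrodes)]


def measurement_table(n_electrodes: int = N_ELECTRODES,
                      skip: int = PROTOCOL_SKIP) -> pd.DataFrame:
    """Pair-major, electrode-minor index table for the 196 measurements."""
    rows = []
    for k, (a, b) in enumerate(skip_protocol(n_electrodes, skip)):
        for e in range(n_electrodes):
            rows.append((k, a, b, e))
    return pd.DataFrame(rows, columns=["pair", "inj_a", "inj_b", "electrode"])


def _injection_patterns(n_electrodes: int, skip: int, current: float) -> np.ndarray:
    pats = np.zeros((n_electrodes, n_electrodes))
    for k, (a, b) in enumerate(skip_protocol(n_electrodes, skip)):
        pats[a, k], pats[b, k] = current, -current
    return pats


def _measurement_patterns(n_electrodes: int, reference: str) -> np.ndarray:
    """Unit-current adjoint patterns matching the voltage reference."""
    if reference == "mean":
        return np.eye(n_electrodes) - 1.0 / n_electrodes
    if reference == "ground":
        raise ValueError(
            "ground-referenced measurements have no zero-sum adjoint pattern; "
            "use reference='mean'")
    raise ValueError(f"unknown reference {reference!r}")


def protocol_voltages(mesh: Mesh, sigma: np.ndarray,
                      current: float = 200e-6, skip: int = PROTOCOL_SKIP,
                      reference: str = "mean") -> tuple[np.ndarray, pd.DataFrame]:
    """Baseline transfer voltages for the full skip protocol.

    Returns the 196-vector (pair-major, electrode-minor) of electrode
    voltages relative to the quasi-tripolar reference (mean of all cuff
    electrodes) and the measurement index table.
    """
    L = mesh.n_electrodes
    op = CEMOperator(mesh, sigma)
    _, V = op.solve_currents(_injection_patterns(L, skip, current))
    if reference == "mean":
        V = V - V.mean(axis=0, keepdims=True)
    elif reference != "ground":
        raise ValueError(f"unknown reference {reference!r}")
    # V[e, k] -> pair-major flatten
    return V.T.ravel().copy(), measurement_table(L, skip)


@dataclass
class VoxelGrid:
    """Square-voxel grid over the nerve cross-section (2D hexahedral analog)."""

    voxel_size: float
    centers: np.ndarray          # (V, 2) meters
    nerve_radius: float
    empty: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return self.centers.shape[0]


@dataclass
class JacobianMatrix:
    """Sensitivity of each measurement to fractional conductivity change.

    ``matrix`` has shape (n_measurements, n_voxels-or-elements) in volts per
    unit fractional conductivity change (d sigma / sigma).
    """

    matrix: np.ndarray
    index: pd.DataFrame
    grid: VoxelGrid | None = None

    @property
    def n_measurements(self) -> int:
        return self.matrix.shape[0]


def assemble_jacobian(mesh: Mesh, sigma: np.ndarray,
                      current: float = 200e-6, skip: int = PROTOCOL_SKIP,
                      reference: str = "mean") -> JacobianMatrix:
    """Adjoint-method Jacobian on the FEM elements.

    J[(k, e), m] = -sigma_m * t * A_m * grad(u_k) . grad(w_e), the change of
    measurement (k, e) per unit fractional conductivity change of element m;
    u_k is the injection field at the protocol current and w_e the adjoint
    (unit-current measurement-pattern) field.
    """
    L = mesh.n_electrodes
    op = CEMOperator(mesh, sigma)
    U, _ = op.solve_currents(_injection_patterns(L, skip, current))
    W, _ = op.solve_currents(_measurement_patterns(L, reference))
    grads, areas = _p1_gradients(mesh)
    # per-element gradient of each solution: (M, 2, P)
    gU = np.einsum("eid,eip->edp", grads, U[mesh.elements])
    gW = np.einsum("eid,eip->edp", grads, W[mesh.elements])
    scale = sigma * mesh.thickness * areas
    # J[(k,e), m] pair-major
    J = -np.einsum("mdk,mde,m->kem", gU, gW, scale).reshape(L * L, -1)
    return JacobianMatrix(matrix=J, index=measurement_table(L, skip))


def make_voxel_grid(nerve_radius: float, voxel_size: float = 150e-6) -> np.ndarray:
    """Candidate voxel centers: cells of an origin-centered grid whose center
    lies inside the nerve disk."""
    n = int(np.ceil(nerve_radius / voxel_size))
    idx = np.arange(-n, n)
    cx, cy = np.meshgrid((idx + 0.5) * voxel_size, (idx + 0.5) * voxel_size)
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    keep = np.hypot(centers[:, 0], centers[:, 1]) <= nerve_radius
    return centers[keep]


def voxelize_jacobian(J_fem: JacobianMatrix, mesh: Mesh,
                      voxel_size: float = 150e-6) -> JacobianMatrix:
    """Convert the element Jacobian to the coarse square-voxel grid.

    Each nerve element contributes its whole column to the voxel containing
    its centroid, so total sensitivity is conserved exactly.  Voxels inside
    the nerve that receive no element (possible on very coarse meshes) are
    kept as zero columns and flagged in ``grid.empty``.
    """
    cent = mesh.element_centroids()
    nerve = mesh.region == REGION_NERVE
    R = mesh.nerve_radius

    def cell_of(pts: np.ndarray) -> np.ndarray:
        return np.floor(pts / voxel_size).astype(np.int64)

    centers = make_voxel_grid(R, voxel_size)
    cells = {tuple(c): i for i, c in enumerate(cell_of(centers))}
    extra = []
    el_cells = cell_of(cent[nerve])
    for c in map(tuple, el_cells):
        if c not in cells:
            cells[c] = len(centers) + len(extra)
            extra.append(((c[0] + 0.5) * voxel_size, (c[1] + 0.5) * voxel_size))
    if extra:
        centers = np.vstack([centers, np.asarray(extra)])

    V = len(centers)
    Jv = np.zeros((J_fem.matrix.shape[0], V))
    cols = np.array([cells[tuple(c)] for c in map(tuple, el_cells)])
    np.add.at(Jv.T, cols, J_fem.matrix.T[nerve])
    filled = np.zeros(V, dtype=bool)
    filled[cols] = True
    grid = VoxelGrid(voxel_size=voxel_size, centers=centers,
                     nerve_radius=R, empty=~filled)
    return JacobianMatrix(matrix=Jv, index=J_fem.index.copy(), grid=grid)
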