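"""Plane-stress constant-strain-triangle finite elements on pixel masks.

The Bone Strain Index is computed from a 2D linear-elastic solve on a mesh
derived directly from the DXA bone segmentation: every in-mask pixel (or
``refinement x refinement`` sub-pixel) is split into two triangles along its
NW-SE diagonal, each triangle carrying the areal density of its owner pixel.
Plane stress with unit out-of-plane thickness is assumed throughout — the
input is a 2D projection, so a 2D idealization is the natural model.

Conventions
-----------
* Physical coordinates: ``x = col * spacing``, ``y = (nrows - row) * spacing``
  (y grows upward, origin at the grid's bottom-left corner), 0-based
  half-open pixel indexing.
* Strain vectors are ``(eps_x, eps_y, gamma_xy)`` with engineering shear.
* Units: lengths cm, forces N, moduli N/cm² (1 MPa = 100 N/cm²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "TriMesh",
    "BoundarySpec",
    "StrainField",
    "SingularStiffnessError",
    "mesh_from_mask",
    "boundary_edges",
    "morgan_modulus",
    "MORGAN_COEFFS",
    "solve_plane_elastic",
    "equivalent_strain",
    "MPA_TO_N_PER_CM2",
]

MPA_TO_N_PER_CM2 = 100.0

#: Site-specific density-to-modulus power laws E = a * rho^b
#: (E in MPa, apparent density rho in g/cm³); fully configurable.
MORGAN_COEFFS = {"vertebra": (4730.0, 1.56), "femur": (6850.0, 1.49)}


class SingularStiffnessError(RuntimeError):
    """Stiffness system is singular (rigid-body modes not constrained)."""


@dataclass
class TriMesh:
    """Triangle mesh over a pixel mask.

    ``nodes`` is (n, 2) physical coordinates; ``elements`` (m, 3) node index
    triples, positively (counter-clockwise) oriented; ``element_density``
    the areal density (g/cm²) sampled at each element's owner pixel;
    ``element_owner`` the (row, col) owner pixel of each element.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_density: np.ndarray
    element_owner: np.ndarray
    pixel_spacing: float
    grid_shape: tuple[int, int]
    refinement: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def areas(self) -> np.ndarray:
        """Signed triangle areas (positive for a valid mesh)."""
        p = self.nodes[self.elements]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def element_labels(self, label_grid: np.ndarray) -> np.ndarray:
        """Per-element label sampled from a pixel label grid (e.g. ROI ids)."""
        return np.asarray(label_grid)[self.element_owner[:, 0], self.element_owner[:, 1]]


@dataclass
class BoundarySpec:
    """Dirichlet constraints and edge tractions.

    ``fixed`` maps node index -> (fix_x, fix_y); ``edge_tractions`` is a list
    of ``((n1, n2), (tx, ty))`` with traction in N/cm of edge length.
    """

    fixed: dict[int, tuple[bool, bool]] = field(default_factory=dict)
    edge_tractions: list[tuple[tuple[int, int], tuple[float, float]]] = field(
        default_factory=list
    )

    def validate(self, n_nodes: int) -> None:
        loaded = {n for (edge, _) in self.edge_tractions for n in edge}
        for n in list(self.fixed) + sorted(loaded):
            if not 0 <= n < n_nodes:
                raise ValueError(f"node index {n} out of range")
        overlap = loaded & {
            n for n, (fx, fy) in self.fixed.items() if fx and fy
        }
        if overlap:
            raise ValueError(
                f"nodes {sorted(overlap)} are both fully fixed and loaded"
            )


@dataclass
class StrainField:
    """Element-wise strain state from a plane-stress solve."""

    strain: np.ndarray  # (m, 3): eps_x, eps_y, gamma_xy
    equivalent: np.ndarray  # (m,) von Mises equivalent strain, >= 0
    displacements: np.ndarray  # (n, 2)
    reactions: np.ndarray  # (n, 2), nonzero only at constrained dofs
    applied: np.ndarray  # (n, 2) consistent nodal loads


def mesh_from_mask(
    mask: np.ndarray,
    pixel_spacing: float,
    refinement: int = 1,
    density: np.ndarray | None = None,
) -> TriMesh:
    """Triangulate a 4-connected binary mask.

    Each pixel is subdivided into ``refinement²`` square cells, each split
    into two triangles along the NW-SE diagonal (deterministic tie-break).
    ``density`` (same shape as ``mask``) supplies per-element areal density
    from the owner pixel; defaults to 1 everywhere.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be a nonempty 2D binary array")
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    n_comp = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
    if n_comp != 1:
        raise ValueError(f"mask must be one 4-connected component, found {n_comp}")
    nrow, ncol = mask.shape
    r = refinement
    h = pixel_spacing / r

    cell_rows, cell_cols = np.nonzero(np.repeat(np.repeat(mask, r, 0), r, 1))
    # fine-lattice corner ids on a ((nrow*r)+1) x ((ncol*r)+1) grid
    ncols_fine = ncol * r + 1

    def nid(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return i * ncols_fine + j

    nw = nid(cell_rows, cell_cols)
    ne = nid(cell_rows, cell_cols + 1)
    sw = nid(cell_rows + 1, cell_cols)
    se = nid(cell_rows + 1, cell_cols + 1)
    # CCW in physical coordinates (y flips the image row axis)
    tris = np.concatenate(
        [np.stack([nw, se, ne], axis=1), np.stack([nw, sw, se], axis=1)]
    )
    owners = np.concatenate([np.stack([cell_rows // r, cell_cols // r], axis=1)] * 2)

    used, inverse = np.unique(tris, return_inverse=True)
    elements = inverse.reshape(tris.shape)
    fi, fj = np.divmod(used, ncols_fine)
    nodes = np.stack([fj * h, (nrow * r - fi) * h], axis=1).astype(float)

    if density is None:
        dens = np.ones(len(elements))
    else:
        density = np.asarray(density, dtype=float)
        dens = density[owners[:, 0], owners[:, 1]]

    mesh = TriMesh(
        nodes=nodes,
        elements=elements,
        element_density=dens,
        element_owner=owners,
        pixel_spacing=pixel_spacing,
        grid_shape=(nrow, ncol),
        refinement=r,
    )
    if np.any(mesh.areas() <= 0):
        raise RuntimeError("mesh contains non-positively-oriented triangles")
    return mesh


def boundary_edges(mesh: TriMesh) -> np.ndarray:
    """Exterior edges (appearing in exactly one triangle), as (k, 2) node ids."""
    e = mesh.elements
    edges = np.concatenate([e[:, [0, 1]], e[:, [1, 2]], e[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return uniq[counts == 1]


def morgan_modulus(
    apparent_density: np.ndarray | float,
    site: str = "vertebra",
    coeffs: tuple[float, float] | None = None,
    floor_modulus: float = 1.0,
) -> np.ndarray | float:
    """Density-to-modulus power law ``E = a * rho^b`` (MPa, rho in g/cm³).

    Non-positive densities get ``floor_modulus`` (MPa) with a warning rather
    than a NaN: a masked-out or radiolucent pixel should degrade gracefully.
    """
    if coeffs is None:
        try:
            coeffs = MORGAN_COEFFS[site]
        except KeyError:
            raise ValueError(f"unknown site {site!r}") from None
    a, b = coeffs
    rho = np.asarray(apparent_density, dtype=float)
    scalar = rho.ndim == 0
    rho = np.atleast_1d(rho)
    bad = rho <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive densities floored to E = {floor_modulus} MPa",
            stacklevel=2,
        )
    E = np.where(bad, floor_modulus, a * np.power(np.where(bad, 1.0, rho), b))
    return float(E[0]) if scalar else E


def _cst_b_matrices(nodes: np.ndarray, elements: np.ndarray):
    p = nodes[elements]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    )
    c = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    )
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    m = len(elements)
    B = np.zeros((m, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    B /= area2[:, None, None]
    return B, area2 / 2.0


def solve_plane_elastic(
    mesh: TriMesh,
    modulus: np.ndarray | float,
    poisson: float,
    boundary: BoundarySpec,
    thickness: float = 1.0,
) -> StrainField:
    """Static linear plane-stress solve; returns element strains.

    ``modulus`` is per-element (or scalar) in N/cm².  Raises
    :class:`SingularStiffnessError` if the constraints leave rigid-body
    modes (checked via the relative equilibrium residual).
    """
    boundary.validate(mesh.n_nodes)
    E = np.broadcast_to(np.asarray(modulus, dtype=float), (mesh.n_elements,))
    nu = float(poisson)
    m = mesh.n_elements

    B, area = _cst_b_matrices(mesh.nodes, mesh.elements)
    fac = E / (1.0 - nu**2)
    D = np.zeros((m, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = fac
    D[:, 0, 1] = D[:, 1, 0] = fac * nu
    D[:, 2, 2] = fac * (1.0 - nu) / 2.0
    Ke = thickness * area[:, None, None] * np.einsum("eji,ejk,ekl->eil", B, D, B)

    dofs = np.empty((m, 6), dtype=int)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    ndof = 2 * mesh.n_nodes
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()

    f = np.zeros(ndof)
    for (n1, n2), (tx, ty) in boundary.edge_tractions:
        L = float(np.linalg.norm(mesh.nodes[n2] - mesh.nodes[n1]))
        for n in (n1, n2):
            f[2 * n] += thickness * tx * L / 2.0
            f[2 * n + 1] += thickness * ty * L / 2.0

    constrained = np.zeros(ndof, dtype=bool)
    for n, (fx, fy) in boundary.fixed.items():
        if fx:
            constrained[2 * n] = True
        if fy:
            constrained[2 * n + 1] = True
    if not constrained.any():
        raise SingularStiffnessError("no Dirichlet constraints: rigid-body modes free")

    free = ~constrained
    u = np.zeros(ndof)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sparse.linalg.MatrixRankWarning)
        try:
            u[free] = spsolve(K[free][:, free].tocsc(), f[free])
        except (sparse.linalg.MatrixRankWarning, RuntimeError) as exc:
            raise SingularStiffnessError(
                f"stiffness matrix is singular under the given constraints: {exc}"
            ) from exc
    if not np.all(np.isfinite(u)):
        raise SingularStiffnessError("solution is not finite; system under-constrained")

    residual = K @ u - f
    rel = np.linalg.norm(residual[free]) / max(np.linalg.norm(f), 1e-30)
    if rel > 1e-8:
        raise SingularStiffnessError(
            f"equilibrium residual {rel:.2e} exceeds 1e-8; system ill-conditioned"
        )

    reactions = np.where(constrained, residual, 0.0)
    strain = np.einsum("eij,ej->ei", B, u[dofs])
    eq = equivalent_strain(strain, nu)
    return StrainField(
        strain=strain,
        equivalent=eq,
        displacements=u.reshape(-1, 2),
        reactions=reactions.reshape(-1, 2),
        applied=f.reshape(-1, 2),
    )


def equivalent_strain(strain: np.ndarray, poisson: float) -> np.ndarray | float:
    """Von Mises equivalent strain of plane-stress strain state(s).

    ``strain`` is (..., 3) as (eps_x, eps_y, gamma_xy) with engineering
    shear.  The out-of-plane normal strain is recovered from the plane-stress
    condition, ``eps_z = -nu (eps_x + eps_y) / (1 - nu)``, and the scalar is
    ``sqrt(2/3 * e:e)`` with ``e`` the deviatoric strain tensor — zero iff
    the strain state is zero, invariant to in-plane rotations.
    """
    s = np.asarray(strain, dtype=float)
    scalar = s.ndim == 1
    s = np.atleast_2d(s)
    if not np.all(np.isfinite(s)):
        raise ValueError("strain components must be finite")
    nu = float(poisson)
    ex, ey, gxy = s[..., 0], s[..., 1], s[..., 2]
    ez = -nu * (ex + ey) / (1.0 - nu)
    em = (ex + ey + ez) / 3.0
    dev = (ex - em) ** 2 + (ey - em) ** 2 + (ez - em) ** 2 + 0.5 * gxy**2
    out = np.sqrt(2.0 / 3.0 * dev)
    return float(out[0]) if scalar else out
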