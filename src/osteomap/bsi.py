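"""Bone Strain Index: ROI-averaged equivalent strain from the DXA-style FEM.

The BSI of a region of interest is the element-area-weighted mean von Mises
equivalent strain from a plane-stress linear-elastic solve, multiplied by a
dimensionless scale constant.  Higher BSI means a bone that strains more
under its physiological load, i.e. a mechanically weaker bone; a density
increase at fixed geometry strictly lowers it.

Load cases
----------
vertebra
    Axial compression: a fraction of body weight (standing trunk load,
    ``standing_load_fraction``, default 0.6) applied as uniform downward
    traction on the superior endplate; the inferior endplate rests on
    frictionless rollers (vertical support, one node pinned horizontally).
    A fully clamped inferior endplate is available via
    ``vertebra_constraint='fixed'``.
foemur / sideways fall
    Femoral head and distal shaft section constrained; a horizontal,
    medially directed load of one body weight distributed over the greater
    trochanteric arc.

Absolute BSI units are set by the scale constant (default 1.0, raw strain);
:func:`calibrate_scale` rescales so a reference vertebral phantom at the
population-mean lumbar BMD yields the population-mean lumbar BSI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fem import (
    MORGAN_COEFFS,
    MPA_TO_N_PER_CM2,
    BoundarySpec,
    StrainField,
    TriMesh,
    boundary_edges,
    mesh_from_mask,
    morgan_modulus,
    solve_plane_elastic,
)
from .phantom import DensityPhantom, generate_phantom

__all__ = ["BSIConfig", "BSIResult", "compute_bsi", "calibrate_scale", "CALIBRATION"]

#: Population-mean (BMD, BSI) pairs anchoring the calibration helper per site.
CALIBRATION = {"vertebra": (0.813, 2.298), "femur": (0.773, 1.638)}
CALIBRATION_BSI = CALIBRATION["vertebra"][1]

GRAVITY = 9.81  # m/s², load = weight [kg] * g -> N


@dataclass(frozen=True)
class BSIConfig:
    """Material, load and discretization settings for a BSI computation."""

    poisson: float = 0.3
    refinement: int = 2
    scale: float = 1.0
    #: effective projection thickness (cm) converting areal to apparent density
    effective_thickness: dict = field(
        default_factory=lambda: {"vertebra": 3.0, "femur": 3.5}
    )
    morgan_coeffs: dict = field(default_factory=lambda: dict(MORGAN_COEFFS))
    #: trunk-load fraction of body weight on a lumbar vertebra, standing
    standing_load_fraction: float = 0.6
    #: sideways-fall load on the trochanter, as multiple of body weight
    fall_load_multiple: float = 1.0
    vertebra_constraint: str = "roller"  # or "fixed"
    floor_modulus: float = 1.0  # MPa, for non-positive densities
    load_override: float | None = None  # total load in N, bypassing weight


@dataclass
class BSIResult:
    """Per-ROI Bone Strain Index values from one FEM solve."""

    values: dict[int, float]
    site: str
    load_magnitude: float  # N
    mean_equivalent_strain: dict[int, float]  # unscaled
    scale: float
    mesh: TriMesh | None = None
    field: StrainField | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "roi": list(self.values),
                "bsi": list(self.values.values()),
                "mean_equivalent_strain": [
                    self.mean_equivalent_strain[k] for k in self.values
                ],
                "site": self.site,
                "load_N": self.load_magnitude,
            }
        )


def _vertebra_boundary(mesh: TriMesh, total_load: float, constraint: str) -> BoundarySpec:
    y = mesh.nodes[:, 1]
    tol = 1e-9 * max(1.0, y.max())
    ext = boundary_edges(mesh)
    top = ext[
        (np.abs(y[ext[:, 0]] - y.max()) < tol) & (np.abs(y[ext[:, 1]] - y.max()) < tol)
    ]
    if len(top) == 0:
        raise ValueError("vertebra phantom has no superior edge to load")
    width = float(
        np.sum(np.linalg.norm(mesh.nodes[top[:, 1]] - mesh.nodes[top[:, 0]], axis=1))
    )
    traction = (0.0, -total_load / width)
    bottom_nodes = np.nonzero(np.abs(y - y.min()) < tol)[0]
    if constraint == "fixed":
        fixed = {int(n): (True, True) for n in bottom_nodes}
    elif constraint == "roller":
        fixed = {int(n): (False, True) for n in bottom_nodes}
        pin = int(bottom_nodes[np.argmin(mesh.nodes[bottom_nodes, 0])])
        fixed[pin] = (True, True)
    else:
        raise ValueError("vertebra_constraint must be 'roller' or 'fixed'")
    return BoundarySpec(
        fixed=fixed, edge_tractions=[((int(a), int(b)), traction) for a, b in top]
    )


def _femur_boundary(mesh: TriMesh, total_load: float) -> BoundarySpec:
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    w, h = x.max() - x.min(), y.max() - y.min()
    # head: medial-most band of nodes; distal: inferior edge of the shaft
    head = np.nonzero(x <= x.min() + 0.10 * w)[0]
    distal = np.nonzero(y <= y.min() + 0.05 * h)[0]
    fixed = {int(n): (True, True) for n in np.concatenate([head, distal])}
    ext = boundary_edges(mesh)
    mid = 0.5 * (mesh.nodes[ext[:, 0]] + mesh.nodes[ext[:, 1]])
    lateral = ext[
        (mid[:, 0] >= x.max() - 0.08 * w)
        & (mid[:, 1] >= y.min() + 0.55 * h)
        & (mid[:, 1] <= y.min() + 0.80 * h)
    ]
    if len(lateral) == 0:
        raise ValueError("femur phantom has no trochanteric arc to load")
    arc_len = float(
        np.sum(
            np.linalg.norm(mesh.nodes[lateral[:, 1]] - mesh.nodes[lateral[:, 0]], axis=1)
        )
    )
    traction = (-total_load / arc_len, 0.0)  # medially directed
    return BoundarySpec(
        fixed=fixed,
        edge_tractions=[((int(a), int(b)), traction) for a, b in lateral],
    )


def compute_bsi(
    phantom: DensityPhantom,
    config: BSIConfig | None = None,
    keep_field: bool = False,
) -> BSIResult:
    """Run the site-appropriate load case and average strain per ROI."""
    config = config or BSIConfig()
    site = phantom.site
    mesh = mesh_from_mask(
        phantom.bone_mask,
        phantom.pixel_spacing,
        refinement=config.refinement,
        density=phantom.grid,
    )
    t_eff = config.effective_thickness[site]
    rho_app = mesh.element_density / t_eff  # g/cm³
    E_mpa = morgan_modulus(
        rho_app,
        site=site,
        coeffs=config.morgan_coeffs[site],
        floor_modulus=config.floor_modulus,
    )
    E = np.asarray(E_mpa) * MPA_TO_N_PER_CM2

    if config.load_override is not None:
        load = float(config.load_override)
    elif site == "vertebra":
        load = config.standing_load_fraction * phantom.weight * GRAVITY
    else:
        load = config.fall_load_multiple * phantom.weight * GRAVITY
    if site == "vertebra":
        boundary = _vertebra_boundary(mesh, load, config.vertebra_constraint)
    else:
        boundary = _femur_boundary(mesh, load)

    field = solve_plane_elastic(mesh, E, config.poisson, boundary)
    labels = mesh.element_labels(phantom.roi_labels)
    areas = mesh.areas()
    raw: dict[int, float] = {}
    for roi in phantom.roi_ids:
        sel = labels == roi
        raw[roi] = float(
            np.sum(areas[sel] * field.equivalent[sel]) / np.sum(areas[sel])
        )
    values = {roi: config.scale * v for roi, v in raw.items()}
    return BSIResult(
        values=values,
        site=site,
        load_magnitude=load,
        mean_equivalent_strain=raw,
        scale=config.scale,
        mesh=mesh if keep_field else None,
        field=field if keep_field else None,
    )


def calibrate_scale(
    config: BSIConfig | None = None,
    site: str = "vertebra",
    target: float | None = None,
    target_bmd: float | None = None,
    weight: float = 60.0,
    height: float = 160.0,
) -> BSIConfig:
    """Return a config whose scale maps the calibration phantom to ``target``.

    The calibration phantom is a noise-free phantom of the given site at the
    population-mean BMD carried by an average-build patient; the default
    target is the population-mean BSI of that site.
    """
    config = config or BSIConfig()
    cal_bmd, cal_bsi = CALIBRATION[site]
    target = cal_bsi if target is None else target
    target_bmd = cal_bmd if target_bmd is None else target_bmd
    phantom = generate_phantom(
        site=site,
        target_bmd=target_bmd,
        noise_sd=0.0,
        weight=weight,
        height=height,
    )
    raw = compute_bsi(phantom, replace(config, scale=1.0)).values[1]
    return replace(config, scale=target / raw)
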