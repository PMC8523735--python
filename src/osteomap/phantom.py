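"""2D areal-density phantoms standing in for DXA scans.

A phantom is a raster of areal bone mineral density (g/cm²) with a binary
bone mask and integer ROI labels, plus the patient covariates (weight,
height) that set the mechanical load.  Two parametric sites are provided:

* ``vertebra`` — a rectangular vertebral body (the FEM load case compresses
  it axially, mimicking standing);
* ``femur`` — a simplified proximal femur silhouette (vertical shaft, angled
  neck, circular head) for the sideways-fall load case.

Density inside the mask is ``target_bmd`` plus optional smooth lateral
modulation and pixel noise, clipped at zero; the in-mask mean is re-centred
on ``target_bmd`` so the phantom's ROI BMD is exact when ``noise_sd == 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DensityPhantom", "generate_phantom", "save_phantom", "load_phantom"]

SITES = ("vertebra", "femur")


@dataclass
class DensityPhantom:
    """Areal-density grid with bone mask and ROI labels.

    ``grid`` is g/cm² (zero outside ``bone_mask``); ``roi_labels`` is zero
    outside ROIs and every labelled pixel lies inside the mask.
    """

    grid: np.ndarray
    pixel_spacing: float  # cm
    bone_mask: np.ndarray
    roi_labels: np.ndarray
    site: str
    weight: float  # kg
    height: float  # cm

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.bone_mask = np.asarray(self.bone_mask, dtype=bool)
        self.roi_labels = np.asarray(self.roi_labels, dtype=int)
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.grid.shape != self.bone_mask.shape != self.roi_labels.shape:
            raise ValueError("grid, bone_mask and roi_labels shapes must agree")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("density grid contains non-finite values")
        if np.any(self.grid < 0):
            raise ValueError("areal density must be >= 0")
        if np.any(self.grid[~self.bone_mask] != 0):
            raise ValueError("density must be zero outside the bone mask")
        if np.any((self.roi_labels != 0) & ~self.bone_mask):
            raise ValueError("ROI labels must lie inside the bone mask")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    def roi_bmd(self, label: int = 1) -> float:
        """Mean areal density (g/cm²) over one ROI."""
        sel = self.roi_labels == label
        if not sel.any():
            raise ValueError(f"ROI label {label} is empty")
        return float(self.grid[sel].mean())

    @property
    def roi_ids(self) -> list[int]:
        ids = np.unique(self.roi_labels)
        return [int(i) for i in ids if i != 0]


def _vertebra_mask(shape: tuple[int, int], rng: np.random.Generator | None) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[:, :] = True
    return mask


def _femur_mask(shape: tuple[int, int], spacing: float) -> np.ndarray:
    """Simplified proximal femur: shaft + 45-degree neck + head disc."""
    nrow, ncol = shape
    rows, cols = np.mgrid[0:nrow, 0:ncol]
    x = cols * spacing
    y = (nrow - 1 - rows) * spacing  # y grows upward
    w = ncol * spacing
    h = nrow * spacing
    mask = np.zeros(shape, dtype=bool)
    # vertical shaft along the lateral (right) side
    shaft_x0, shaft_x1 = 0.62 * w, 0.92 * w
    mask |= (x >= shaft_x0) & (x <= shaft_x1) & (y <= 0.72 * h)
    # neck: capsule from the head centre down into the upper shaft
    cx, cy = 0.30 * w, 0.78 * h  # head centre
    ax, ay = 0.77 * w, 0.60 * h  # attachment inside the shaft
    t = np.clip(
        ((x - cx) * (ax - cx) + (y - cy) * (ay - cy))
        / ((ax - cx) ** 2 + (ay - cy) ** 2),
        0.0,
        1.0,
    )
    neck = np.hypot(x - (cx + t * (ax - cx)), y - (cy + t * (ay - cy))) <= 0.10 * h
    mask |= neck
    # femoral head
    mask |= np.hypot(x - cx, y - cy) <= 0.16 * h
    return mask


def generate_phantom(
    site: str = "vertebra",
    target_bmd: float = 0.813,
    shape: tuple[int, int] = (36, 40),
    pixel_spacing: float = 0.1,
    gradient: float = 0.0,
    noise_sd: float = 0.0,
    weight: float = 60.0,
    height: float = 160.0,
    seed: int = 0,
) -> DensityPhantom:
    """Build a parametric density phantom.

    Parameters
    ----------
    site : {'vertebra', 'femur'}
    target_bmd : float
        Mask-mean areal density, g/cm²; must be positive.  Exact (to
        re-centring) when ``noise_sd == 0``.
    shape : (rows, cols)
        Raster size; with the default 0.1 cm spacing the vertebra phantom is
        4.0 cm wide and 3.6 cm tall, desk-scale but anatomically plausible.
    gradient : float
        Peak-to-centre relative smooth lateral density modulation (0 = flat).
    noise_sd : float
        Per-pixel Gaussian noise SD in g/cm².
    """
    if target_bmd <= 0:
        raise ValueError(f"target_bmd must be positive, got {target_bmd}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if site == "vertebra":
        mask = _vertebra_mask(shape, rng)
    elif site == "femur":
        mask = _femur_mask(shape, pixel_spacing)
    else:
        raise ValueError(f"site must be one of {SITES}, got {site!r}")

    nrow, ncol = shape
    cols = np.arange(ncol)[None, :] * np.ones((nrow, 1))
    profile = 1.0 + gradient * np.cos(2 * np.pi * cols / max(ncol - 1, 1))
    grid = np.where(mask, target_bmd * profile, 0.0)
    if noise_sd > 0:
        grid = grid + np.where(mask, rng.normal(0.0, noise_sd, size=shape), 0.0)
    # re-centre so the mask mean is exactly target_bmd, then clip at zero
    grid = np.where(mask, grid - grid[mask].mean() + target_bmd, 0.0)
    grid = np.clip(grid, 0.0, None)
    roi = mask.astype(int)
    return DensityPhantom(
        grid=grid,
        pixel_spacing=pixel_spacing,
        bone_mask=mask,
        roi_labels=roi,
        site=site,
        weight=weight,
        height=height,
    )


def save_phantom(phantom: DensityPhantom, directory, fmt: str = "tiff") -> None:
    """Persist a phantom as rasters + JSON sidecar.

    ``fmt='tiff'`` writes 16-bit TIFFs with the density scale factor declared
    in the sidecar; ``fmt='text'`` writes plain-text grids.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "pixel_spacing_cm": phantom.pixel_spacing,
        "site": phantom.site,
        "weight_kg": phantom.weight,
        "height_cm": phantom.height,
        "format": fmt,
    }
    if fmt == "tiff":
        import tifffile

        scale = 65535.0 / max(phantom.grid.max(), 1e-12)
        meta["density_scale"] = scale
        tifffile.imwrite(
            directory / "density.tif",
            np.round(phantom.grid * scale).astype(np.uint16),
        )
        tifffile.imwrite(directory / "mask.tif", phantom.bone_mask.astype(np.uint16))
        tifffile.imwrite(directory / "roi.tif", phantom.roi_labels.astype(np.uint16))
    elif fmt == "text":
        np.savetxt(directory / "density.txt", phantom.grid)
        np.savetxt(directory / "mask.txt", phantom.bone_mask.astype(int), fmt="%d")
        np.savetxt(directory / "roi.txt", phantom.roi_labels, fmt="%d")
    else:
        raise ValueError("fmt must be 'tiff' or 'text'")
    (directory / "phantom.json").write_text(json.dumps(meta, indent=2))


def load_phantom(directory) -> DensityPhantom:
    directory = Path(directory)
    meta = json.loads((directory / "phantom.json").read_text())
    if meta["format"] == "tiff":
        import tifffile

        grid = tifffile.imread(directory / "density.tif").astype(float)
        grid /= meta["density_scale"]
        mask = tifffile.imread(directory / "mask.tif").astype(bool)
        roi = tifffile.imread(directory / "roi.tif").astype(int)
    else:
        grid = np.loadtxt(directory / "density.txt")
        mask = np.loadtxt(directory / "mask.txt").astype(bool)
        roi = np.loadtxt(directory / "roi.txt").astype(int)
    grid[~mask] = 0.0  # quantization can leave epsilon outside the mask
    return DensityPhantom(
        grid=grid,
        pixel_spacing=meta["pixel_spacing_cm"],
        bone_mask=mask,
        roi_labels=roi,
        site=meta["site"],
        weight=meta["weight_kg"],
        height=meta["height_cm"],
    )
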