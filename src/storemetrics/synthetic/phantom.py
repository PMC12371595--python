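"""Phantom red blood cells with known geometry and stiffness.

A phantom cell is a radially symmetric object: a biconcave-disc height
profile and a monotone center-to-edge Young's-modulus profile, both given as
functions of the normalized radius r = (distance from center)/radius.
Rasterizing a set of non-overlapping phantoms onto a grid yields a
:class:`PhantomScan` with per-pixel ground-truth topography and modulus,
which the scan synthesizer turns into raw approach curves and the inverse
pipeline is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PhantomCell",
    "PhantomScan",
    "biconcave_height",
    "plateau_edge_modulus",
    "uniform_modulus",
    "generate_phantom",
    "phantom_presets",
]

#: sentinel stored in ``modulus_truth`` for substrate pixels
SUBSTRATE_SENTINEL = np.nan


@dataclass(frozen=True)
class PhantomCell:
    """One synthetic cell: position, size, and radial height/modulus profiles."""

    center_xy: tuple[float, float]  # µm, (x, y)
    radius_um: float
    height_profile: Callable[[np.ndarray], np.ndarray]  # r_norm -> µm
    modulus_profile: Callable[[np.ndarray], np.ndarray]  # r_norm -> Pa


def biconcave_height(rim_height_um: float = 2.5, center_fraction: float = 0.4):
    """Dimpled disc height profile: h(r) = h_rim·(c + (1−c)·sin(πr)), 0 beyond r=1.

    The center sits at ``center_fraction`` of the rim height and the rim ring
    peaks at r = 0.5, giving the familiar biconcave cross-section.
    """

    def profile(r):
        r = np.asarray(r, dtype=float)
        h = rim_height_um * (
            center_fraction + (1.0 - center_fraction) * np.sin(np.pi * np.clip(r, 0.0, 1.0))
        )
        return np.where(r < 1.0, h, 0.0)

    return profile


def plateau_edge_modulus(
    center_pa: float = 300.0,
    edge_pa: float = 80.0,
    plateau_r: float = 0.55,
    edge_r: float = 0.85,
):
    """Center plateau at ``center_pa``, linear ramp to ``edge_pa``, flat edge band.

    Monotone between the center and edge values; the plateau/edge extents are
    in normalized radius.
    """
    if not (0.0 < plateau_r < edge_r <= 1.0):
        raise ValueError("need 0 < plateau_r < edge_r <= 1")

    def profile(r):
        r = np.asarray(r, dtype=float)
        t = np.clip((r - plateau_r) / (edge_r - plateau_r), 0.0, 1.0)
        return center_pa + (edge_pa - center_pa) * t

    return profile


def uniform_modulus(e_pa: float):
    """Spatially uniform stiffness."""

    def profile(r):
        return np.full_like(np.asarray(r, dtype=float), e_pa)

    return profile


@dataclass
class PhantomScan:
    """Ground-truth grids: topography (µm) and modulus (Pa, NaN on substrate)."""

    topography_um: np.ndarray
    modulus_pa: np.ndarray
    pixel_size_um: float
    substrate_level_um: float = 0.0

    def __post_init__(self) -> None:
        if self.topography_um.shape != self.modulus_pa.shape:
            raise ValueError("topography and modulus grids must share a shape")


def generate_phantom(
    cells: Sequence[PhantomCell],
    grid_shape: tuple[int, int],
    pixel_size_um: float,
    substrate_level_um: float = 0.0,
) -> PhantomScan:
    """Rasterize non-overlapping phantom cells onto a grid.

    Pixel (i, j) samples the physical point (x, y) = ((j+0.5)·p, (i+0.5)·p).
    Topography is the pixelwise maximum of the substrate level and each cell's
    height; modulus is taken from the owning cell's profile on cell pixels and
    is the NaN sentinel elsewhere.

    Raises
    ------
    ValueError
        If cells overlap, fall outside the grid, or a modulus profile yields
        a non-positive value on a cell pixel.
    """
    ny, nx = grid_shape
    p = float(pixel_size_um)
    for k, c in enumerate(cells):
        x, y = c.center_xy
        if not (c.radius_um <= x <= nx * p - c.radius_um) or not (
            c.radius_um <= y <= ny * p - c.radius_um
        ):
            raise ValueError(f"cell {k} footprint extends outside the grid")
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            dx = cells[a].center_xy[0] - cells[b].center_xy[0]
            dy = cells[a].center_xy[1] - cells[b].center_xy[1]
            if np.hypot(dx, dy) < cells[a].radius_um + cells[b].radius_um:
                raise ValueError(f"cells {a} and {b} have overlapping footprints")

    yy, xx = np.indices(grid_shape, dtype=float)
    px = (xx + 0.5) * p
    py = (yy + 0.5) * p
    topo = np.full(grid_shape, float(substrate_level_um))
    modulus = np.full(grid_shape, SUBSTRATE_SENTINEL)
    for c in cells:
        r = np.hypot(px - c.center_xy[0], py - c.center_xy[1]) / c.radius_um
        inside = r < 1.0
        h = np.where(inside, c.height_profile(r), 0.0)
        if np.any(h < 0):
            raise ValueError("height profile must be nonnegative")
        topo = np.maximum(topo, substrate_level_um + h)
        e = c.modulus_profile(r[inside])
        if np.any(~np.isfinite(e)) or np.any(e <= 0):
            raise ValueError("modulus profile must be finite and positive on the cell")
        modulus[inside] = e
    return PhantomScan(topo, modulus, p, float(substrate_level_um))


def phantom_presets() -> dict[str, PhantomCell]:
    """Named single-cell fixtures used by the packaged study scenarios.

    ``as1_center``
        A cell whose center plateau sits at 300 Pa — the stiffness observed at
        the center of cells imaged in their own additive solution — ramping
        down to an 80 Pa edge band (edges are reported below 100 Pa).
    ``as1n_pss``
        A uniformly soft cell (80 Pa center to 50 Pa edge) standing in for
        normoglycemically stored cells after transfer to a plasma-like salt
        solution, whose surface moduli lie entirely below 100 Pa.
    ``stiff``
        A nearly rigid cell (1 MPa) for topography-accuracy checks, where the
        compliance bias of the threshold crossing is negligible.
    """
    return {
        "as1_center": PhantomCell(
            center_xy=(16.0, 16.0),
            radius_um=10.0,
            height_profile=biconcave_height(),
            modulus_profile=plateau_edge_modulus(300.0, 80.0),
        ),
        "as1n_pss": PhantomCell(
            center_xy=(16.0, 16.0),
            radius_um=10.0,
            height_profile=biconcave_height(),
            modulus_profile=plateau_edge_modulus(80.0, 50.0),
        ),
        "stiff": PhantomCell(
            center_xy=(16.0, 16.0),
            radius_um=10.0,
            height_profile=biconcave_height(),
            modulus_profile=uniform_modulus(1.0e6),
        ),
    }
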