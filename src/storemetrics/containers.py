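"""Shared in-memory containers and their on-disk formats.

A hopping-mode scan is a raster of *approach curves*: at each XY pixel the
nanopipette descends toward the surface while the ion current drops; the
percent current drop versus vertical position is the raw observable that the
stiffness-mapping pipeline consumes.  On disk a scan lives in a directory
holding ``metadata.json`` (acquisition parameters, grid shape, pixel size)
and ``curves.h5`` with the ragged per-pixel curves in a CSR-style layout,
reference (bare-substrate) curves under the ``reference`` group.

Derived maps (topography in µm, Young's modulus in Pa with NaN marking
substrate/undefined pixels, integer cell labels) are written as TIFFs so any
image tool can open them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ApproachCurve",
    "AcquisitionParams",
    "ScanGrid",
    "TopographyMap",
    "SlopeMap",
    "ModulusMap",
    "CellMask",
    "Histogram",
    "read_scan",
    "write_scan",
    "read_maps",
    "write_maps",
]


@dataclass(frozen=True)
class ApproachCurve:
    """One hop: percent ion-current drop versus descending vertical position.

    ``z_um`` is strictly decreasing (the probe approaches the surface);
    ``drop_pct`` is the current reduction relative to the bulk value, in
    percent, and the final sample is the one that tripped the stop threshold.
    """

    z_um: np.ndarray
    drop_pct: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_um, dtype=float)
        d = np.asarray(self.drop_pct, dtype=float)
        if z.ndim != 1 or z.shape != d.shape:
            raise ValueError("z_um and drop_pct must be 1-D arrays of equal length")
        object.__setattr__(self, "z_um", z)
        object.__setattr__(self, "drop_pct", d)

    def __len__(self) -> int:
        return self.z_um.size


@dataclass(frozen=True)
class AcquisitionParams:
    """Pressurized-SICM acquisition settings.

    The defaults mirror a typical pressurized hopping-mode session: 2 kPa
    back-pressure, 5 µm hop height, the approach stopping at a 2.1 % current
    drop, the 1–2 % window used for slope regression, 200 bare-substrate
    reference hops, and the geometry factor A = 0.1617 relating slope ratio
    to Young's modulus.
    """

    pressure_pa: float = 2000.0
    stop_threshold_pct: float = 2.1
    window_lo_pct: float = 1.0
    window_hi_pct: float = 2.0
    hop_height_um: float = 5.0
    n_reference: int = 200
    substrate_slope_pct_per_um: float = 25.0
    a_geom: float = 0.1617
    z_step_um: float = 0.005
    current_noise_sd_pct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.window_lo_pct < self.window_hi_pct < self.stop_threshold_pct):
            raise ValueError(
                "need 0 < window_lo_pct < window_hi_pct < stop_threshold_pct"
            )
        if self.pressure_pa <= 0:
            raise ValueError("pressure_pa must be positive")
        if self.substrate_slope_pct_per_um <= 0:
            raise ValueError("substrate_slope_pct_per_um must be positive")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.n_reference < 1:
            raise ValueError("n_reference must be >= 1")
        if self.current_noise_sd_pct < 0:
            raise ValueError("current_noise_sd_pct must be >= 0")


@dataclass
class ScanGrid:
    """A 2-D raster of approach curves plus acquisition metadata."""

    curves: list[list[ApproachCurve]]
    reference_curves: list[ApproachCurve]
    params: AcquisitionParams
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.curves), len(self.curves[0]) if self.curves else 0)

    def curve(self, i: int, j: int) -> ApproachCurve:
        return self.curves[i][j]


@dataclass
class TopographyMap:
    """Surface heights (µm) relative to the fitted substrate plane."""

    height_um: np.ndarray
    contact_z_um: np.ndarray  # raw 2.1 %-crossing positions before leveling
    plane_coeffs: tuple[float, float, float]  # z = a*x + b*y + c (pixel units)


@dataclass
class SlopeMap:
    """Per-pixel window slopes (% per µm, positive magnitudes) with fit QC."""

    s: np.ndarray
    fit_r2: np.ndarray
    n_points: np.ndarray


@dataclass
class ModulusMap:
    """Per-pixel Young's modulus (Pa).

    NaN marks substrate or undefined pixels, +inf marks "rigid" pixels whose
    window slope reached the substrate reference slope.
    """

    e_pa: np.ndarray
    a_geom: float
    pressure_pa: float


@dataclass
class CellMask:
    """Integer cell labels; 0 is the excluded substrate."""

    labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def pixel_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts) if v != 0}


@dataclass
class Histogram:
    """Binned pixelwise modulus distribution."""

    bin_edges: np.ndarray
    mass: np.ndarray  # counts, or fractions summing to 1 when normalized
    normalized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mass": self.mass,
            }
        )


# ---------------------------------------------------------------------------
# scan container I/O


def _pack_ragged(curves: list[ApproachCurve]):
    row_ptr = np.zeros(len(curves) + 1, dtype=np.int64)
    for k, c in enumerate(curves):
        row_ptr[k + 1] = row_ptr[k] + len(c)
    z = np.concatenate([c.z_um for c in curves]) if curves else np.empty(0)
    d = np.concatenate([c.drop_pct for c in curves]) if curves else np.empty(0)
    return row_ptr, z, d


def _unpack_ragged(row_ptr, z, d) -> list[ApproachCurve]:
    return [
        ApproachCurve(z[a:b], d[a:b]) for a, b in zip(row_ptr[:-1], row_ptr[1:])
    ]


def write_scan(scan: ScanGrid, path: str | Path) -> Path:
    """Write a scan container directory (``metadata.json`` + ``curves.h5``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ny, nx = scan.shape
    meta = {
        "grid_shape": [ny, nx],
        "pixel_size_um": scan.pixel_size_um,
        "acquisition": dataclasses.asdict(scan.params),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))

    flat = [scan.curves[i][j] for i in range(ny) for j in range(nx)]
    with h5py.File(path / "curves.h5", "w") as f:
        g = f.create_group("curves")
        row_ptr, z, d = _pack_ragged(flat)
        g.create_dataset("row_ptr", data=row_ptr)
        g.create_dataset("z_um", data=z)
        g.create_dataset("drop_pct", data=d)
        r = f.create_group("reference")
        row_ptr, z, d = _pack_ragged(scan.reference_curves)
        r.create_dataset("row_ptr", data=row_ptr)
        r.create_dataset("z_um", data=z)
        r.create_dataset("drop_pct", data=d)
    return path


def read_scan(path: str | Path) -> ScanGrid:
    """Read a scan container directory written by :func:`write_scan`."""
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"scan container is missing 'metadata.json': {path}")
    meta = json.loads(meta_path.read_text())
    for key in ("grid_shape", "pixel_size_um", "acquisition"):
        if key not in meta:
            raise KeyError(f"metadata.json is missing required key '{key}'")
    params = AcquisitionParams(**meta["acquisition"])
    ny, nx = meta["grid_shape"]
    curves_path = path / "curves.h5"
    if not curves_path.exists():
        raise FileNotFoundError(f"scan container is missing 'curves.h5': {path}")
    with h5py.File(curves_path, "r") as f:
        g = f["curves"]
        flat = _unpack_ragged(g["row_ptr"][...], g["z_um"][...], g["drop_pct"][...])
        r = f["reference"]
        ref = _unpack_ragged(r["row_ptr"][...], r["z_um"][...], r["drop_pct"][...])
    if len(flat) != ny * nx:
        raise ValueError(
            f"curve count {len(flat)} does not match grid shape {ny}x{nx}"
        )
    curves = [[flat[i * nx + j] for j in range(nx)] for i in range(ny)]
    return ScanGrid(
        curves=curves,
        reference_curves=ref,
        params=params,
        pixel_size_um=float(meta["pixel_size_um"]),
    )


# ---------------------------------------------------------------------------
# map I/O


def write_maps(
    out_dir: str | Path,
    topo: TopographyMap | None = None,
    modulus: ModulusMap | None = None,
    mask: CellMask | None = None,
) -> Path:
    """Write derived maps as TIFFs (float32 for topography/modulus, uint16 labels)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if topo is not None:
        tifffile.imwrite(out_dir / "topography_um.tif", topo.height_um.astype(np.float32))
    if modulus is not None:
        tifffile.imwrite(out_dir / "modulus_pa.tif", modulus.e_pa.astype(np.float32))
    if mask is not None:
        tifffile.imwrite(out_dir / "cell_labels.tif", mask.labels.astype(np.uint16))
    return out_dir


def read_maps(out_dir: str | Path) -> dict[str, np.ndarray]:
    """Read back whichever map TIFFs are present in ``out_dir``."""
    out_dir = Path(out_dir)
    out: dict[str, np.ndarray] = {}
    for name, fname in [
        ("topography_um", "topography_um.tif"),
        ("modulus_pa", "modulus_pa.tif"),
        ("cell_labels", "cell_labels.tif"),
    ]:
        p = out_dir / fname
        if p.exists():
            out[name] = tifffile.imread(p)
    if not out:
        raise FileNotFoundError(f"no map TIFFs found in {out_dir}")
    return out
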