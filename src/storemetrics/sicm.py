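"""Pressurized-SICM stiffness mapping: approach curves → modulus maps.

A nanopipette back-pressurized at P0 ejects a nanofluidic jet that indents
the sample; on a compliant pixel the ion current therefore falls more slowly
with depth than on rigid glass.  The pipeline regresses the percent current
drop against vertical position inside a fixed window (1–2 % drop by
default), references the slope s to the rigid-substrate slope s_inf (median
over many same-spot hops), and converts the ratio to a Young's modulus with
the empirical relation

    E = A · P0 / (s_inf / s − 1),

where A is a geometry factor obtained from finite-element modelling of the
tip (0.1617 for the pipettes used here).  Topography comes from the vertical
position at which the drop first reaches the stop threshold (2.1 %), leveled
by a plane fit to the substrate pixels.  Cells are isolated from the glass
by marker-controlled watershed on the leveled topography, and substrate
pixels (label 0) are excluded from all downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.stats import trim_mean
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from .containers import (
    AcquisitionParams,
    ApproachCurve,
    CellMask,
    Histogram,
    ModulusMap,
    ScanGrid,
    SlopeMap,
    TopographyMap,
)

__all__ = [
    "RIGID",
    "UNDEFINED",
    "ReferenceSlope",
    "fit_window_slope",
    "extract_contact_z",
    "reference_slope",
    "modulus_from_slope",
    "build_maps",
    "segment_cells",
    "modulus_distribution",
    "cell_region_stats",
]

#: modulus sentinel for pixels whose slope reached the substrate slope
RIGID = math.inf
#: modulus sentinel for pixels with no usable window fit (and substrate maps)
UNDEFINED = math.nan

MIN_WINDOW_POINTS = 3


@dataclass(frozen=True)
class ReferenceSlope:
    """Substrate reference: median window slope over repeated same-spot hops."""

    s_inf: float
    n_curves: int
    slope_iqr: float


def fit_window_slope(
    curve: ApproachCurve,
    window_lo_pct: float = 1.0,
    window_hi_pct: float = 2.0,
) -> tuple[float, float, int]:
    """OLS slope of drop vs z over samples inside the analysis window.

    Returns ``(slope, r2, n_points)`` where slope is the positive magnitude
    in % per µm.  Fewer than 3 in-window samples (including an empty window)
    yields ``(nan, nan, n)`` rather than an exception: noise can legitimately
    empty the narrow window.
    """
    d = curve.drop_pct
    z = curve.z_um
    sel = (d >= window_lo_pct) & (d <= window_hi_pct)
    n = int(sel.sum())
    if n < MIN_WINDOW_POINTS:
        return (math.nan, math.nan, n)
    zw, dw = z[sel], d[sel]
    zc = zw - zw.mean()
    dc = dw - dw.mean()
    szz = float(zc @ zc)
    if szz == 0.0:
        return (math.nan, math.nan, n)
    slope = float(zc @ dc) / szz
    sdd = float(dc @ dc)
    r2 = 1.0 if sdd == 0.0 else float((zc @ dc) ** 2 / (szz * sdd))
    return (abs(slope), r2, n)


def extract_contact_z(curve: ApproachCurve, stop_threshold_pct: float = 2.1) -> float:
    """Vertical position of the first stop-threshold crossing during approach.

    Linearly interpolated between the bracketing samples; a sample exactly at
    the threshold returns that sample's z.

    Raises
    ------
    ValueError
        If the curve never reaches the threshold (malformed curve).
    """
    d = curve.drop_pct
    z = curve.z_um
    hits = np.nonzero(d >= stop_threshold_pct)[0]
    if hits.size == 0:
        raise ValueError("approach curve never reaches the stop threshold")
    k = int(hits[0])
    if d[k] == stop_threshold_pct or k == 0:
        return float(z[k])
    frac = (stop_threshold_pct - d[k - 1]) / (d[k] - d[k - 1])
    return float(z[k - 1] + frac * (z[k] - z[k - 1]))


def reference_slope(
    reference_curves: Sequence[ApproachCurve],
    window_lo_pct: float = 1.0,
    window_hi_pct: float = 2.0,
) -> ReferenceSlope:
    """Median window slope over the substrate reference hops.

    The median (mean of the central pair for even counts) makes s_inf robust
    to up to just-under-half of the hops being corrupted.

    Raises
    ------
    ValueError
        If no curve yields a defined slope.
    """
    if len(reference_curves) == 0:
        raise ValueError("need at least one reference curve")
    slopes = np.array(
        [fit_window_slope(c, window_lo_pct, window_hi_pct)[0] for c in reference_curves]
    )
    slopes = slopes[np.isfinite(slopes)]
    if slopes.size == 0:
        raise ValueError("no reference curve produced a defined window slope")
    q1, med, q3 = np.percentile(slopes, [25, 50, 75])
    return ReferenceSlope(s_inf=float(med), n_curves=int(slopes.size),
                          slope_iqr=float(q3 - q1))


def modulus_from_slope(
    s: float, s_inf: float, a_geom: float = 0.1617, pressure_pa: float = 2000.0
) -> float:
    """Young's modulus from the slope ratio: E = A·P0/(s_inf/s − 1).

    Strictly increasing in s on (0, s_inf); s ≥ s_inf means the pixel is at
    least as stiff as the reference substrate and returns the RIGID sentinel
    (+inf).  A NaN slope (undefined fit) propagates to NaN.
    """
    if math.isnan(s):
        return UNDEFINED
    if s <= 0 or s_inf <= 0:
        raise ValueError("slopes must be positive")
    if a_geom <= 0 or pressure_pa <= 0:
        raise ValueError("a_geom and pressure_pa must be positive")
    if s >= s_inf:
        return RIGID
    return a_geom * pressure_pa / (s_inf / s - 1.0)


def _fit_substrate_plane(
    contact_z: np.ndarray, min_height_um: float, n_iter: int = 8
) -> tuple[float, float, float]:
    """Least-squares plane through substrate pixels, found iteratively.

    Start from all pixels, then repeatedly refit on pixels within
    ``min_height_um`` of the current plane (the provisional label-0 set).
    Assumes the substrate is the majority phase, as in a sparse cell field.
    """
    yy, xx = np.indices(contact_z.shape, dtype=float)
    mask = np.ones(contact_z.shape, dtype=bool)
    coef = (0.0, 0.0, float(np.median(contact_z)))
    for _ in range(n_iter):
        a = np.column_stack([xx[mask], yy[mask], np.ones(int(mask.sum()))])
        sol, *_ = np.linalg.lstsq(a, contact_z[mask], rcond=None)
        coef = (float(sol[0]), float(sol[1]), float(sol[2]))
        resid = contact_z - (coef[0] * xx + coef[1] * yy + coef[2])
        new_mask = resid < min_height_um
        if not new_mask.any() or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return coef


def build_maps(
    scan: ScanGrid, min_height_um: float = 0.2
) -> tuple[TopographyMap, SlopeMap, ModulusMap]:
    """Run the full per-pixel inverse: contact, window slope, modulus.

    Topography is reported relative to the substrate plane (least-squares fit
    to the provisional substrate pixels).  Pixels whose slope is undefined or
    not below s_inf carry the corresponding modulus sentinel.

    Raises
    ------
    ValueError
        If the scan carries no reference curves.
    """
    if not scan.reference_curves:
        raise ValueError("scan has no substrate reference curves")
    p = scan.params
    ref = reference_slope(scan.reference_curves, p.window_lo_pct, p.window_hi_pct)

    ny, nx = scan.shape
    contact = np.empty((ny, nx))
    s = np.empty((ny, nx))
    r2 = np.empty((ny, nx))
    npts = np.empty((ny, nx), dtype=int)
    e = np.empty((ny, nx))
    for i in range(ny):
        for j in range(nx):
            c = scan.curve(i, j)
            contact[i, j] = extract_contact_z(c, p.stop_threshold_pct)
            s[i, j], r2[i, j], npts[i, j] = fit_window_slope(
                c, p.window_lo_pct, p.window_hi_pct
            )
            e[i, j] = modulus_from_slope(s[i, j], ref.s_inf, p.a_geom, p.pressure_pa)

    coef = _fit_substrate_plane(contact, min_height_um)
    yy, xx = np.indices((ny, nx), dtype=float)
    height = contact - (coef[0] * xx + coef[1] * yy + coef[2])
    return (
        TopographyMap(height_um=height, contact_z_um=contact, plane_coeffs=coef),
        SlopeMap(s=s, fit_r2=r2, n_points=npts),
        ModulusMap(e_pa=e, a_geom=p.a_geom, pressure_pa=p.pressure_pa),
    )


def segment_cells(
    topo: TopographyMap | np.ndarray,
    min_height_um: float = 0.2,
    smooth_sigma_px: float = 1.0,
    marker_h_um: float = 0.1,
) -> CellMask:
    """Marker-controlled watershed isolating cells from the glass substrate.

    Foreground = pixels at least ``min_height_um`` above the substrate plane.
    Markers come from the Gaussian-smoothed topography with maxima shallower
    than ``marker_h_um`` suppressed by morphological reconstruction: peaks
    whose separating saddle is within ``marker_h_um`` of their tops merge
    into one plateau (so a dimpled cell's rim ridge stays one marker), while
    two cells fused by a neck deeper than ``marker_h_um`` keep separate
    markers and split at the saddle.  An empty foreground yields all label 0.
    """
    height = topo.height_um if isinstance(topo, TopographyMap) else np.asarray(topo, float)
    fg = height >= min_height_um
    if not fg.any():
        return CellMask(labels=np.zeros(height.shape, dtype=np.int32))
    smoothed = ndi.gaussian_filter(height, sigma=smooth_sigma_px)
    smoothed = np.where(fg, smoothed, 0.0)
    suppressed = reconstruction(smoothed - marker_h_um, smoothed, method="dilation")
    maxima = local_maxima(suppressed) & fg
    if not maxima.any():  # degenerate: foreground thinner than marker depth
        maxima = fg
    markers, _ = ndi.label(maxima)
    labels = watershed(-smoothed, markers=markers, mask=fg)
    return CellMask(labels=labels.astype(np.int32))


def modulus_distribution(
    modulus: ModulusMap,
    mask: CellMask,
    bins: int | np.ndarray = 50,
    value_range: tuple[float, float] | None = None,
    normalize: bool = False,
) -> Histogram:
    """Pixelwise modulus histogram over finite-modulus cell pixels only.

    Substrate (label 0), undefined, and rigid pixels never contribute.  With
    ``normalize`` the bin masses sum to one.

    Raises
    ------
    ValueError
        If no cell pixel has a finite modulus.
    """
    values = modulus.e_pa[(mask.labels > 0) & np.isfinite(modulus.e_pa)]
    if values.size == 0:
        raise ValueError("no finite-modulus cell pixels to histogram")
    counts, edges = np.histogram(values, bins=bins, range=value_range)
    mass = counts.astype(float)
    if normalize:
        mass = mass / mass.sum()
    return Histogram(bin_edges=edges, mass=mass, normalized=normalize)


def cell_region_stats(
    modulus: ModulusMap,
    mask: CellMask,
    label: int,
    trim: float = 0.05,
    quartile: float = 0.25,
) -> tuple[float, float]:
    """Trimmed-mean modulus of a cell's center and edge bands.

    Pixels of the labeled region are ranked by normalized Euclidean distance
    from the region boundary; the center band is the innermost ``quartile``
    fraction of pixels, the edge band the outermost fraction.  Means are
    trimmed (5 % each tail by default) over finite-modulus pixels.

    Raises
    ------
    ValueError
        If the label is absent or the region has fewer than 8 pixels.
    """
    region = mask.labels == label
    n = int(region.sum())
    if label <= 0 or n == 0:
        raise ValueError(f"label {label} not present in mask")
    if n < 8:
        raise ValueError(f"region {label} has only {n} pixels (< 8)")
    padded = np.pad(region, 1)
    dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    ndist = dist[region] / dist[region].max()
    lo, hi = np.quantile(ndist, [quartile, 1.0 - quartile])
    values = modulus.e_pa[region]
    center_vals = values[(ndist >= hi) & np.isfinite(values)]
    edge_vals = values[(ndist <= lo) & np.isfinite(values)]
    if center_vals.size == 0 or edge_vals.size == 0:
        raise ValueError("no finite-modulus pixels in a requested band")
    return (
        float(trim_mean(center_vals, trim)),
        float(trim_mean(edge_vals, trim)),
    )
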