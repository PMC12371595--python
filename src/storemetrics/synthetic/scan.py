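"""Forward synthesis of hopping-mode approach curves over a phantom.

The forward model is the minimal one that exercises the inverse pipeline: on
a pixel of Young's modulus E the percent current drop is zero above a fixed
sensing onset and grows linearly with depth below it, with window slope

    s = s_inf / (1 + A·P0/E)

(cell pixels) or s = s_inf (rigid substrate).  The onset sits a fixed sensing
distance ``stop_threshold / s_inf`` above the local surface, so on rigid
substrate the stop-threshold crossing recovers the surface exactly, while on
compliant pixels it lands below the true contact — the compliance bias the
topography stage inherits.  Each curve terminates at the first sample whose
(possibly noisy) drop reaches the stop threshold.
"""

from __future__ import annotations

import numpy as np

from ..containers import AcquisitionParams, ApproachCurve, ScanGrid
from .phantom import PhantomScan

__all__ = ["synthesize_scan", "window_slope_for_modulus"]


def window_slope_for_modulus(e_pa, acq: AcquisitionParams):
    """Expected window slope (% per µm) at modulus ``e_pa`` under ``acq``.

    The inverse of the modulus equation: s = s_inf / (1 + A·P0/E).
    """
    e = np.asarray(e_pa, dtype=float)
    return acq.substrate_slope_pct_per_um / (1.0 + acq.a_geom * acq.pressure_pa / e)


def _one_curve(
    surface_um: float,
    slope: float,
    acq: AcquisitionParams,
    rng: np.random.Generator,
) -> ApproachCurve:
    onset = surface_um + acq.stop_threshold_pct / acq.substrate_slope_pct_per_um
    z_start = surface_um + acq.hop_height_um
    # sample past the noise-free crossing so a noisy curve still terminates
    z_end = onset - acq.stop_threshold_pct / slope - 1.0
    n = int(np.ceil((z_start - z_end) / acq.z_step_um)) + 1
    z = z_start - acq.z_step_um * np.arange(n)
    drop = np.maximum(0.0, slope * (onset - z))
    if acq.current_noise_sd_pct > 0:
        drop = drop + rng.normal(0.0, acq.current_noise_sd_pct, size=n)
    hits = np.nonzero(drop >= acq.stop_threshold_pct)[0]
    if hits.size == 0:  # pragma: no cover - guard band above makes this unreachable
        raise RuntimeError("approach curve never reached the stop threshold")
    stop = hits[0]
    return ApproachCurve(z[: stop + 1], drop[: stop + 1])


def synthesize_scan(phantom: PhantomScan, acq: AcquisitionParams) -> ScanGrid:
    """Emit a full raster of approach curves plus substrate reference hops.

    Every random draw comes from one generator seeded with ``acq.seed``, so
    identical parameters give bit-identical scans.

    Raises
    ------
    ValueError
        If any cell pixel carries a non-positive or non-finite-but-non-NaN
        modulus.
    """
    topo = np.asarray(phantom.topography_um, dtype=float)
    e = np.asarray(phantom.modulus_pa, dtype=float)
    if not np.all(np.isfinite(topo)):
        raise ValueError("phantom topography must be finite")
    cell = ~np.isnan(e)
    if np.any(e[cell] <= 0) or np.any(np.isinf(e[cell])):
        raise ValueError("cell moduli must be positive and finite")

    rng = np.random.default_rng(acq.seed)
    s_inf = acq.substrate_slope_pct_per_um
    slopes = np.where(cell, window_slope_for_modulus(np.where(cell, e, 1.0), acq), s_inf)

    ny, nx = topo.shape
    curves = [
        [_one_curve(topo[i, j], slopes[i, j], acq, rng) for j in range(nx)]
        for i in range(ny)
    ]
    reference = [
        _one_curve(phantom.substrate_level_um, s_inf, acq, rng)
        for _ in range(acq.n_reference)
    ]
    return ScanGrid(
        curves=curves,
        reference_curves=reference,
        params=acq,
        pixel_size_um=phantom.pixel_size_um,
    )
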