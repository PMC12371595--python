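"""Synthetic cyanmethemoglobin-assay absorbance sets for hemolysis testing.

Drabkin's reagent converts hemoglobin to cyanmethemoglobin, read at 540 nm
against standards between 0 and 1 mg/mL.  The generator plants a true lysis
percentage, splits the (mixed-basis) total hemoglobin into supernatant and
pellet concentrations by inverting the lysis formula

    Lysis% = 100 · [Hb_sup]·(1 − HCT) / ([Hb_sup] + [Hb_pellet]),

and emits the absorbances that a plate reader would record after the stated
10-fold (supernatant) and 1000-fold (pellet) dilutions, plus a ≥6-level
standards table spanning 0–1 mg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AbsorbanceSet", "synthesize_hemolysis_absorbances"]


@dataclass
class AbsorbanceSet:
    """Standards plus the supernatant/pellet readings for one lysis assay."""

    standards_mg_ml: np.ndarray
    standards_abs: np.ndarray
    abs_supernatant: float
    abs_pellet: float
    supernatant_dilution: float
    pellet_dilution: float
    hct: float

    def standards_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"hb_mg_ml": self.standards_mg_ml, "absorbance": self.standards_abs}
        )


def synthesize_hemolysis_absorbances(
    true_lysis_pct: float,
    hct: float,
    total_hb_mg_ml: float = 300.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    extinction_slope: float = 0.7,  # absorbance per mg/mL at 540 nm
    blank_abs: float = 0.04,
    n_standards: int = 6,
) -> AbsorbanceSet:
    """Generate one assay's absorbances consistent with a planted lysis %.

    ``total_hb_mg_ml`` is the sum [Hb_sup] + [Hb_pellet] appearing in the
    lysis formula's denominator.  With ``noise_sd = 0`` the assay pipeline
    (calibration fit → dilution correction → lysis formula) recovers
    ``true_lysis_pct`` exactly.
    """
    if not (0.0 <= true_lysis_pct <= 100.0):
        raise ValueError("true_lysis_pct must be in [0, 100]")
    if not (0.0 < hct < 1.0):
        raise ValueError("hct must be in (0, 1)")
    if n_standards < 6:
        raise ValueError("at least six calibration standards are required")
    rng = np.random.default_rng(seed)

    hb_sup = true_lysis_pct * total_hb_mg_ml / (100.0 * (1.0 - hct))
    hb_pellet = total_hb_mg_ml - hb_sup
    if hb_pellet < 0:
        raise ValueError("planted lysis is inconsistent with total hemoglobin")

    conc = np.linspace(0.0, 1.0, n_standards)
    abs_std = blank_abs + extinction_slope * conc
    abs_sup = blank_abs + extinction_slope * hb_sup / 10.0
    abs_pel = blank_abs + extinction_slope * hb_pellet / 1000.0
    if noise_sd > 0:
        abs_std = abs_std + rng.normal(0.0, noise_sd, size=n_standards)
        abs_sup += rng.normal(0.0, noise_sd)
        abs_pel += rng.normal(0.0, noise_sd)
    return AbsorbanceSet(
        standards_mg_ml=conc,
        standards_abs=abs_std,
        abs_supernatant=float(abs_sup),
        abs_pellet=float(abs_pel),
        supernatant_dilution=10.0,
        pellet_dilution=1000.0,
        hct=hct,
    )
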