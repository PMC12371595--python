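"""Storage-bag glucose kinetics with sampling, feeding, and meter noise.

A refrigerated bag of red cells consumes glucose fastest early in storage and
progressively slower; the simulator models the consumption *rate* as a single
exponential r(t) = r0·exp(−t/τ) (µmol/h), integrated in closed form between
events, with the default (r0 = 1.3 µmol/h, τ = 450 h for a ~50 mL bag)
calibrated so that early-storage replacement demand is ~0.87 µL of 300 mM
stock every 12 min, thinning to one such bolus per several hours by day 56.

Volumes are mL, concentrations mM (≡ µmol/mL), times hours.  Sampling
removes suspension (volume drops, concentration unchanged); feeding mixes a
stock solution into the bag; glucometer readings apply multiplicative
lognormal noise at a configured CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BagParams", "StorageBag", "simulate_storage_bag"]


@dataclass(frozen=True)
class BagParams:
    """Initial conditions and kinetics for one storage bag."""

    initial_volume_ml: float = 50.0
    hematocrit: float = 0.6
    initial_glucose_mm: float = 5.5
    consumption_rate0_umol_h: float = 1.3
    consumption_decay_tau_h: float = 450.0
    glucometer_cv: float = 0.05
    measurement_interval_h: float = 84.0  # every 3.5 days
    sampling_events: tuple[tuple[float, float], ...] = ()  # (time_h, volume_ml)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_volume_ml <= 0:
            raise ValueError("initial_volume_ml must be positive")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError("hematocrit must be in (0, 1)")
        if min(self.initial_glucose_mm, self.consumption_rate0_umol_h,
               self.glucometer_cv) < 0:
            raise ValueError("rates, concentrations and CV must be >= 0")
        if self.consumption_decay_tau_h <= 0:
            raise ValueError("consumption_decay_tau_h must be positive")


class StorageBag:
    """Mutable bag state: glucose mass (µmol), volume (mL), clock (h)."""

    def __init__(self, params: BagParams):
        self.params = params
        self.volume_ml = params.initial_volume_ml
        self.glucose_umol = params.initial_glucose_mm * params.initial_volume_ml
        self.time_h = 0.0
        self.total_consumed_umol = 0.0
        self.total_fed_umol = 0.0
        self.total_fed_ml = 0.0
        self.total_sampled_umol = 0.0
        self.total_sampled_ml = 0.0
        self._rng = np.random.default_rng(params.seed)

    @property
    def glucose_mm(self) -> float:
        return self.glucose_umol / self.volume_ml

    def predicted_consumption_umol(self, t0_h: float, t1_h: float) -> float:
        """Closed-form ∫ r0·exp(−t/τ) dt over [t0, t1]."""
        r0 = self.params.consumption_rate0_umol_h
        tau = self.params.consumption_decay_tau_h
        return r0 * tau * (math.exp(-t0_h / tau) - math.exp(-t1_h / tau))

    def advance(self, dt_h: float) -> None:
        """Consume glucose over ``dt_h`` (mass floored at zero)."""
        if dt_h < 0:
            raise ValueError("cannot advance backwards")
        demand = self.predicted_consumption_umol(self.time_h, self.time_h + dt_h)
        consumed = min(demand, self.glucose_umol)
        self.glucose_umol -= consumed
        self.total_consumed_umol += consumed
        self.time_h += dt_h

    def feed(self, volume_ml: float, stock_mm: float) -> None:
        """Mix ``volume_ml`` of stock at ``stock_mm`` into the bag."""
        if volume_ml < 0 or stock_mm < 0:
            raise ValueError("feed volume and concentration must be >= 0")
        self.glucose_umol += volume_ml * stock_mm
        self.volume_ml += volume_ml
        self.total_fed_umol += volume_ml * stock_mm
        self.total_fed_ml += volume_ml

    def sample(self, volume_ml: float) -> None:
        """Withdraw suspension; concentration is unchanged."""
        if volume_ml < 0:
            raise ValueError("sample volume must be >= 0")
        if volume_ml >= self.volume_ml:
            raise ValueError(
                f"sample of {volume_ml} mL exceeds bag volume {self.volume_ml} mL"
            )
        removed = self.glucose_mm * volume_ml
        self.glucose_umol -= removed
        self.volume_ml -= volume_ml
        self.total_sampled_umol += removed
        self.total_sampled_ml += volume_ml

    def measure(self) -> float:
        """Glucometer reading: true concentration × mean-one lognormal noise."""
        cv = self.params.glucometer_cv
        if cv == 0:
            return self.glucose_mm
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        factor = math.exp(self._rng.normal(0.0, sigma) - 0.5 * sigma * sigma)
        return self.glucose_mm * factor


def simulate_storage_bag(
    params: BagParams,
    duration_h: float,
    feed_events: tuple[tuple[float, float, float], ...] = (),
) -> pd.DataFrame:
    """Uncontrolled bag evolution with optional externally scheduled feeds.

    ``feed_events`` are (time_h, volume_ml, stock_mm) triples.  Returns one
    row per event/breakpoint with columns ``time_h``, ``true_mm``,
    ``measured_mm`` (NaN except at glucometer times), ``volume_ml``.
    Consumption between breakpoints is exact (closed-form integral), so no
    fine time grid is needed.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    bag = StorageBag(params)

    events: list[tuple[float, int, str, tuple]] = []
    for t, v in params.sampling_events:
        events.append((t, 0, "sample", (v,)))
    for t, v, c in feed_events:
        events.append((t, 1, "feed", (v, c)))
    n_meas = int(math.floor(duration_h / params.measurement_interval_h))
    for k in range(1, n_meas + 1):
        events.append((k * params.measurement_interval_h, 2, "measure", ()))
    events.append((duration_h, 3, "end", ()))
    events.sort(key=lambda e: (e[0], e[1]))

    rows = [
        {"time_h": 0.0, "true_mm": bag.glucose_mm, "measured_mm": np.nan,
         "volume_ml": bag.volume_ml}
    ]
    for t, _, kind, args in events:
        if t > duration_h:
            continue
        bag.advance(t - bag.time_h)
        measured = np.nan
        if kind == "sample":
            bag.sample(*args)
        elif kind == "feed":
            bag.feed(*args)
        elif kind == "measure":
            measured = bag.measure()
        rows.append(
            {"time_h": t, "true_mm": bag.glucose_mm, "measured_mm": measured,
             "volume_ml": bag.volume_ml}
        )
    return pd.DataFrame(rows)
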