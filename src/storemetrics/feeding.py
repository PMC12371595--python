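"""Closed-loop glucose maintenance for normoglycemic red-cell storage.

The dosing law has two layers:

* **feed-forward** — micro-boluses of concentrated glucose stock delivered at
  a fixed scheduling granularity, each sized to replace the consumption
  model's predicted glucose mass over the coming interval.  Because the
  modelled consumption rate decays exponentially through storage, bolus
  cadence naturally lengthens from sub-µL doses every few minutes early on to
  one dose per several hours near the end of storage.
* **feedback** — at every glucometer reading below the target, the exact
  mixing volume v = V·(target − measured)/(stock − target) that restores the
  target concentration is delivered.  Control is one-sided: readings above
  the target are flagged but never "corrected" (the hardware cannot withdraw
  glucose).

Stock volumes are quantized to whole peristaltic-pump steps (160 nL per
0.225° step by default) with the sub-step remainder carried forward, so the
cumulative dosing shortfall never exceeds one pump step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic.bag import BagParams, StorageBag

__all__ = [
    "PumpCalibration",
    "ControllerConfig",
    "BagState",
    "FeedEvent",
    "SampleEvent",
    "MeasurementEvent",
    "QuantizedDose",
    "FeedSchedule",
    "PerformanceReport",
    "quantize_to_steps",
    "feedback_bolus_volume",
    "feedforward_schedule",
    "apply_event",
    "replay_ledger",
    "run_closed_loop",
]


@dataclass(frozen=True)
class PumpCalibration:
    """Stepper-driven peristaltic pump resolution."""

    step_angle_deg: float = 0.225
    volume_per_step_nl: float = 160.0

    def __post_init__(self) -> None:
        if self.step_angle_deg <= 0 or self.volume_per_step_nl <= 0:
            raise ValueError("pump calibration values must be positive")


@dataclass(frozen=True)
class ControllerConfig:
    """Target band, stock concentration, and scheduling granularity."""

    target_mm: float = 5.0
    band_mm: float = 1.0
    stock_mm: float = 300.0
    micro_bolus_interval_min: float = 12.0
    consumption_rate0_umol_h: float = 1.3
    consumption_decay_tau_h: float = 450.0

    def __post_init__(self) -> None:
        if self.target_mm - self.band_mm <= 0:
            raise ValueError("target_mm - band_mm must be positive")
        if self.stock_mm <= self.target_mm:
            raise ValueError("stock_mm must exceed target_mm")
        if self.micro_bolus_interval_min <= 0:
            raise ValueError("micro_bolus_interval_min must be positive")

    def predicted_consumption_umol(self, t0_h: float, t1_h: float) -> float:
        tau = self.consumption_decay_tau_h
        return self.consumption_rate0_umol_h * tau * (
            math.exp(-t0_h / tau) - math.exp(-t1_h / tau)
        )


@dataclass(frozen=True)
class FeedEvent:
    time_h: float
    volume_ml: float
    stock_mm: float


@dataclass(frozen=True)
class SampleEvent:
    time_h: float
    volume_ml: float


@dataclass(frozen=True)
class MeasurementEvent:
    time_h: float
    measured_mm: float


@dataclass(frozen=True)
class BagState:
    """Controller-side bag ledger: volume, last reading, and event history."""

    volume_ml: float
    glucose_mm: float
    time_h: float = 0.0
    ledger: tuple = ()

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")


@dataclass(frozen=True)
class QuantizedDose:
    n_steps: int
    delivered_nl: float
    remainder_nl: float


def quantize_to_steps(volume_nl: float, cal: PumpCalibration) -> QuantizedDose:
    """Round a requested volume down to whole pump steps.

    Requests below one step deliver nothing and carry the full request as
    remainder; the caller accumulates remainders across boluses.
    """
    if volume_nl < 0:
        raise ValueError("volume_nl must be >= 0")
    step = cal.volume_per_step_nl
    # tiny tolerance so carried remainders that sum to an exact step count
    # are not floored by one float ulp
    n = int(math.floor(volume_nl / step + 1e-9))
    delivered = n * step
    return QuantizedDose(n_steps=n, delivered_nl=delivered,
                         remainder_nl=max(volume_nl - delivered, 0.0))


def feedback_bolus_volume(
    measured_mm: float, state: BagState, cfg: ControllerConfig
) -> float:
    """Exact mixing volume (mL) of stock that restores the target concentration.

    v = V·(target − measured)/(stock − target); zero when the reading is at
    or above target (one-sided control).
    """
    if measured_mm < 0:
        raise ValueError("measured_mm must be >= 0")
    if cfg.stock_mm <= cfg.target_mm:
        raise ValueError("stock concentration must exceed the target")
    if measured_mm >= cfg.target_mm:
        return 0.0
    return state.volume_ml * (cfg.target_mm - measured_mm) / (cfg.stock_mm - cfg.target_mm)


@dataclass
class FeedSchedule:
    """Feed-forward plan: delivered boluses plus the carried sub-step remainder."""

    boluses: list[tuple[float, float]]  # (time_h, delivered_nl)
    carry_nl: float

    def __iter__(self):
        return iter(self.boluses)

    def __len__(self):
        return len(self.boluses)


def feedforward_schedule(
    state: BagState,
    cfg: ControllerConfig,
    horizon_h: float,
    cal: PumpCalibration = PumpCalibration(),
    carry_nl: float = 0.0,
) -> FeedSchedule:
    """Plan quantized micro-boluses replacing predicted consumption.

    At each tick of the scheduling granularity the predicted glucose mass for
    the coming interval is converted to stock volume, added to the carried
    remainder, and floored to whole pump steps.  Zero-step ticks are omitted,
    which is what stretches the cadence as consumption decays.
    """
    if horizon_h <= 0:
        raise ValueError("horizon_h must be positive")
    dt = cfg.micro_bolus_interval_min / 60.0
    boluses: list[tuple[float, float]] = []
    t = state.time_h
    end = state.time_h + horizon_h
    while t < end - 1e-12:
        t1 = min(t + dt, end)
        mass_umol = cfg.predicted_consumption_umol(t, t1)
        request_nl = mass_umol / cfg.stock_mm * 1.0e6 + carry_nl
        dose = quantize_to_steps(request_nl, cal)
        carry_nl = dose.remainder_nl
        if dose.n_steps > 0:
            boluses.append((t1, dose.delivered_nl))
        t = t1
    return FeedSchedule(boluses=boluses, carry_nl=carry_nl)


def apply_event(state: BagState, event) -> BagState:
    """Fold one ledger event into the bag state (pure function).

    Feeds add volume, samples remove it, measurements update the last known
    concentration; every event is appended to the ledger so replaying the
    ledger from the initial state reconstructs the volume exactly.
    """
    if event.time_h < state.time_h:
        raise ValueError("events must not move backwards in time")
    if isinstance(event, FeedEvent):
        if event.volume_ml < 0:
            raise ValueError("feed volume must be >= 0")
        new_volume = state.volume_ml + event.volume_ml
        glucose = state.glucose_mm
    elif isinstance(event, SampleEvent):
        if not (0 <= event.volume_ml < state.volume_ml):
            raise ValueError("sample volume must be < bag volume")
        new_volume = state.volume_ml - event.volume_ml
        glucose = state.glucose_mm
    elif isinstance(event, MeasurementEvent):
        new_volume = state.volume_ml
        glucose = event.measured_mm
    else:
        raise TypeError(f"unknown event type: {type(event).__name__}")
    return BagState(
        volume_ml=new_volume,
        glucose_mm=glucose,
        time_h=event.time_h,
        ledger=state.ledger + (event,),
    )


def replay_ledger(initial: BagState) -> BagState:
    """Re-fold a state's ledger from the initial conditions."""
    state = BagState(
        volume_ml=initial.volume_ml, glucose_mm=initial.glucose_mm,
        time_h=initial.time_h,
    )
    for event in initial.ledger:
        state = apply_event(state, event)
    return state


@dataclass
class PerformanceReport:
    """Closed-loop run outcome: every measurement plus summary figures."""

    measurements: pd.DataFrame  # time_h, true_mm, measured_mm, in_band, fed_nl
    fraction_in_band: float
    n_measurements: int
    total_fed_ml: float
    final_volume_ml: float
    high_readings: int  # readings above target+band (flagged, never corrected)

    def summary(self) -> dict:
        return {
            "fraction_in_band": self.fraction_in_band,
            "n_measurements": self.n_measurements,
            "total_fed_ml": self.total_fed_ml,
            "final_volume_ml": self.final_volume_ml,
            "high_readings": self.high_readings,
        }


def run_closed_loop(
    bag: BagParams,
    cfg: ControllerConfig = ControllerConfig(),
    cal: PumpCalibration = PumpCalibration(),
    duration_h: float = 56 * 24.0,
    seed: int | None = None,
) -> PerformanceReport:
    """Couple the bag simulator with the two-layer controller.

    Feed-forward boluses run continuously at the scheduling granularity;
    at each glucometer time (``bag.measurement_interval_h``) the noisy
    reading is recorded and, if below target, a feedback bolus is delivered.
    Scheduled sampling withdrawals from ``bag.sampling_events`` are applied
    and booked so the controller's volume stays exact.  ``seed`` overrides
    ``bag.seed`` for the meter noise; a fixed seed gives identical reports.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if seed is not None:
        bag = replace(bag, seed=seed)
    sim = StorageBag(bag)
    dt = cfg.micro_bolus_interval_min / 60.0
    carry_nl = 0.0
    sampling = sorted(
        [(t, v) for t, v in bag.sampling_events if t <= duration_h]
    )
    next_meas = bag.measurement_interval_h
    rows = []
    high = 0

    t = 0.0
    while t < duration_h - 1e-9:
        t1 = min(t + dt, duration_h)
        # feed-forward: replace the mass the model predicts will be consumed
        mass = cfg.predicted_consumption_umol(t, t1)
        request_nl = mass / cfg.stock_mm * 1.0e6 + carry_nl
        dose = quantize_to_steps(request_nl, cal)
        carry_nl = dose.remainder_nl
        sim.advance(t1 - t)
        fed_nl = dose.delivered_nl
        if dose.n_steps > 0:
            sim.feed(dose.delivered_nl * 1.0e-6, cfg.stock_mm)
        while sampling and sampling[0][0] <= t1 + 1e-9:
            sim.sample(sampling.pop(0)[1])
        if next_meas <= t1 + 1e-9 and next_meas <= duration_h + 1e-9:
            measured = sim.measure()
            corrective_nl = 0.0
            if measured < cfg.target_mm:
                state = BagState(volume_ml=sim.volume_ml, glucose_mm=measured,
                                 time_h=sim.time_h)
                v_ml = feedback_bolus_volume(measured, state, cfg)
                dose = quantize_to_steps(v_ml * 1.0e6 + carry_nl, cal)
                carry_nl = dose.remainder_nl
                if dose.n_steps > 0:
                    sim.feed(dose.delivered_nl * 1.0e-6, cfg.stock_mm)
                    corrective_nl = dose.delivered_nl
            elif measured > cfg.target_mm + cfg.band_mm:
                high += 1
            rows.append(
                {
                    "time_h": sim.time_h,
                    "true_mm": sim.glucose_mm,
                    "measured_mm": measured,
                    "in_band": abs(measured - cfg.target_mm) <= cfg.band_mm,
                    "fed_nl": fed_nl + corrective_nl,
                }
            )
            next_meas += bag.measurement_interval_h
        t = t1

    df = pd.DataFrame(
        rows, columns=["time_h", "true_mm", "measured_mm", "in_band", "fed_nl"]
    )
    frac = float(df["in_band"].mean()) if len(df) else math.nan
    return PerformanceReport(
        measurements=df,
        fraction_in_band=frac,
        n_measurements=len(df),
        total_fed_ml=sim.total_fed_ml,
        final_volume_ml=sim.volume_ml,
        high_readings=high,
    )
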