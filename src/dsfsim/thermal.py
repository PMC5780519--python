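"""Discrete-time simulation of the plate heating hardware.

The real instrument is a silicone heat pad driven through a solid-state
relay by a microcontroller that reads an NTC glass-bead thermistor,
averages several readings, and closes a PID loop around the pad
temperature.  A measurement run steps the setpoint from room temperature
to a ceiling (typically 95 °C) in fixed increments, dwelling at each step
for incubation and a fluorescence read.

This module reproduces that behaviour in software: the thermistor
beta-equation, sensor-reading averaging, a clamped PID law with
anti-windup, a first-order lumped heat-pad plant integrated with explicit
Euler, and the heat/incubate/measure step scheduler.  All temperatures
are degrees Celsius at the API surface; kelvin appears only inside the
beta-equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

KELVIN_OFFSET = 273.15

__all__ = [
    "ThermistorSpec",
    "PIDConfig",
    "PIDState",
    "HeatPadPlant",
    "Schedule",
    "TemperatureTrace",
    "ntc_temperature",
    "temperature_to_resistance",
    "average_sensor_readings",
    "pid_update",
    "build_schedule",
    "simulate_heat_pad",
    "pad_surface_temperature",
]


@dataclass(frozen=True)
class ThermistorSpec:
    """NTC thermistor constants for the beta-equation.

    Parameters
    ----------
    beta : float
        Material constant in kelvin; controls the steepness of the
        resistance-temperature curve.
    r0 : float
        Resistance in ohm at the reference temperature ``t0``.
    t0 : float
        Reference temperature in kelvin (298.15 K for the common 25 °C
        rating).
    """

    beta: float = 3950.0
    r0: float = 10_000.0
    t0: float = 298.15

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.r0 <= 0 or self.t0 <= 0:
            raise ValueError("beta, r0 and t0 must all be positive")


def ntc_temperature(resistance, spec: ThermistorSpec = ThermistorSpec()):
    """Convert an NTC thermistor resistance to temperature in °C.

    Uses the beta-equation 1/T = 1/T0 + ln(R/R0)/beta with T in kelvin.
    Accepts scalars or arrays; strictly decreasing in resistance.
    """
    r = np.asarray(resistance, dtype=float)
    if np.any(r <= 0):
        raise ValueError("thermistor resistance must be positive")
    inv_t = 1.0 / spec.t0 + np.log(r / spec.r0) / spec.beta
    t_c = 1.0 / inv_t - KELVIN_OFFSET
    return float(t_c) if np.isscalar(resistance) else t_c


def temperature_to_resistance(t_c, spec: ThermistorSpec = ThermistorSpec()):
    """Inverse of :func:`ntc_temperature` (°C in, ohm out)."""
    t_k = np.asarray(t_c, dtype=float) + KELVIN_OFFSET
    if np.any(t_k <= 0):
        raise ValueError("temperature below absolute zero")
    r = spec.r0 * np.exp(spec.beta * (1.0 / t_k - 1.0 / spec.t0))
    return float(r) if np.isscalar(t_c) else r


def average_sensor_readings(samples) -> float:
    """Arithmetic mean of a window of temperature readings (°C).

    The firmware averages several thermistor reads per control decision
    to suppress ADC noise; an empty window is a programming error.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty window of sensor readings")
    return float(arr.mean())


@dataclass(frozen=True)
class PIDConfig:
    """Gains and timing of the duty-cycle PID controller.

    ``kp``/``ki``/``kd`` are in duty per °C, per °C·s and per °C/s.  The
    integral contribution (``ki`` times the accumulated error) is clamped
    to ±``integral_clamp`` duty units for anti-windup.  ``n_average``
    thermistor readings are averaged per control tick of ``tick`` seconds.
    """

    kp: float = 0.5
    ki: float = 0.02
    kd: float = 0.0
    duty_min: float = 0.0
    duty_max: float = 1.0
    integral_clamp: float = 1.0
    tick: float = 1.0
    n_average: int = 8

    def __post_init__(self) -> None:
        if not self.duty_min < self.duty_max:
            raise ValueError("duty_min must be below duty_max")
        if self.tick <= 0:
            raise ValueError("tick must be positive")
        if self.n_average < 1:
            raise ValueError("n_average must be at least 1")


@dataclass(frozen=True)
class PIDState:
    """Controller memory: accumulated error integral and previous error."""

    integral: float = 0.0  # °C·s
    prev_error: Optional[float] = None


def pid_update(
    state: PIDState,
    setpoint: float,
    measured: float,
    dt: float,
    cfg: PIDConfig,
) -> tuple[float, PIDState]:
    """One PID control decision.

    Returns the commanded duty cycle, clamped into
    ``[duty_min, duty_max]``, and the updated controller state.  The
    integral term is clamped so its contribution never exceeds
    ±``integral_clamp`` duty units (anti-windup); saturation of the output
    is a valid, non-error condition.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    error = setpoint - measured
    integral = state.integral + error * dt
    if cfg.ki > 0:
        bound = cfg.integral_clamp / cfg.ki
        integral = float(np.clip(integral, -bound, bound))
    derivative = 0.0 if state.prev_error is None else (error - state.prev_error) / dt
    duty = cfg.kp * error + cfg.ki * integral + cfg.kd * derivative
    duty = float(np.clip(duty, cfg.duty_min, cfg.duty_max))
    return duty, PIDState(integral=integral, prev_error=error)


@dataclass(frozen=True)
class Schedule:
    """Ordered heat/incubate/measure step programme.

    Setpoints run from ``start`` upward in increments of ``step`` without
    exceeding ``ceiling``; each step dwells ``dwell`` minutes for
    incubation plus measurement.
    """

    start: float
    step: float
    ceiling: float
    dwell: float  # minutes

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("temperature step must be positive")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")
        if self.ceiling < self.start:
            raise ValueError("ceiling must be at or above start")

    @property
    def setpoints(self) -> np.ndarray:
        n = int(np.floor((self.ceiling - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def n_steps(self) -> int:
        return len(self.setpoints)

    @property
    def total_minutes(self) -> float:
        return self.n_steps * self.dwell


def build_schedule(
    start: float = 25.0,
    step: float = 3.0,
    ceiling: float = 95.0,
    dwell: float = 5.0,
) -> Schedule:
    """Build the step schedule; defaults give 24 setpoints over 120 min.

    The default programme (25 °C start, 3 °C steps to a 95 °C ceiling,
    5 min dwell per step) is the instrument's standard two-hour run.
    """
    return Schedule(start=float(start), step=float(step), ceiling=float(ceiling), dwell=float(dwell))


@dataclass(frozen=True)
class HeatPadPlant:
    """First-order lumped thermal model of the silicone heat pad.

    dT/dt = (max_power·duty − loss_coeff·(T − t_ambient)) / heat_capacity.

    ``sensor_noise_sd`` is the per-reading Gaussian noise of the
    thermistor chain.  ``surface_gain``/``surface_offset`` hold the
    calibrated linear map from software setpoint to pad-surface
    temperature (near-identity on the calibrated instrument).
    """

    heat_capacity: float = 60.0  # J/°C
    max_power: float = 50.0  # W
    loss_coeff: float = 0.5  # W/°C
    t_ambient: float = 25.0  # °C
    sensor_noise_sd: float = 0.1  # °C per reading
    surface_gain: float = 1.008
    surface_offset: float = 0.366  # °C

    def __post_init__(self) -> None:
        if self.heat_capacity <= 0 or self.max_power <= 0 or self.loss_coeff <= 0:
            raise ValueError("heat_capacity, max_power and loss_coeff must be positive")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")


def pad_surface_temperature(setpoint, plant: HeatPadPlant = HeatPadPlant()):
    """Calibrated pad-surface temperature for a software setpoint (°C)."""
    return plant.surface_gain * np.asarray(setpoint, dtype=float) + plant.surface_offset


@dataclass(frozen=True)
class TemperatureTrace:
    """Per-tick record of a closed-loop heating run (aligned arrays)."""

    time: np.ndarray  # s
    setpoint: np.ndarray  # °C
    pad_temp: np.ndarray  # °C
    duty: np.ndarray  # [duty_min, duty_max]
    step_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("setpoint", "pad_temp", "duty", "step_index"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace series must share one length")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (time, setpoint, pad_temp, duty) for export."""
        return pd.DataFrame(
            {
                "time_s": self.time,
                "setpoint_C": self.setpoint,
                "pad_temp_C": self.pad_temp,
                "duty": self.duty,
            }
        )

    def terminal_temperatures(self) -> np.ndarray:
        """Pad temperature at the last tick of each schedule step."""
        last = np.flatnonzero(np.diff(self.step_index) != 0)
        last = np.append(last, len(self.step_index) - 1)
        return self.pad_temp[last]


def simulate_heat_pad(
    plant: HeatPadPlant = HeatPadPlant(),
    cfg: PIDConfig = PIDConfig(),
    schedule: Schedule = None,
    seed: int = 0,
) -> TemperatureTrace:
    """Closed-loop simulation of the PID-controlled heat pad.

    Per control tick: draw ``n_average`` noisy thermistor readings of the
    true pad temperature, average them, run one PID update, and advance
    the first-order plant by explicit Euler.  Controller state persists
    across schedule steps, as in the firmware.  Deterministic for a fixed
    seed.
    """
    if schedule is None:
        schedule = build_schedule()
    setpoints = schedule.setpoints
    if len(setpoints) == 0:
        raise ValueError("schedule has no setpoints")
    rng = np.random.default_rng(seed)
    ticks_per_step = max(1, int(round(schedule.dwell * 60.0 / cfg.tick)))
    n_total = ticks_per_step * len(setpoints)

    time = np.empty(n_total)
    sp_series = np.empty(n_total)
    pad = np.empty(n_total)
    duty_series = np.empty(n_total)
    step_series = np.empty(n_total, dtype=int)

    temp = plant.t_ambient
    state = PIDState()
    k = 0
    for i_step, sp in enumerate(setpoints):
        for _ in range(ticks_per_step):
            if plant.sensor_noise_sd > 0:
                readings = temp + rng.normal(0.0, plant.sensor_noise_sd, cfg.n_average)
            else:
                readings = np.full(cfg.n_average, temp)
            measured = average_sensor_readings(readings)
            duty, state = pid_update(state, sp, measured, cfg.tick, cfg)
            dT = (plant.max_power * duty - plant.loss_coeff * (temp - plant.t_ambient)) / plant.heat_capacity
            temp += cfg.tick * dT
            time[k] = (k + 1) * cfg.tick
            sp_series[k] = sp
            pad[k] = temp
            duty_series[k] = duty
            step_series[k] = i_step
            k += 1
    return TemperatureTrace(
        time=time, setpoint=sp_series, pad_temp=pad, duty=duty_series, step_index=step_series
    )
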