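"""Synthetic plate-run generator.

Maps heat-pad temperature to in-well sample temperature through the
calibrated linear lag (wells run cooler than the pad because the plate
conducts poorly), evaluates a dye-specific fluorescence model of
two-state unfolding per well, and assembles the per-step readings of a
whole 96-well run.  Dye families cover SYPRO Orange (hydrophobic-core
binding), CPM (thiol-reactive, shallower multi-step transitions) and
ThermoFAD (flavin release).  Artefact effects are modelled explicitly:
post-denaturation signal decay, amplitude loss after air exposure of
oxygen-sensitive samples, and temperature-coupled additive interference
such as the DDAO detergent produces in blanks and samples alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .thermal import Schedule

__all__ = [
    "WellThermalModel",
    "Transition",
    "UnfoldingModel",
    "DyeModel",
    "DYE_KINDS",
    "WellAssignment",
    "PlateLayout",
    "RawRun",
    "pad_to_well_temperature",
    "unfolded_fraction",
    "interference_profile",
    "fluorescence_signal",
    "simulate_plate_run",
]

DYE_KINDS = ("SYPRO", "CPM", "FAD")

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


@dataclass(frozen=True)
class WellThermalModel:
    """Linear pad-to-well temperature transfer with well-to-well scatter.

    Defaults are the calibrated instrument constants: the well
    temperature tracks 0.681 of the pad temperature plus 7.034 °C, with
    0.8 °C Gaussian spread between plate positions.
    """

    gain: float = 0.681
    offset: float = 7.034  # °C
    well_noise_sd: float = 0.8  # °C

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.well_noise_sd < 0:
            raise ValueError("well_noise_sd must be non-negative")


def pad_to_well_temperature(
    t_pad,
    model: WellThermalModel = WellThermalModel(),
    rng: Union[np.random.Generator, int, None] = None,
):
    """Sample-well temperature for a pad temperature (°C).

    ``rng`` (a Generator or an integer seed) supplies the Gaussian
    well-to-well noise and is required whenever ``well_noise_sd > 0``.
    """
    base = model.gain * np.asarray(t_pad, dtype=float) + model.offset
    if model.well_noise_sd > 0:
        if rng is None:
            raise ValueError("an rng or seed is required when well_noise_sd > 0")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        base = base + rng.normal(0.0, model.well_noise_sd, np.shape(base))
    return float(base) if np.isscalar(t_pad) else base


@dataclass(frozen=True)
class Transition:
    """One two-state unfolding transition: midpoint, slope factor, weight."""

    tm: float  # °C
    slope_factor: float  # °C
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.slope_factor <= 0:
            raise ValueError("slope_factor must be positive")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")


@dataclass(frozen=True)
class UnfoldingModel:
    """Weighted mixture of sigmoidal unfolding transitions.

    A single transition is the classic two-state melt.  Several closely
    spaced equal-weight transitions emulate the stepwise exposure of
    cysteine residues seen with CPM, which flattens the global curve;
    two well-separated transitions emulate sequential denaturation of
    subunits (double-sigmoid curves).
    """

    transitions: tuple[Transition, ...]

    def __post_init__(self) -> None:
        if len(self.transitions) == 0:
            raise ValueError("at least one transition is required")
        tms = [t.tm for t in self.transitions]
        if any(b <= a for a, b in zip(tms, tms[1:])):
            raise ValueError("transition midpoints must be strictly increasing")
        total = sum(t.weight for t in self.transitions)
        if abs(total - 1.0) > 1e-8:
            raise ValueError("transition weights must sum to 1")

    @classmethod
    def single(cls, tm: float, slope_factor: float = 1.5) -> "UnfoldingModel":
        return cls((Transition(tm, slope_factor, 1.0),))

    @classmethod
    def stepwise(
        cls, tm: float, n: int = 3, spread: float = 4.0, slope_factor: float = 2.5
    ) -> "UnfoldingModel":
        """``n`` equal-weight transitions spread ±``spread`` °C about ``tm``."""
        if n < 1:
            raise ValueError("n must be at least 1")
        centres = np.linspace(tm - spread, tm + spread, n) if n > 1 else np.array([tm])
        return cls(tuple(Transition(float(c), slope_factor, 1.0 / n) for c in centres))

    @classmethod
    def double(
        cls,
        tm1: float,
        tm2: float,
        frac: float = 0.5,
        slope1: float = 1.5,
        slope2: float = 1.5,
    ) -> "UnfoldingModel":
        return cls((Transition(tm1, slope1, frac), Transition(tm2, slope2, 1.0 - frac)))

    @property
    def t_full_denat(self) -> float:
        """Temperature past which the signal is treated as saturated."""
        last = self.transitions[-1]
        return last.tm + 3.0 * last.slope_factor


def unfolded_fraction(t_well, model: UnfoldingModel):
    """Unfolded fraction in [0, 1] at a well temperature.

    Sum over transitions of weight / (1 + exp((tm − T)/slope)); monotone
    non-decreasing in temperature.
    """
    t = np.asarray(t_well, dtype=float)
    out = np.zeros_like(t)
    for tr in model.transitions:
        out = out + tr.weight / (1.0 + np.exp((tr.tm - t) / tr.slope_factor))
    return float(out) if np.isscalar(t_well) else out


@dataclass(frozen=True)
class DyeModel:
    """Fluorescence response of one reporter dye (arbitrary units).

    ``interference_level`` scales a fixed monotone temperature-coupled
    background (the DDAO failure mode, visible in blanks too);
    ``aggregated_fraction`` removes that share of the protein-dependent
    amplitude, the signature of air-exposed oxygen-sensitive samples
    after aggregate removal; ``decay_rate`` is the linear signal loss per
    °C beyond full denaturation.
    """

    kind: str
    f_native: float
    f_unfolded: float
    background: float = 0.0
    decay_rate: float = 0.0  # AU/°C past full denaturation
    interference_level: float = 0.0  # AU
    aggregated_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in DYE_KINDS:
            raise ValueError(f"unknown dye kind {self.kind!r}; expected one of {DYE_KINDS}")
        if not self.f_unfolded > self.f_native >= 0:
            raise ValueError("need f_unfolded > f_native >= 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be non-negative")
        if not 0 <= self.aggregated_fraction < 1:
            raise ValueError("aggregated_fraction must be in [0, 1)")

    @classmethod
    def sypro(cls, **overrides) -> "DyeModel":
        defaults = dict(
            kind="SYPRO", f_native=100.0, f_unfolded=1100.0, background=50.0, decay_rate=8.0
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def cpm(cls, **overrides) -> "DyeModel":
        defaults = dict(
            kind="CPM", f_native=150.0, f_unfolded=1150.0, background=100.0, decay_rate=5.0
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def fad(cls, **overrides) -> "DyeModel":
        # intrinsic flavin release; spectrometer yields lower absolute counts
        defaults = dict(
            kind="FAD", f_native=80.0, f_unfolded=600.0, background=40.0, decay_rate=3.0
        )
        defaults.update(overrides)
        return cls(**defaults)


def interference_profile(t_well):
    """Fixed monotone temperature profile g(T) in [0, 1] for interference."""
    return 1.0 / (1.0 + np.exp((55.0 - np.asarray(t_well, dtype=float)) / 10.0))


def fluorescence_signal(
    fraction, t_well, dye: DyeModel, t_full_denat: float
) -> Union[float, np.ndarray]:
    """Deterministic fluorescence (AU) for an unfolded fraction at ``t_well``.

    F = background + interference_level·g(T)
        + (1 − aggregated_fraction)·[f_native + fraction·(f_unfolded − f_native)]
        − decay_rate·max(0, T − t_full_denat), floored at zero.
    """
    frac = np.asarray(fraction, dtype=float)
    if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
        raise ValueError("fraction must lie in [0, 1]")
    t = np.asarray(t_well, dtype=float)
    protein = (1.0 - dye.aggregated_fraction) * (
        dye.f_native + frac * (dye.f_unfolded - dye.f_native)
    )
    f = (
        dye.background
        + dye.interference_level * interference_profile(t)
        + protein
        - dye.decay_rate * np.maximum(0.0, t - t_full_denat)
    )
    f = np.maximum(f, 0.0)
    return float(f) if np.isscalar(fraction) and np.isscalar(t_well) else f


@dataclass(frozen=True)
class WellAssignment:
    """Contents of one well: condition, replicate group, dye, model."""

    condition: str
    replicate_group: str
    blank: bool
    dye: DyeModel
    unfolding: Optional[UnfoldingModel] = None

    def __post_init__(self) -> None:
        if self.blank and self.unfolding is not None:
            raise ValueError("blank wells carry no unfolding model")
        if not self.blank and self.unfolding is None:
            raise ValueError("non-blank wells require an unfolding model")


@dataclass(frozen=True)
class PlateLayout:
    """Map from well id (A1..H12) to its assignment."""

    wells: Mapping[str, WellAssignment]

    def __post_init__(self) -> None:
        if len(self.wells) == 0:
            raise ValueError("plate layout is empty")
        for well in self.wells:
            if not _WELL_RE.match(well):
                raise ValueError(f"invalid well id {well!r} (expected A1..H12)")

    @property
    def well_ids(self) -> list[str]:
        return sorted(self.wells, key=lambda w: (w[0], int(w[1:])))

    def conditions(self) -> list[str]:
        """Non-blank condition labels in plate order, unique."""
        seen: list[str] = []
        for w in self.well_ids:
            a = self.wells[w]
            if not a.blank and a.condition not in seen:
                seen.append(a.condition)
        return seen

    def blank_wells(self) -> list[str]:
        return [w for w in self.well_ids if self.wells[w].blank]


@dataclass(frozen=True)
class RawRun:
    """One simulated or recorded run: per-step, per-well fluorescence.

    ``table`` is long format with columns (step, setpoint, well,
    fluorescence); setpoints are on the pad scale.  Record count is
    n_steps × n_wells by construction.
    """

    schedule: Schedule
    table: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"step", "setpoint", "well", "fluorescence"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"run table needs columns {sorted(required)}")
        wells = self.well_ids
        if len(self.table) != self.schedule.n_steps * len(wells):
            raise ValueError("record count must equal n_steps × n_wells")
        sched_sp = self.schedule.setpoints
        for step, grp in self.table.groupby("step"):
            if not np.allclose(grp["setpoint"], sched_sp[int(step)]):
                raise ValueError(f"step {step} setpoints disagree with the schedule")

    @property
    def well_ids(self) -> list[str]:
        return sorted(self.table["well"].unique(), key=lambda w: (w[0], int(w[1:])))

    def well_signal(self, well: str) -> np.ndarray:
        sub = self.table[self.table["well"] == well].sort_values("step")
        if len(sub) != self.schedule.n_steps:
            raise ValueError(f"well {well!r} missing steps")
        return sub["fluorescence"].to_numpy()

    def to_tidy(self) -> pd.DataFrame:
        """Long-format copy of the readings table."""
        return self.table.copy().reset_index(drop=True)

    @classmethod
    def from_tidy(
        cls, table: pd.DataFrame, schedule: Schedule, metadata: Optional[dict] = None
    ) -> "RawRun":
        return cls(schedule=schedule, table=table.reset_index(drop=True), metadata=metadata or {})


def simulate_plate_run(
    layout: PlateLayout,
    schedule: Schedule,
    well_model: WellThermalModel = WellThermalModel(),
    seed: int = 0,
    noise_rel: float = 0.02,
    noise_floor: float = 1.0,
) -> RawRun:
    """Simulate a full plate run and return its readings.

    For every schedule step and well: pad setpoint → well temperature
    (with well-to-well scatter) → unfolded fraction → dye fluorescence,
    plus Gaussian measurement noise of sd ``noise_rel·|signal| +
    noise_floor``.  Blanks contribute background and interference only.
    Deterministic for a fixed seed; the recorded temperature axis is the
    pad setpoint scale, as on the real instrument.
    """
    rng = np.random.default_rng(seed)
    wells = layout.well_ids
    records = []
    for i_step, sp in enumerate(schedule.setpoints):
        for well in wells:
            a = layout.wells[well]
            t_well = pad_to_well_temperature(float(sp), well_model, rng)
            if a.blank:
                signal = a.dye.background + a.dye.interference_level * float(
                    interference_profile(t_well)
                )
            else:
                frac = unfolded_fraction(t_well, a.unfolding)
                signal = fluorescence_signal(frac, t_well, a.dye, a.unfolding.t_full_denat)
            sd = noise_rel * abs(signal) + noise_floor
            if sd > 0:
                signal = signal + rng.normal(0.0, sd)
            records.append((i_step, float(sp), well, float(signal)))
    table = pd.DataFrame(records, columns=["step", "setpoint", "well", "fluorescence"])
    meta = {
        "seed": int(seed),
        "dyes": sorted({a.dye.kind for a in layout.wells.values()}),
        "n_wells": len(wells),
    }
    return RawRun(schedule=schedule, table=table, metadata=meta)
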