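"""Melting-curve evaluation and thermal-shift screening.

Pipeline mirroring standard DSF practice: subtract the protein-free
blank, average replicate curves, discard the post-denaturation decay
tail, fit a Boltzmann sigmoid (or a double Boltzmann when the curve
shows two inflection points), fall back to the second-derivative
zero-crossing when a fit will not converge, and tabulate melting
temperatures and ΔTm values across screening conditions.  Temperatures
are on the heat-pad scale by default; a calibration line converts them
to the true in-well scale on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .instrument import PlateLayout, RawRun

__all__ = [
    "MeltCurve",
    "BoltzmannFit",
    "DoubleBoltzmannFit",
    "CalibrationLine",
    "ScreenReport",
    "boltzmann",
    "double_boltzmann",
    "smooth_signal",
    "subtract_blank",
    "average_replicates",
    "truncate_post_denaturation",
    "count_inflections",
    "fit_boltzmann",
    "fit_double_boltzmann",
    "tm_by_second_derivative",
    "fit_calibration",
    "apply_well_calibration",
    "delta_tm",
    "fold_cmc",
    "analyze_run",
]

# Default signal-to-noise ratio below which a curve is called "no melt":
# the smoothed signal range must exceed this multiple of the robust
# noise estimate before a transition is believed.
SNR_MIN = 3.0
# Goodness-of-fit gate: the fitted amplitude must exceed this multiple of
# the fit's residual RMSE, else the "transition" is noise structure (the
# signature of interference-swamped curves, where apparent amplitudes run
# only ~2-5x the residuals while genuine melts run ~40x and above).
FIT_SNR_MIN = 10.0
SMOOTH_WINDOW = 5


@dataclass(frozen=True)
class MeltCurve:
    """Fluorescence vs temperature for one condition (pad scale °C)."""

    temps: np.ndarray
    signal: np.ndarray
    sd: Optional[np.ndarray] = None
    n_replicates: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temps, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temps", t)
        object.__setattr__(self, "signal", y)
        if len(t) != len(y):
            raise ValueError("temps and signal must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.sd is not None:
            s = np.asarray(self.sd, dtype=float)
            if len(s) != len(t):
                raise ValueError("sd must match the grid length")
            object.__setattr__(self, "sd", s)

    def __len__(self) -> int:
        return len(self.temps)

    def slice(self, stop: int) -> "MeltCurve":
        return MeltCurve(
            temps=self.temps[:stop],
            signal=self.signal[:stop],
            sd=None if self.sd is None else self.sd[:stop],
            n_replicates=self.n_replicates,
            condition=self.condition,
        )


@dataclass(frozen=True)
class BoltzmannFit:
    """Four-parameter sigmoid fit: plateaus a1/a2, midpoint tm, slope dt."""

    a1: float
    a2: float
    tm: float
    dt: float
    tm_sd: float
    rss: float
    converged: bool
    no_melt: bool = False

    @property
    def ok(self) -> bool:
        return self.converged and not self.no_melt


@dataclass(frozen=True)
class DoubleBoltzmannFit:
    """Two-transition sigmoid fit with shared plateaus and mixing fraction."""

    a1: float
    a2: float
    frac: float
    tm1: float
    tm2: float
    dt1: float
    dt2: float
    tm1_sd: float
    tm2_sd: float
    rss: float
    converged: bool
    no_melt: bool = False

    @property
    def ok(self) -> bool:
        return self.converged and not self.no_melt


@dataclass(frozen=True)
class CalibrationLine:
    """OLS line y = slope·x + intercept with standard errors (°C scale)."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    resid_sd: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass(frozen=True)
class ScreenReport:
    """Per-condition melting temperatures, flags and ranking."""

    table: pd.DataFrame
    reference: Optional[str] = None


def boltzmann(t, a1, a2, tm, dt):
    """Sigmoid F(T) = a2 + (a1 − a2)/(1 + exp((T − tm)/dt)).

    ``a1`` is the pre-transition (low-temperature) plateau, ``a2`` the
    post-transition plateau, ``tm`` the midpoint and ``dt`` the slope
    factor, following the Origin-style parameterization.
    """
    with np.errstate(over="ignore"):
        return a2 + (a1 - a2) / (1.0 + np.exp((np.asarray(t, dtype=float) - tm) / dt))


def double_boltzmann(t, a1, a2, frac, tm1, tm2, dt1, dt2):
    """Two-transition sigmoid with shared plateaus and fraction ``frac``."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        s1 = frac / (1.0 + np.exp((t - tm1) / dt1))
        s2 = (1.0 - frac) / (1.0 + np.exp((t - tm2) / dt2))
    return a2 + (a1 - a2) * (s1 + s2)


def smooth_signal(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centred moving average with edge replication; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    y = np.asarray(y, dtype=float)
    if window == 1 or len(y) < 2:
        return y.copy()
    half = window // 2
    padded = np.concatenate([np.full(half, y[0]), y, np.full(half, y[-1])])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _noise_estimate(y: np.ndarray, window: int = SMOOTH_WINDOW) -> float:
    """Robust per-point noise sd from residuals about the smoothed curve."""
    resid = np.asarray(y, dtype=float) - smooth_signal(y, window)
    return float(1.4826 * np.median(np.abs(resid)))


def subtract_blank(curve: MeltCurve, blank: MeltCurve) -> MeltCurve:
    """Pointwise blank subtraction; sds combine in quadrature."""
    if len(curve) != len(blank) or not np.allclose(curve.temps, blank.temps):
        raise ValueError("curve and blank must share the temperature grid")
    sd = None
    if curve.sd is not None and blank.sd is not None:
        sd = np.sqrt(curve.sd**2 + blank.sd**2)
    elif curve.sd is not None:
        sd = curve.sd.copy()
    elif blank.sd is not None:
        sd = blank.sd.copy()
    return MeltCurve(
        temps=curve.temps.copy(),
        signal=curve.signal - blank.signal,
        sd=sd,
        n_replicates=curve.n_replicates,
        condition=curve.condition,
    )


def average_replicates(curves: Sequence[MeltCurve]) -> MeltCurve:
    """Pointwise mean of replicate curves with sample sd per point.

    The sd is flagged unavailable (None) for a single replicate.
    """
    if len(curves) == 0:
        raise ValueError("no replicate curves to average")
    grid = curves[0].temps
    for c in curves[1:]:
        if len(c) != len(curves[0]) or not np.allclose(c.temps, grid):
            raise ValueError("replicates must share the temperature grid")
    stack = np.vstack([c.signal for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) >= 2 else None
    return MeltCurve(
        temps=grid.copy(),
        signal=mean,
        sd=sd,
        n_replicates=len(curves),
        condition=curves[0].condition,
    )


def truncate_post_denaturation(curve: MeltCurve, window: int = SMOOTH_WINDOW) -> MeltCurve:
    """Drop the decaying tail past the fluorescence maximum.

    The peak is located on the lightly smoothed signal and then refined
    to the raw maximum within half a smoothing window; ties break toward
    the higher temperature so no usable data are lost.  Only the trailing
    segment is ever removed.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points to truncate")
    smoothed = smooth_signal(curve.signal, window)
    peak = int(np.flatnonzero(smoothed == smoothed.max())[-1])
    lo = max(0, peak - window // 2)
    hi = min(len(curve), peak + window // 2 + 1)
    local = curve.signal[lo:hi]
    peak = lo + int(np.flatnonzero(local == local.max())[-1])
    if peak >= len(curve) - 1:
        return curve
    return curve.slice(peak + 1)


def count_inflections(
    curve: MeltCurve,
    prominence_frac: float = 0.25,
    min_separation: int = 3,
    window: int = SMOOTH_WINDOW,
    snr_min: float = SNR_MIN,
) -> int:
    """Number of unfolding transitions visible in the curve (0, 1 or 2).

    Counts well-separated peaks of the smoothed first difference whose
    prominence exceeds ``prominence_frac`` of the maximum slope.  Curves
    whose smoothed range does not clear ``snr_min`` times the robust
    noise estimate are reported as 0 (no melt).  Counts above two are
    capped at two, the largest model the fitter distinguishes.
    """
    if len(curve) < 7:
        raise ValueError("need at least 7 points to count inflections")
    smoothed = smooth_signal(curve.signal, window)
    rise = smoothed.max() - smoothed.min()
    noise = _noise_estimate(curve.signal, window)
    if rise <= 0 or (noise > 0 and rise < snr_min * noise):
        return 0
    slope = np.diff(smoothed) / np.diff(curve.temps)
    if slope.max() <= 0:
        return 0
    # sentinel padding so maxima at the ends still register as peaks
    padded = np.concatenate([[slope.min() - 1.0], slope, [slope.min() - 1.0]])
    peaks, _ = signal.find_peaks(
        padded, prominence=prominence_frac * slope.max(), distance=min_separation
    )
    return int(min(len(peaks), 2))


def _initial_boltzmann_guess(curve: MeltCurve, window: int) -> tuple[float, float, float, float]:
    n = len(curve)
    decile = max(1, n // 10)
    a1 = float(curve.signal[:decile].mean())
    a2 = float(curve.signal[-decile:].mean())
    smoothed = smooth_signal(curve.signal, window)
    slope = np.diff(smoothed) / np.diff(curve.temps)
    i = int(np.argmax(slope))
    tm = float(0.5 * (curve.temps[i] + curve.temps[i + 1]))
    dt = float(np.median(np.diff(curve.temps)))
    return a1, a2, tm, dt


def fit_boltzmann(
    curve: MeltCurve, window: int = SMOOTH_WINDOW, snr_min: float = SNR_MIN
) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid fit of a truncated melt curve.

    Initialised from the data (plateaus from the first/last decile means,
    midpoint from the steepest ascent, slope from the grid step).  Flat
    or noise-dominated curves — fitted amplitude below ``snr_min`` times
    the robust noise level — return a no-melt result rather than raising.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 points to fit")
    a1, a2, tm0, dt0 = _initial_boltzmann_guess(curve, window)
    t, y = curve.temps, curve.signal
    noise = _noise_estimate(y, window)
    smoothed = smooth_signal(y, window)
    rise = smoothed.max() - smoothed.min()
    if rise <= 0 or (noise > 0 and rise < snr_min * noise):
        return BoltzmannFit(a1, a2, np.nan, dt0, np.nan, np.nan, converged=False, no_melt=True)
    span = t[-1] - t[0]
    bounds = (
        [-np.inf, -np.inf, t[0], 1e-3],
        [np.inf, np.inf, t[-1], max(span, 1e-2)],
    )
    tm0 = float(np.clip(tm0, t[0], t[-1]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                boltzmann, t, y, p0=[a1, a2, tm0, dt0], bounds=bounds, maxfev=20_000
            )
    except (RuntimeError, ValueError):
        return BoltzmannFit(a1, a2, np.nan, dt0, np.nan, np.nan, converged=False, no_melt=False)
    a1f, a2f, tmf, dtf = (float(v) for v in popt)
    resid = y - boltzmann(t, *popt)
    rss = float(np.sum(resid**2))
    tm_sd = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    if noise > 0 and abs(a2f - a1f) < snr_min * noise:
        return BoltzmannFit(a1f, a2f, tmf, dtf, tm_sd, rss, converged=False, no_melt=True)
    rmse = np.sqrt(rss / max(len(t) - 4, 1))
    if rmse > 0 and abs(a2f - a1f) < FIT_SNR_MIN * rmse:
        return BoltzmannFit(a1f, a2f, tmf, dtf, tm_sd, rss, converged=True, no_melt=True)
    return BoltzmannFit(a1f, a2f, tmf, dtf, tm_sd, rss, converged=True)


def fit_double_boltzmann(
    curve: MeltCurve, window: int = SMOOTH_WINDOW, snr_min: float = SNR_MIN
) -> DoubleBoltzmannFit:
    """Least-squares two-transition sigmoid fit (midpoints ordered tm1 < tm2)."""
    if len(curve) < 7:
        raise ValueError("need at least 7 points to fit two transitions")
    t, y = curve.temps, curve.signal
    n = len(curve)
    decile = max(1, n // 10)
    a1 = float(y[:decile].mean())
    a2 = float(y[-decile:].mean())
    noise = _noise_estimate(y, window)
    smoothed = smooth_signal(y, window)
    rise = smoothed.max() - smoothed.min()
    if rise <= 0 or (noise > 0 and rise < snr_min * noise):
        return DoubleBoltzmannFit(
            a1, a2, 0.5, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            converged=False, no_melt=True,
        )
    slope = np.diff(smoothed) / np.diff(t)
    peaks, _ = signal.find_peaks(slope, distance=3)
    if len(peaks) >= 2:
        top = peaks[np.argsort(slope[peaks])[-2:]]
        tm1_0, tm2_0 = sorted(float(t[i]) for i in top)
    else:
        tm1_0 = float(np.quantile(t, 0.35))
        tm2_0 = float(np.quantile(t, 0.7))
    dt0 = float(np.median(np.diff(t)))
    span = t[-1] - t[0]
    bounds = (
        [-np.inf, -np.inf, 1e-3, t[0], t[0], 1e-3, 1e-3],
        [np.inf, np.inf, 1.0 - 1e-3, t[-1], t[-1], span, span],
    )
    p0 = [a1, a2, 0.5, tm1_0, tm2_0, dt0, dt0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                double_boltzmann, t, y, p0=p0, bounds=bounds, maxfev=40_000
            )
    except (RuntimeError, ValueError):
        return DoubleBoltzmannFit(
            a1, a2, 0.5, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            converged=False, no_melt=False,
        )
    a1f, a2f, frac, tm1, tm2, dt1, dt2 = (float(v) for v in popt)
    sd1 = float(np.sqrt(pcov[3, 3])) if np.isfinite(pcov[3, 3]) else np.nan
    sd2 = float(np.sqrt(pcov[4, 4])) if np.isfinite(pcov[4, 4]) else np.nan
    if tm1 > tm2:  # ordering contract, swap the two transitions
        tm1, tm2 = tm2, tm1
        dt1, dt2 = dt2, dt1
        sd1, sd2 = sd2, sd1
        frac = 1.0 - frac
    resid = y - double_boltzmann(t, *popt)
    rss = float(np.sum(resid**2))
    rmse = np.sqrt(rss / max(len(t) - 7, 1))
    no_melt = bool(rmse > 0 and abs(a2f - a1f) < FIT_SNR_MIN * rmse)
    return DoubleBoltzmannFit(
        a1f, a2f, frac, tm1, tm2, dt1, dt2, sd1, sd2, rss, converged=True, no_melt=no_melt
    )


def tm_by_second_derivative(
    curve: MeltCurve, window: int = SMOOTH_WINDOW
) -> Optional[float]:
    """Melting point from the zero-crossing of the second derivative.

    The signal is smoothed, differentiated twice numerically, and the
    sign change nearest the point of steepest ascent is located by
    linear interpolation.  Returns None (no melt) when no genuine sign
    change exists, e.g. on linear or flat curves.
    """
    if len(curve) < 7:
        raise ValueError("need at least 7 points for the derivative method")
    t = curve.temps
    smoothed = smooth_signal(curve.signal, window)
    d1 = np.gradient(smoothed, t)
    d2 = np.gradient(d1, t)
    # edge-replicated smoothing bends the curve ends, and the numerical
    # derivatives spread that contamination two more points inward;
    # search the clean interior only
    half = window // 2
    lo, hi = half + 2, len(d2) - half - 2
    if hi <= lo:
        return None
    interior = d2[lo:hi]
    scale = np.max(np.abs(interior)) if len(interior) else 0.0
    # curvature must be significant relative to the signal, not float dust
    h = float(np.median(np.diff(t)))
    rise = float(np.ptp(smoothed))
    if scale * h * h <= 1e-9 * max(rise, 1e-12):
        return None
    tol = 1e-6 * scale
    i_steep = lo + int(np.argmax(d1[lo:hi]))
    crossings = [
        i for i in range(lo, hi - 1) if d2[i] > tol and d2[i + 1] <= 0.0
    ]
    if not crossings:
        return None
    best = min(crossings, key=lambda i: abs(i - i_steep))
    f0, f1 = d2[best], d2[best + 1]
    frac = f0 / (f0 - f1)
    return float(t[best] + frac * (t[best + 1] - t[best]))


def fit_calibration(set_temps, measured) -> CalibrationLine:
    """OLS calibration line through (set temperature, measured temperature)."""
    x = np.asarray(set_temps, dtype=float)
    y = np.asarray(measured, dtype=float)
    if len(x) != len(y):
        raise ValueError("set_temps and measured must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(x) == 0:
        raise ValueError("set temperatures have zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = len(x) - 2
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        resid_sd=resid_sd,
    )


def apply_well_calibration(tm_pad, cal: CalibrationLine):
    """Convert a pad-scale melting temperature to the in-well scale."""
    out = cal.slope * np.asarray(tm_pad, dtype=float) + cal.intercept
    return float(out) if np.isscalar(tm_pad) else out


def delta_tm(fit_a, fit_b) -> Optional[tuple[float, float]]:
    """Thermal shift tm_a − tm_b with sds combined in quadrature.

    Accepts Boltzmann fits (uses ``tm``) or bare (tm, tm_sd) pairs.
    Returns None when either side is a failed/no-melt fit.
    """

    def unpack(f):
        if f is None:
            return None
        if isinstance(f, (BoltzmannFit,)):
            if not f.ok:
                return None
            return f.tm, f.tm_sd
        if isinstance(f, DoubleBoltzmannFit):
            if not f.ok:
                return None
            return f.tm1, f.tm1_sd
        tm, sd = f
        return float(tm), float(sd)

    a = unpack(fit_a)
    b = unpack(fit_b)
    if a is None or b is None:
        return None
    shift = a[0] - b[0]
    sa = 0.0 if not np.isfinite(a[1]) else a[1]
    sb = 0.0 if not np.isfinite(b[1]) else b[1]
    return float(shift), float(np.hypot(sa, sb))


def fold_cmc(concentration: float, cmc: float) -> float:
    """Detergent dose as a multiple of its critical micellar concentration.

    Both arguments share units (e.g. % w/v); the result is reported to
    one decimal, the convention for fold-CMC figures.
    """
    if cmc <= 0:
        raise ValueError("cmc must be positive")
    return round(concentration / cmc, 1)


def _replicate_tm_sd(curves: Sequence[MeltCurve], n_transitions: int) -> Optional[float]:
    """sd of per-replicate fitted Tm values; None if too few converge."""
    tms = []
    for c in curves:
        try:
            trunc = truncate_post_denaturation(c)
            if n_transitions == 2 and len(trunc) >= 7:
                f = fit_double_boltzmann(trunc)
                if f.ok:
                    tms.append(f.tm1)
            else:
                f = fit_boltzmann(trunc)
                if f.ok:
                    tms.append(f.tm)
        except ValueError:
            continue
    if len(tms) >= 2:
        return float(np.std(tms, ddof=1))
    return None


def analyze_run(
    run: RawRun,
    layout: PlateLayout,
    reference: Optional[str] = None,
    calibration: Optional[CalibrationLine] = None,
    well_scale: bool = False,
    snr_min: float = SNR_MIN,
) -> ScreenReport:
    """Full screening analysis of one plate run.

    Per non-blank condition: subtract the condition-matched mean blank
    (falling back to the plate-wide blank), average replicates, truncate
    the post-denaturation tail, choose the model from the inflection
    count, fit, and fall back to the second-derivative zero-crossing
    when the fit fails.  Reported Tm sd is the sd over replicate-wise
    fits when at least three replicates converge, else the fit standard
    error.  Rows are ranked by Tm (descending); ΔTm columns appear when
    a reference condition is given.
    """
    if well_scale and calibration is None:
        raise ValueError("well_scale requires a calibration line")
    missing = [w for w in run.well_ids if w not in layout.wells]
    if missing:
        raise ValueError(f"wells present in run but absent from layout: {missing}")

    temps = run.schedule.setpoints

    def curve_for(well: str) -> MeltCurve:
        a = layout.wells[well]
        return MeltCurve(temps=temps, signal=run.well_signal(well), condition=a.condition)

    blank_by_condition: dict[str, MeltCurve] = {}
    blank_wells = [w for w in run.well_ids if layout.wells[w].blank]
    for w in blank_wells:
        cond = layout.wells[w].condition
        blank_by_condition.setdefault(cond, None)
    for cond in list(blank_by_condition):
        members = [curve_for(w) for w in blank_wells if layout.wells[w].condition == cond]
        blank_by_condition[cond] = average_replicates(members)
    plate_blank = average_replicates([curve_for(w) for w in blank_wells]) if blank_wells else None

    rows = []
    for cond in layout.conditions():
        wells = [
            w
            for w in run.well_ids
            if not layout.wells[w].blank and layout.wells[w].condition == cond
        ]
        blank = blank_by_condition.get(cond, plate_blank)
        reps = []
        for w in wells:
            c = curve_for(w)
            if blank is not None:
                c = subtract_blank(c, blank)
            reps.append(c)
        avg = average_replicates(reps)
        trunc = truncate_post_denaturation(avg)
        row = {
            "condition": cond,
            "n_replicates": len(reps),
            "fit_type": "none",
            "tm": np.nan,
            "tm_sd": np.nan,
            "tm2": np.nan,
            "tm2_sd": np.nan,
            "no_melt": False,
            "fallback_used": False,
        }
        n_infl = count_inflections(trunc, snr_min=snr_min) if len(trunc) >= 7 else (
            1 if len(trunc) >= 5 else 0
        )
        if n_infl == 0:
            row["no_melt"] = True
        elif n_infl == 2:
            fit = fit_double_boltzmann(trunc, snr_min=snr_min)
            if fit.ok:
                row.update(
                    fit_type="double_boltzmann",
                    tm=fit.tm1,
                    tm_sd=fit.tm1_sd,
                    tm2=fit.tm2,
                    tm2_sd=fit.tm2_sd,
                )
                rep_sd = _replicate_tm_sd(reps, 2) if len(reps) >= 3 else None
                if rep_sd is not None:
                    row["tm_sd"] = rep_sd
            elif fit.no_melt:
                row["no_melt"] = True
            else:
                tm = tm_by_second_derivative(trunc) if len(trunc) >= 7 else None
                if tm is None:
                    row["no_melt"] = True
                else:
                    row.update(fit_type="second_derivative", tm=tm, fallback_used=True)
        else:
            fit = fit_boltzmann(trunc, snr_min=snr_min)
            if fit.ok:
                row.update(fit_type="boltzmann", tm=fit.tm, tm_sd=fit.tm_sd)
                rep_sd = _replicate_tm_sd(reps, 1) if len(reps) >= 3 else None
                if rep_sd is not None:
                    row["tm_sd"] = rep_sd
            elif fit.no_melt:
                row["no_melt"] = True
            else:
                tm = tm_by_second_derivative(trunc) if len(trunc) >= 7 else None
                if tm is None:
                    row["no_melt"] = True
                else:
                    row.update(fit_type="second_derivative", tm=tm, fallback_used=True)
        rows.append(row)

    table = pd.DataFrame(rows)
    if len(table) == 0:
        table = pd.DataFrame(
            columns=[
                "condition", "n_replicates", "fit_type", "tm", "tm_sd",
                "tm2", "tm2_sd", "no_melt", "fallback_used",
            ]
        )
    if well_scale and len(table) > 0:
        for col in ("tm", "tm2"):
            table[col] = apply_well_calibration(table[col].to_numpy(), calibration)
        for col in ("tm_sd", "tm2_sd"):
            table[col] = calibration.slope * table[col]
    if len(table) > 0:
        table = table.sort_values("tm", ascending=False, na_position="last").reset_index(drop=True)
        table["rank"] = np.where(table["tm"].notna(), np.arange(1, len(table) + 1), np.nan)
    if reference is not None and len(table) > 0:
        ref_rows = table[table["condition"] == reference]
        if len(ref_rows) == 0:
            raise ValueError(f"reference condition {reference!r} not in the report")
        ref_tm = float(ref_rows["tm"].iloc[0])
        ref_sd = float(ref_rows["tm_sd"].iloc[0])
        table["delta_tm"] = table["tm"] - ref_tm
        sd = table["tm_sd"].to_numpy(dtype=float)
        sd = np.where(np.isfinite(sd), sd, 0.0)
        rsd = ref_sd if np.isfinite(ref_sd) else 0.0
        table["delta_tm_sd"] = np.hypot(sd, rsd)
    return ScreenReport(table=table, reference=reference)
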