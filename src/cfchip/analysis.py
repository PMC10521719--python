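"""Measurement operators for chemostat fluorescence time series.

Implements the quantities the device's experiments report: sliding-window
steady-state detection, fold repression (unrepressed over maximally
repressed signal), PWM linearity, response time to an inducer pulse, and
dose-response Kd recovery — plus a seeded generator of noisy synthetic
traces that emulates fluorescence measurement error.

All fluorescence values are in arbitrary units; every operator is
invariant to (or explicit about) uniform rescaling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TimeSeriesTable",
    "SteadyStateResult",
    "RepressionResult",
    "LinearityResult",
    "ResponseResult",
    "KdFit",
    "InsufficientDataError",
    "UndefinedRatioError",
    "UnidentifiableError",
    "detect_steady_state",
    "fold_repression",
    "pwm_linearity",
    "response_time",
    "fit_kd",
    "synthesize_noisy_traces",
]

TS_COLUMNS = ["cell_id", "row", "col", "length_um", "time_h", "species", "value"]


class InsufficientDataError(ValueError):
    """Trace too short for the requested analysis."""


class UndefinedRatioError(ValueError):
    """Fold repression undefined (zero or negative denominator)."""


class UnidentifiableError(ValueError):
    """Dose-response data carry no repression signal to fit."""


@dataclass
class TimeSeriesTable:
    """Long-format per-cell, per-species fluorescence trajectories.

    Columns: cell_id, row, col, length_um, time_h, species, value.
    One value per (cell, time, species); times non-decreasing per cell.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TS_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in TS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"time-series table missing columns {missing}")
        if len(self.frame):
            if (self.frame["time_h"] < 0).any():
                raise ValueError("times must be non-negative")
            dup = self.frame.duplicated(["cell_id", "time_h", "species"])
            if dup.any():
                raise ValueError("duplicate (cell, time, species) records")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cells(self) -> list[str]:
        return sorted(self.frame["cell_id"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.frame["species"].unique())

    def trace(self, cell_id: str, species: str) -> tuple[np.ndarray, np.ndarray]:
        """(times_h, values) for one cell and channel, time-sorted."""
        sub = self.frame[(self.frame["cell_id"] == cell_id)
                         & (self.frame["species"] == species)]
        sub = sub.sort_values("time_h")
        return sub["time_h"].to_numpy(float), sub["value"].to_numpy(float)

    def cell_meta(self, cell_id: str) -> dict:
        row = self.frame[self.frame["cell_id"] == cell_id].iloc[0]
        return {"row": int(row["row"]), "col": int(row["col"]),
                "length_um": float(row["length_um"])}

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "TimeSeriesTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: list[dict]) -> "TimeSeriesTable":
        return cls(pd.DataFrame.from_records(records, columns=TS_COLUMNS))


# -- steady-state detection ---------------------------------------------------


@dataclass(frozen=True)
class SteadyStateResult:
    level: float
    time_reached_h: float | None
    window_used_h: float
    reached: bool


def detect_steady_state(times_h: np.ndarray, values: np.ndarray,
                        slope_tol_per_h: float = 0.02,
                        window_h: float = 2.0) -> SteadyStateResult:
    """Earliest time after which the trace stays flat.

    A window of width ``window_h`` slides along the trace; within each
    window an ordinary least-squares line is fitted and the relative slope
    |dF/dt| / mean(F) compared against ``slope_tol_per_h``.  The steady
    state is reached at the start of the earliest window from which every
    later window also passes; the level is the mean over that first
    passing window.  Being a relative criterion, the detection is
    invariant to uniform rescaling of the trace.
    """
    times_h = np.asarray(times_h, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_h.ndim != 1 or times_h.shape != values.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    if len(times_h) < 2 or times_h[-1] - times_h[0] < window_h:
        raise InsufficientDataError(
            f"trace spans {times_h[-1] - times_h[0] if len(times_h) else 0:.2f} h, "
            f"shorter than the {window_h} h detection window")

    starts = [i for i in range(len(times_h))
              if times_h[i] + window_h <= times_h[-1] + 1e-12]
    passing = []
    for i in starts:
        mask = (times_h >= times_h[i] - 1e-12) & (times_h <= times_h[i] + window_h + 1e-12)
        t, v = times_h[mask], values[mask]
        if len(t) < 2:
            passing.append(False)
            continue
        slope = np.polyfit(t, v, 1)[0]
        mean = float(np.mean(v))
        rel = abs(slope) / abs(mean) if mean != 0 else (0.0 if slope == 0 else np.inf)
        passing.append(rel <= slope_tol_per_h)

    # earliest start index from which every later window passes
    idx = None
    for k in range(len(starts) - 1, -1, -1):
        if passing[k]:
            idx = k
        else:
            break
    if idx is None:
        return SteadyStateResult(level=float(values[-1]), time_reached_h=None,
                                 window_used_h=window_h, reached=False)
    i = starts[idx]
    mask = (times_h >= times_h[i] - 1e-12) & (times_h <= times_h[i] + window_h + 1e-12)
    return SteadyStateResult(level=float(np.mean(values[mask])),
                             time_reached_h=float(times_h[i]),
                             window_used_h=window_h, reached=True)


# -- fold repression ----------------------------------------------------------


@dataclass(frozen=True)
class RepressionResult:
    condition: tuple
    fold_repression: float | np.ndarray
    mode: str


def fold_repression(values_no_tf: np.ndarray, values_max_tf: np.ndarray,
                    mode: str = "endpoint"):
    """FR = signal without repressor / signal at the highest repressor dose.

    ``endpoint`` divides the last common samples; ``timecourse`` divides
    pointwise (the traces must share timestamps).
    """
    a = np.asarray(values_no_tf, dtype=float)
    b = np.asarray(values_max_tf, dtype=float)
    if mode == "endpoint":
        denom = b.ravel()[-1]
        if denom <= 0:
            raise UndefinedRatioError(
                f"repressed endpoint signal {denom:g} is not positive")
        return float(a.ravel()[-1] / denom)
    if mode == "timecourse":
        if a.shape != b.shape:
            raise ValueError("timecourse mode requires traces of equal length")
        if np.any(b <= 0):
            raise UndefinedRatioError("repressed trace touches zero")
        return a / b
    raise ValueError(f"unknown mode {mode!r}")


# -- PWM linearity ------------------------------------------------------------


@dataclass(frozen=True)
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float


def pwm_linearity(duty_levels: np.ndarray,
                  measured: np.ndarray) -> LinearityResult:
    """Ordinary least squares of measured signal against duty cycle."""
    x = np.asarray(duty_levels, dtype=float)
    y = np.asarray(measured, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("at least 3 duty levels are required")
    if x.shape != y.shape:
        raise ValueError("duty levels and measurements must match in length")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return LinearityResult(slope=float(slope), intercept=float(intercept),
                           r_squared=r2)


# -- response time ------------------------------------------------------------


@dataclass(frozen=True)
class ResponseResult:
    responsive: bool
    response_time_h: float | None
    pre_level: float
    extremum: float


def response_time(times_h: np.ndarray, values: np.ndarray,
                  event_time_h: float,
                  min_relative_change: float = 0.05) -> ResponseResult:
    """Time from a perturbation until the trace crosses the midpoint
    between its pre-event level and its post-event extremum.

    Traces whose post-event excursion is below ``min_relative_change`` of
    the pre-event level are flagged not-responsive instead of raising.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if t[0] > event_time_h or t[-1] < event_time_h:
        raise ValueError("trace does not span the event time")
    before = t < event_time_h - 1e-12
    # last sample strictly before the event; the event sample itself may
    # already carry the response
    pre = float(v[before][-1]) if before.any() else float(v[0])
    after = t >= event_time_h - 1e-12
    ta, va = t[after], v[after]
    if len(ta) < 2:
        raise InsufficientDataError("no samples after the event")
    iext = int(np.argmax(np.abs(va - pre)))
    extremum = float(va[iext])
    scale = max(abs(pre), abs(extremum), 1e-30)
    if abs(extremum - pre) <= min_relative_change * scale:
        return ResponseResult(False, None, pre, extremum)
    mid = 0.5 * (pre + extremum)
    sign = np.sign(extremum - pre)
    crossed = sign * (va - mid) >= 0
    idx = np.argmax(crossed)
    if not crossed[idx]:
        return ResponseResult(False, None, pre, extremum)
    if idx == 0:
        t_cross = ta[0]
    else:
        # linear interpolation between the bracketing samples
        t0, t1 = ta[idx - 1], ta[idx]
        v0, v1 = va[idx - 1], va[idx]
        t_cross = t0 + (mid - v0) / (v1 - v0) * (t1 - t0) if v1 != v0 else t1
    return ResponseResult(True, float(t_cross - event_time_h), pre, extremum)


# -- Kd recovery --------------------------------------------------------------


@dataclass(frozen=True)
class KdFit:
    kd_nm: float
    ci_low_nm: float
    ci_high_nm: float
    l0: float
    residual_norm: float


def _occupancy_model(tf, l0, kd, hill_n):
    return l0 / (1.0 + (tf / kd) ** hill_n)


def fit_kd(tf_levels_nm: np.ndarray, steady_levels: np.ndarray,
           hill_n: float = 1.0, n_boot: int = 200,
           seed: int = 0) -> KdFit:
    """Least-squares Kd from a steady-state dose-response curve.

    Fits the single-site occupancy model ``level = L0 / (1 + (TF/Kd)^n)``
    with fixed Hill coefficient; the confidence interval is a seeded
    residual bootstrap (2.5-97.5 percentiles).
    """
    tf = np.asarray(tf_levels_nm, dtype=float)
    y = np.asarray(steady_levels, dtype=float)
    if len(tf) < 4:
        raise InsufficientDataError("at least 4 TF levels are required")
    if not np.any(tf == 0):
        raise InsufficientDataError("the TF titration must include zero")
    if np.any(tf < 0):
        raise ValueError("TF levels must be >= 0")
    span = y.max() - y.min()
    if span <= 1e-9 * max(abs(y.max()), 1e-30):
        raise UnidentifiableError("dose-response levels carry no repression signal")

    l0_guess = float(y[tf == 0].mean())
    half = 0.5 * l0_guess
    below = tf[y <= half]
    kd_guess = float(below.min()) if len(below) and below.min() > 0 else \
        float(np.median(tf[tf > 0]))

    def model(x, l0, kd):
        return _occupancy_model(x, l0, kd, hill_n)

    popt, _ = curve_fit(model, tf, y, p0=[l0_guess, kd_guess],
                        bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10_000)
    l0_hat, kd_hat = popt
    resid = y - model(tf, *popt)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        y_b = model(tf, *popt) + rng.choice(resid, size=len(resid), replace=True)
        try:
            p_b, _ = curve_fit(model, tf, np.clip(y_b, 0, None),
                               p0=popt, bounds=([0, 1e-12], [np.inf, np.inf]),
                               maxfev=10_000)
            boots.append(p_b[1])
        except RuntimeError:  # pragma: no cover - rare non-convergence
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:  # pragma: no cover
        lo = hi = kd_hat
    return KdFit(kd_nm=float(kd_hat), ci_low_nm=float(lo), ci_high_nm=float(hi),
                 l0=float(l0_hat), residual_norm=float(np.linalg.norm(resid)))


# -- synthetic noisy traces ---------------------------------------------------


def synthesize_noisy_traces(clean: TimeSeriesTable, noise_cv: float,
                            background: float, seed: int) -> TimeSeriesTable:
    """Fluorescence-measurement emulation on a clean simulated table.

    value' = value * LogNormal(0, noise_cv) + Normal(background,
    background/10), floored at zero; fully reproducible from the seed.
    """
    if noise_cv < 0:
        raise ValueError("noise CV must be >= 0")
    rng = np.random.default_rng(seed)
    df = clean.frame.copy()
    n = len(df)
    mult = rng.lognormal(mean=0.0, sigma=noise_cv, size=n) if noise_cv > 0 else 1.0
    add = rng.normal(loc=background, scale=background / 10.0, size=n) \
        if background > 0 else 0.0
    df["value"] = np.clip(df["value"].to_numpy(float) * mult + add, 0.0, None)
    return TimeSeriesTable(df)
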