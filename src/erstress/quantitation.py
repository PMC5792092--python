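"""Absolute quantitation of ER chaperone and client levels from densitometry.

Standard-curve densitometry against known quantities of purified protein is
the route by which copies-per-cell of the chaperone BiP and its client, the
IgM secretory heavy chain (µs), are estimated.  This module converts raw
band signals into absolute abundances, fits logistic (sigmoidal) kinetics on
a log-time axis, and derives the three UPR-branch activity readouts:

* IRE1α  — percent XBP1 mRNA splicing,
* PERK   — CHOP level relative to a loading control,
* ATF6α  — released p50 level relative to a loading control,

each expressed as percent of its maximum over the time course, plus the
Welch-t classification of whether BiP or µs is in excess at each time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

AVOGADRO = 6.02214076e23  # molecules per mole

__all__ = [
    "AVOGADRO",
    "CalibrationError",
    "FitError",
    "StandardSeries",
    "Calibration",
    "AbundanceTimeCourse",
    "SigmoidFit",
    "SplicingMeasurement",
    "BranchOutput",
    "RatioClass",
    "fit_standard_curve",
    "absolute_copies",
    "lanes_to_copies",
    "timecourse_from_lanes",
    "normalize_to_reference",
    "fit_sigmoid",
    "splicing_fraction",
    "percent_of_max",
    "classify_ratio",
]


class CalibrationError(ValueError):
    """Standard curve is unidentifiable or fit to a non-positive slope."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the data are degenerate."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardSeries:
    """Dilution series of a purified standard on one blot.

    ``purity`` is the fraction of the standard's protein mass attributable
    to the analyte (0.7 for µs within whole purified IgM; 1.0 for
    recombinant BiP).
    """

    analyte: str
    masses_ng: tuple[float, ...]
    signals: tuple[float, ...]
    purity: float = 1.0

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses_ng, float)
        signals = np.asarray(self.signals, float)
        if masses.size < 3 or signals.size != masses.size:
            raise CalibrationError(
                "a standard curve needs >=3 (mass, signal) points"
            )
        if np.any(masses <= 0):
            raise CalibrationError("standard masses must be strictly positive")
        if np.ptp(masses) == 0:
            raise CalibrationError("standard masses are all equal; curve unidentifiable")
        if not (0.0 < self.purity <= 1.0):
            raise CalibrationError("purity must lie in (0, 1]")
        object.__setattr__(self, "masses_ng", tuple(masses))
        object.__setattr__(self, "signals", tuple(signals))


@dataclass(frozen=True)
class Calibration:
    """Linear signal-vs-mass calibration: signal = slope*mass_ng + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError("R^2 outside [0, 1]")


@dataclass(frozen=True)
class AbundanceTimeCourse:
    """Copies-per-cell of one analyte over time with replicate spread."""

    analyte: str
    times_hr: tuple[float, ...]
    copies: tuple[float, ...]
    sem: tuple[float, ...] | None = None
    reference: tuple[str, float] | None = None  # (analyte, time) if normalized

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hr, float)
        c = np.asarray(self.copies, float)
        if t.size != c.size or t.size == 0:
            raise ValueError("times and copies must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("copies must be non-negative")
        object.__setattr__(self, "times_hr", tuple(t))
        object.__setattr__(self, "copies", tuple(c))
        if self.sem is not None:
            object.__setattr__(self, "sem", tuple(np.asarray(self.sem, float)))

    def value_at(self, time_hr: float) -> float:
        t = np.asarray(self.times_hr)
        idx = np.flatnonzero(np.isclose(t, time_hr))
        if idx.size == 0:
            raise KeyError(f"time {time_hr} hr not in course for {self.analyte}")
        return self.copies[int(idx[0])]


@dataclass(frozen=True)
class SigmoidFit:
    """Four-parameter logistic on a log-time axis.

    y(t) = bottom + (top - bottom) * t^h / (t^h + t50^h), with t50 the
    half-time in hours and h the Hill slope.
    """

    bottom: float
    top: float
    half_time_hr: float
    hill: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.top < self.bottom:
            raise ValueError("top must be >= bottom")
        if self.half_time_hr <= 0:
            raise ValueError("half_time must be positive")

    def predict(self, times_hr) -> np.ndarray:
        return _logistic_logtime(
            np.asarray(times_hr, float),
            self.bottom, self.top, self.half_time_hr, self.hill,
        )


@dataclass(frozen=True)
class SplicingMeasurement:
    """XBP1 RT-PCR band intensities: spliced, unspliced, and the hybrid band.

    The hybrid is a PCR-formed heteroduplex of one spliced and one unspliced
    strand, so its intensity is split equally between the two.
    """

    spliced: float
    unspliced: float
    hybrid: float = 0.0

    def __post_init__(self) -> None:
        if min(self.spliced, self.unspliced, self.hybrid) < 0:
            raise ValueError("band signals must be non-negative")


@dataclass(frozen=True)
class BranchOutput:
    """Raw or percent-of-max output of one UPR branch over time."""

    branch: str
    times_hr: tuple[float, ...]
    values: tuple[float, ...]
    is_percent: bool = False

    def __post_init__(self) -> None:
        if len(self.times_hr) != len(self.values) or not self.values:
            raise ValueError("times and values must be equal-length, non-empty")


@dataclass(frozen=True)
class RatioClass:
    """Classification of [BiP] vs [µs] at one time point.

    ``label`` is 'BiP_excess' (p<=0.001 with BiP higher), 'client_excess'
    (p<=0.05 with µs higher) or 'comparable'; thresholds are deliberately
    asymmetric, as printed on the heat-map scale they implement.
    """

    time_hr: float
    label: str
    p_value: float
    mean_bip: float
    mean_client: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_standard_curve(series: StandardSeries) -> Calibration:
    """Ordinary least squares of signal on known mass, with free intercept."""
    masses = np.asarray(series.masses_ng, float)
    signals = np.asarray(series.signals, float)
    res = stats.linregress(masses, signals)
    if not np.isfinite(res.slope) or res.slope <= 0:
        raise CalibrationError(
            f"calibration failure for {series.analyte}: slope {res.slope!r} <= 0"
        )
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return Calibration(float(res.slope), float(res.intercept), min(r2, 1.0))


def absolute_copies(
    signal,
    cal: Calibration,
    *,
    purity: float = 1.0,
    cells_per_lane: float,
    molecular_weight_kda: float,
):
    """Convert a densitometry signal into copies per cell.

    mass_ng = (signal - intercept)/slope * purity; copies follow from the
    molecular weight and Avogadro's number divided by cells loaded per lane.
    Back-computed masses below zero (faint lanes under the fitted
    background) clamp to zero with a warning.
    """
    if cells_per_lane <= 0:
        raise ValueError("cells_per_lane must be positive")
    if molecular_weight_kda <= 0:
        raise ValueError("molecular weight must be positive")
    signal = np.asarray(signal, float)
    mass_ng = (signal - cal.intercept) / cal.slope * purity
    if np.any(mass_ng < 0):
        warnings.warn(
            "signal below calibration intercept; clamping mass to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        mass_ng = np.maximum(mass_ng, 0.0)
    copies = mass_ng * 1e-9 / (molecular_weight_kda * 1e3) * AVOGADRO / cells_per_lane
    return copies if copies.ndim else float(copies)


def lanes_to_copies(
    lanes: pd.DataFrame,
    cal: Calibration,
    *,
    purity: float = 1.0,
    molecular_weight_kda: float,
    signal_col: str = "signal",
    cells_col: str = "cells_per_lane",
) -> pd.DataFrame:
    """Return a copy of ``lanes`` with a ``copies_per_cell`` column added."""
    out = lanes.copy()
    copies = [
        absolute_copies(
            row[signal_col], cal,
            purity=purity,
            cells_per_lane=row[cells_col],
            molecular_weight_kda=molecular_weight_kda,
        )
        for _, row in lanes.iterrows()
    ]
    out["copies_per_cell"] = copies
    return out


def timecourse_from_lanes(
    lanes_with_copies: pd.DataFrame,
    analyte: str,
    *,
    time_col: str = "time_hr",
) -> AbundanceTimeCourse:
    """Aggregate replicate lanes into a mean +/- s.e.m. time course."""
    sub = lanes_with_copies[lanes_with_copies["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"no lanes for analyte {analyte!r}")
    g = sub.groupby(time_col)["copies_per_cell"]
    mean = g.mean()
    sem = g.sem().fillna(0.0)
    return AbundanceTimeCourse(
        analyte=analyte,
        times_hr=tuple(mean.index.to_numpy(float)),
        copies=tuple(mean.to_numpy(float)),
        sem=tuple(sem.to_numpy(float)),
    )


def normalize_to_reference(
    tc: AbundanceTimeCourse,
    reference: AbundanceTimeCourse,
    ref_time_hr: float,
) -> AbundanceTimeCourse:
    """Express a time course in equivalents of ``reference`` at one time."""
    ref_value = reference.value_at(ref_time_hr)
    if ref_value == 0:
        raise ZeroDivisionError("reference value is zero; cannot normalize")
    scale = 1.0 / ref_value
    sem = None if tc.sem is None else tuple(s * scale for s in tc.sem)
    return replace(
        tc,
        copies=tuple(c * scale for c in tc.copies),
        sem=sem,
        reference=(reference.analyte, float(ref_time_hr)),
    )


def _logistic_logtime(t, bottom, top, half_time, hill):
    t = np.asarray(t, float)
    th = np.power(np.maximum(t, 0.0), hill)
    hh = half_time**hill
    return bottom + (top - bottom) * th / (th + hh)


def fit_sigmoid(tc: AbundanceTimeCourse, *, maxfev: int = 20000) -> SigmoidFit:
    """Least-squares four-parameter logistic on a log-time axis.

    Requires >=5 time points; constant data raise :class:`FitError` as
    degenerate.  The fitted object interpolates unobserved times via
    :meth:`SigmoidFit.predict`.
    """
    t = np.asarray(tc.times_hr, float)
    y = np.asarray(tc.copies, float)
    if t.size < 5:
        raise ValueError("sigmoid fit needs >=5 time points")
    span = float(np.ptp(y))
    scale = max(abs(y).max(), 1.0)
    if span <= 1e-12 * scale:
        raise FitError("constant data: logistic parameters are degenerate")

    mid = y.min() + span / 2.0
    above = np.flatnonzero(y >= mid)
    t50_guess = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(
        float(np.median(t[t > 0])) if np.any(t > 0) else 1.0, 1e-6
    )
    p0 = [float(y.min()), float(y.max()), t50_guess, 2.0]
    bounds = ([0.0, 0.0, 1e-6, 0.05], [np.inf, np.inf, 1e6, 50.0])
    try:
        popt, _ = optimize.curve_fit(
            _logistic_logtime, t, y, p0=p0, bounds=bounds, maxfev=maxfev
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    bottom, top, t50, hill = (float(v) for v in popt)
    if top < bottom:
        bottom, top = top, bottom
    resid = y - _logistic_logtime(t, bottom, top, t50, hill)
    return SigmoidFit(bottom, top, t50, hill, float(np.std(resid)))


def splicing_fraction(m: SplicingMeasurement) -> float:
    """Percent spliced XBP1: 100 * S / (S + U) after the hybrid band is
    split equally between the spliced and unspliced species."""
    total = m.spliced + m.unspliced + m.hybrid
    if total <= 0:
        raise ValueError("all-zero band signals: splicing ratio undefined")
    s_eff = m.spliced + m.hybrid / 2.0
    return 100.0 * s_eff / total


def percent_of_max(branch: BranchOutput) -> BranchOutput:
    """Express branch output as percent of its own maximum (idempotent)."""
    values = np.asarray(branch.values, float)
    peak = values.max()
    if peak <= 0:
        raise ValueError(f"branch {branch.branch!r} has no positive output")
    return replace(
        branch, values=tuple(100.0 * values / peak), is_percent=True
    )


def classify_ratio(
    bip_reps: Sequence[float],
    client_reps: Sequence[float],
    time_hr: float = float("nan"),
) -> RatioClass:
    """Welch two-tailed t-test of BiP vs client replicate levels.

    'BiP_excess' requires p<=0.001 with the BiP mean higher; 'client_excess'
    requires p<=0.05 with the client mean higher; anything else is
    'comparable'.
    """
    bip = np.asarray(bip_reps, float)
    client = np.asarray(client_reps, float)
    if bip.size < 2 or client.size < 2:
        raise ValueError("need >=2 replicates per analyte")
    _, p = stats.ttest_ind(bip, client, equal_var=False)
    p = float(p)
    if not np.isfinite(p):  # zero variance in both groups
        p = 1.0 if np.isclose(bip.mean(), client.mean()) else 0.0
    mb, mc = float(bip.mean()), float(client.mean())
    if mb > mc and p <= 0.001:
        label = "BiP_excess"
    elif mc > mb and p <= 0.05:
        label = "client_excess"
    else:
        label = "comparable"
    return RatioClass(float(time_hr), label, p, mb, mc)
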