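"""Proton-pumping kinetics from ACMA fluorescence traces and detergent titrations.

The experimental readout behind this module is the quenching of the pH probe
ACMA inside proteoliposomes: pumping is started by adding Mg2+ (which forms the
Mg-ATP substrate), the fluorescence decays as the vesicle lumen acidifies, and
adding the protonophore CCCP collapses the gradient and restores the signal.
The initial slope of the normalized trace right after Mg2+ addition is the
proton-pumping rate estimate; traces that never quench are flagged inactive.

Detergent solubilization of liposomes is monitored by light scattering and
follows a sigmoid in detergent concentration, fitted here with the Boltzmann
form

    y(x) = Bottom + (Top - Bottom) / (1 + exp((x - V50) / slope))

whose inflection V50 is the concentration at half solubilization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    DegenerateTraceError,
    FitFailureError,
    InsufficientDataError,
)

__all__ = [
    "Trace",
    "NormalizedTrace",
    "PumpRate",
    "SolubilizationSeries",
    "BoltzmannFit",
    "boltzmann",
    "normalize_trace",
    "initial_rate",
    "classify_active",
    "analyze_trace",
    "fit_boltzmann",
    "fold_changes",
]


@dataclass(frozen=True)
class Trace:
    """A raw fluorescence time series with the two reagent-addition events.

    ``t_mg`` marks Mg2+ (pumping start), ``t_cccp`` the protonophore addition.
    Time in seconds, fluorescence in arbitrary units.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    t_mg: float
    t_cccp: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ConfigurationError("time and fluorescence must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("time must be strictly increasing")
        if not (t[0] <= self.t_mg < self.t_cccp <= t[-1]):
            raise ConfigurationError(
                f"event times must satisfy t0 <= t_mg < t_cccp <= t_end "
                f"(got t_mg={self.t_mg}, t_cccp={self.t_cccp})"
            )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)


@dataclass(frozen=True)
class NormalizedTrace(Trace):
    """A trace divided by the intensity directly after Mg2+ addition.

    ``reference`` stores the raw value used for the division; the first sample
    at or after ``t_mg`` equals 1.0 by construction.
    """

    reference: float = 1.0


@dataclass(frozen=True)
class PumpRate:
    """Initial-slope estimate of the proton-pumping rate for one trace.

    ``slope`` is the signed ordinary-least-squares slope of normalized
    fluorescence over the fit window; ``rate`` = -slope so that pumping
    (quenching) gives a positive rate.
    """

    slope: float
    window: tuple[float, float]
    n_points: int
    active: bool = True
    r_squared: float = float("nan")

    @property
    def rate(self) -> float:
        return -self.slope


@dataclass(frozen=True)
class SolubilizationSeries:
    """Light-scattering signal versus detergent concentration (mM)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ConfigurationError("x and y must be equal-length 1-D arrays")
        if len(x) < 5:
            raise ConfigurationError("a solubilization series needs >= 5 points")
        if np.any(np.diff(x) <= 0):
            raise ConfigurationError("detergent concentrations must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted sigmoid parameters; Top > Bottom for a solubilization curve."""

    top: float
    bottom: float
    v50: float
    slope: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        return boltzmann(np.asarray(x, dtype=float), self.top, self.bottom, self.v50, self.slope)


def boltzmann(x, top, bottom, v50, slope):
    """Sigmoid y = Bottom + (Top - Bottom)/(1 + exp((x - V50)/slope))."""
    return bottom + (top - bottom) / (1.0 + np.exp((np.asarray(x, float) - v50) / slope))


def normalize_trace(trace: Trace) -> NormalizedTrace:
    """Divide a trace by the intensity measured directly after Mg2+ addition.

    The reference is the first sample with time >= t_mg (discrete acquisition;
    no interpolation). Idempotent on already-normalized traces.
    """
    idx = np.searchsorted(trace.time, trace.t_mg, side="left")
    if idx >= len(trace.time):
        raise InsufficientDataError("no sample at or after t_mg")
    ref = float(trace.fluorescence[idx])
    if ref <= 0:
        raise DegenerateTraceError(f"reference intensity at t_mg is {ref} (must be > 0)")
    return NormalizedTrace(
        time=trace.time,
        fluorescence=trace.fluorescence / ref,
        t_mg=trace.t_mg,
        t_cccp=trace.t_cccp,
        reference=ref,
    )


def initial_rate(nt: NormalizedTrace, window_s: float = 30.0) -> PumpRate:
    """OLS slope of normalized fluorescence over the first ``window_s`` seconds
    after Mg2+ addition; ``rate`` = -slope is the pumping-rate estimate."""
    t, f = nt.time, nt.fluorescence
    sel = (t >= nt.t_mg) & (t <= nt.t_mg + window_s)
    n = int(sel.sum())
    if n < 2:
        raise InsufficientDataError(
            f"only {n} samples in [{nt.t_mg}, {nt.t_mg + window_s}] s; need >= 2"
        )
    tw, fw = t[sel], f[sel]
    slope, intercept = np.polyfit(tw, fw, 1)
    resid = fw - (slope * tw + intercept)
    ss_tot = float(np.sum((fw - fw.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PumpRate(
        slope=float(slope),
        window=(float(nt.t_mg), float(nt.t_mg + window_s)),
        n_points=n,
        r_squared=r2,
    )


def classify_active(
    nt: NormalizedTrace,
    pre_window_s: float = 5.0,
    post_window_s: float = 5.0,
    reequilibration_s: float = 10.0,
) -> bool:
    """Flag traces that actually pumped.

    A trace is inactive when the signal just before CCCP addition is less than
    10% below the post-CCCP plateau; exactly 10% below counts as active. The
    plateau is measured over the last ``post_window_s`` seconds of the trace,
    which are required to start at least ``reequilibration_s`` after CCCP.
    """
    t, f = nt.time, nt.fluorescence
    pre = (t >= nt.t_cccp - pre_window_s) & (t < nt.t_cccp)
    post_start = max(nt.t_cccp + reequilibration_s, t[-1] - post_window_s)
    post = t >= post_start
    if not pre.any() or not post.any():
        raise InsufficientDataError("missing samples in the pre- or post-CCCP window")
    return bool(f[pre].mean() <= 0.90 * f[post].mean())


def analyze_trace(trace: Trace, window_s: float = 30.0) -> PumpRate:
    """Normalize, estimate the initial rate and attach the activity flag."""
    nt = trace if isinstance(trace, NormalizedTrace) else normalize_trace(trace)
    pr = initial_rate(nt, window_s=window_s)
    return replace(pr, active=classify_active(nt))


def fit_boltzmann(series: SolubilizationSeries, max_restarts: int = 5) -> BoltzmannFit:
    """Nonlinear least-squares fit of the Boltzmann sigmoid.

    Initialization: Top = max(y), Bottom = min(y), V50 = x at the point closest
    to midrange, slope = (max(x) - min(x))/10. On solver failure the start is
    perturbed a bounded number of times before a FitFailureError is raised.
    """
    x, y = series.x, series.y
    top0, bot0 = float(y.max()), float(y.min())
    mid = 0.5 * (top0 + bot0)
    v50_0 = float(x[np.argmin(np.abs(y - mid))])
    slope0 = float((x.max() - x.min()) / 10.0)
    if slope0 == 0:
        raise ConfigurationError("degenerate x range")

    diagnostics: dict = {"attempts": []}
    rng = np.random.default_rng(0)
    p0 = np.array([top0, bot0, v50_0, slope0])
    for attempt in range(max_restarts + 1):
        try:
            popt, _ = curve_fit(boltzmann, x, y, p0=p0, maxfev=20000)
            top, bottom, v50, slope = (float(v) for v in popt)
            if top < bottom:  # model is symmetric under (Top<->Bottom, slope->-slope)
                top, bottom, slope = bottom, top, -slope
            resid = y - boltzmann(x, top, bottom, v50, slope)
            return BoltzmannFit(top, bottom, v50, slope, float(np.sum(resid**2)), True)
        except RuntimeError as exc:
            diagnostics["attempts"].append({"p0": p0.tolist(), "error": str(exc)})
            p0 = np.array([top0, bot0, v50_0, slope0]) * (1 + 0.2 * rng.standard_normal(4))
    raise FitFailureError("Boltzmann fit did not converge", diagnostics)


def fold_changes(
    rates: Mapping[str, Sequence[PumpRate]], reference: str
) -> dict[str, float]:
    """Mean active rate of each condition divided by the reference's mean.

    Inactive traces are excluded from the means (they are flagged upstream,
    never silently dropped from the per-trace tables).
    """
    if reference not in rates:
        raise ConfigurationError(f"reference condition {reference!r} missing")

    def active_mean(prs: Sequence[PumpRate]) -> float:
        vals = [p.rate for p in prs if p.active]
        if not vals:
            raise InsufficientDataError("no active traces in a condition")
        return float(np.mean(vals))

    ref_mean = active_mean(rates[reference])
    if ref_mean == 0:
        raise DegenerateDataError("reference condition has zero mean rate")
    return {cond: active_mean(prs) / ref_mean for cond, prs in rates.items()}
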