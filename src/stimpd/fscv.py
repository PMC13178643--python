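"""Kinetic analysis of evoked dopamine transients.

Fits the pulsed-release / saturable-clearance model to calibrated
voltammetry traces, derives the apparent Michaelis constant at each
inhibitor concentration and estimates drug potency (Ki) from the slope
of apparent Km against concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from . import stats
from ._integrate import integrate_transient

__all__ = [
    "StimulusProtocol",
    "VoltammetryTrace",
    "Calibration",
    "KineticFit",
    "ApparentKmPoint",
    "PotencyResult",
    "UnfittableTraceError",
    "PotencyUndefinedError",
    "CalibrationError",
    "DEFAULT_BASELINE_KM",
    "apply_calibration",
    "check_stability",
    "fit_transient",
    "peak_height",
    "percent_of_baseline",
    "apparent_km_series",
    "estimate_ki",
    "release_by_protocol",
    "assemble_modulation_curve",
]

#: Literature fallback for the baseline Michaelis constant of dopamine
#: clearance (μM), used by the Ki formula when no baseline fit exists.
DEFAULT_BASELINE_KM = 0.16


class UnfittableTraceError(ValueError):
    """Trace carries no usable evoked signal."""


class PotencyUndefinedError(ValueError):
    """Apparent-Km slope is not positive; the drug shows no inhibition."""


class CalibrationError(ValueError):
    """Unit mismatch when converting current to concentration."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical stimulation descriptor; amplitude/pulse width are metadata."""

    n_pulses: int = 1
    frequency: float = 0.0  # Hz, ignored for single pulses
    amplitude_ua: float = 350.0
    pulse_width_ms: float = 4.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.n_pulses > 1 and self.frequency <= 0:
            raise ValueError("frequency must be > 0 for multi-pulse protocols")

    def pulse_times(self, onset: float) -> np.ndarray:
        if self.n_pulses == 1:
            return np.array([onset])
        return onset + np.arange(self.n_pulses) / self.frequency


@dataclass(frozen=True)
class VoltammetryTrace:
    """Uniformly sampled evoked-dopamine recording plus condition metadata."""

    time: np.ndarray
    signal: np.ndarray
    unit: str  # "nA" | "uM"
    protocol: StimulusProtocol
    stim_onset: float
    condition: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.size != s.size or t.size < 2:
            raise ValueError("time and signal must be equal-length with >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
            raise ValueError("time must be strictly increasing and uniform")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal contains non-finite values")
        if self.unit not in ("nA", "uM"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def scan_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class Calibration:
    known_conc: float = 3.0  # μM dopamine standard
    measured_current: float = 15.0  # nA

    def __post_init__(self) -> None:
        if self.known_conc <= 0 or self.measured_current <= 0:
            raise ValueError("calibration inputs must be positive")

    @property
    def factor(self) -> float:
        """Electrode sensitivity, nA per μM."""
        return self.measured_current / self.known_conc


@dataclass(frozen=True)
class KineticFit:
    da_per_pulse: float
    vmax: float
    km: float
    fixed_flags: tuple[str, ...]
    sse: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class ApparentKmPoint:
    concentration: float  # μM drug
    apparent_km: float  # μM dopamine


@dataclass(frozen=True)
class PotencyResult:
    ki: float
    slope: float
    intercept: float
    r_squared: float
    baseline_km: float
    n_points: int


def apply_calibration(trace: VoltammetryTrace, cal: Calibration) -> VoltammetryTrace:
    """Convert a current trace (nA) to concentration (μM)."""
    if trace.unit == "uM":
        raise CalibrationError("trace is already calibrated to uM")
    return replace(trace, signal=trace.signal / cal.factor, unit="uM")


def check_stability(peaks: Sequence[float], tolerance: float = 0.10) -> bool:
    """Stability gate on the last three evoked peaks.

    True iff every peak lies within ``tolerance`` (fractional) of the
    three-peak mean.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size != 3:
        raise ValueError("stability check requires exactly 3 peak heights")
    if np.any(peaks <= 0):
        raise ValueError("peak heights must be positive")
    mean = peaks.mean()
    return bool(np.max(np.abs(peaks - mean)) / mean <= tolerance)


_PARAMS = ("da_per_pulse", "vmax", "km")
_DEFAULT_INIT = {"da_per_pulse": None, "vmax": 2.0, "km": DEFAULT_BASELINE_KM}


def _model_curve(
    trace: VoltammetryTrace, protocol: StimulusProtocol, dap: float, vmax: float, km: float
) -> np.ndarray:
    duration = float(trace.time[-1] - trace.time[0]) + 1.0 / trace.scan_rate
    _, conc = integrate_transient(
        duration,
        trace.scan_rate,
        vmax,
        km,
        protocol.pulse_times(trace.stim_onset - float(trace.time[0])),
        dap,
    )
    return conc


def fit_transient(
    trace: VoltammetryTrace,
    protocol: StimulusProtocol | None = None,
    floating: Sequence[str] = _PARAMS,
    init: Mapping[str, float] | None = None,
    fixed_values: Mapping[str, float] | None = None,
    max_iter: int = 500,
) -> KineticFit:
    """Nonlinear least squares of the forward kinetic model against a trace.

    ``floating`` selects which of (da_per_pulse, vmax, km) are free; the
    rest are pinned to ``fixed_values``.  All parameters are bounded
    below by zero (km by a small positive floor).  Optimizer stalls are
    reported as ``converged=False`` rather than raised.
    """
    if trace.unit != "uM":
        raise ValueError("fit requires a calibrated (uM) trace")
    protocol = protocol or trace.protocol
    floating = tuple(floating)
    for name in floating:
        if name not in _PARAMS:
            raise ValueError(f"unknown parameter {name!r}")
    if not floating:
        raise ValueError("at least one parameter must float")

    onset = trace.stim_onset
    if not (trace.time[0] <= onset <= trace.time[-1]):
        raise UnfittableTraceError("stimulation onset lies outside the trace")
    post = trace.time >= onset - 1e-9
    if post.sum() < 5:
        raise UnfittableTraceError("fewer than 5 samples after stimulation onset")

    pre = (trace.time < onset) & (trace.time >= onset - 1.0)
    baseline = float(trace.signal[pre].mean()) if pre.any() else 0.0
    noise = float(trace.signal[pre].std()) if pre.sum() > 1 else 0.0
    observed = trace.signal - baseline
    peak = float(observed[post].max())
    if peak <= 0 or peak <= 3.0 * noise:
        raise UnfittableTraceError("trace is flat (peak below 3x noise estimate)")

    fixed = dict(fixed_values or {})
    values = {"da_per_pulse": peak / max(protocol.n_pulses, 1), "vmax": _DEFAULT_INIT["vmax"],
              "km": _DEFAULT_INIT["km"]}
    values.update(fixed)
    if init:
        values.update({k: v for k, v in init.items() if k in floating})

    lower = {"da_per_pulse": 0.0, "vmax": 0.0, "km": 1e-6}
    x0 = np.array([values[name] for name in floating])
    lb = np.array([lower[name] for name in floating])

    target = observed[post]

    def residuals(x: np.ndarray) -> np.ndarray:
        p = dict(values)
        p.update(dict(zip(floating, x)))
        model = _model_curve(trace, protocol, p["da_per_pulse"], p["vmax"], p["km"])
        return model[post] - target

    result = least_squares(
        residuals,
        np.maximum(x0, lb),
        bounds=(lb, np.full(len(floating), np.inf)),
        ftol=1e-8,
        xtol=1e-10,
        gtol=1e-10,
        max_nfev=max_iter,
    )
    est = dict(values)
    est.update(dict(zip(floating, result.x)))
    fixed_flags = tuple(name for name in _PARAMS if name not in floating)
    return KineticFit(
        da_per_pulse=float(est["da_per_pulse"]),
        vmax=float(est["vmax"]),
        km=float(est["km"]),
        fixed_flags=fixed_flags,
        sse=float(2.0 * result.cost),
        converged=bool(result.success),
        n_iter=int(result.nfev),
    )


def peak_height(trace: VoltammetryTrace, window: float = 5.0) -> float:
    """Baseline-subtracted maximum within ``window`` s of stimulation onset.

    Baseline is the mean over the 1 s preceding the stimulus.
    """
    if trace.unit != "uM":
        raise ValueError("peak_height requires a calibrated (uM) trace")
    onset = trace.stim_onset
    if not (trace.time[0] <= onset <= trace.time[-1]):
        raise ValueError("stimulation onset lies outside the trace")
    pre = (trace.time < onset) & (trace.time >= onset - 1.0)
    baseline = float(trace.signal[pre].mean()) if pre.any() else 0.0
    sel = (trace.time >= onset - 1e-9) & (trace.time <= onset + window)
    return float(trace.signal[sel].max() - baseline)


def percent_of_baseline(values: Sequence[float], baseline: float) -> np.ndarray:
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * np.asarray(values, dtype=float) / baseline


def apparent_km_series(
    traces: Sequence[VoltammetryTrace],
    baseline_fit: KineticFit,
    fix_vmax: bool = True,
) -> list[ApparentKmPoint]:
    """Apparent Km at each drug concentration.

    Each drug trace is fitted with vmax pinned to the slice's baseline
    estimate (competitive inhibitors leave transporter number unchanged);
    pass ``fix_vmax=False`` for the fully-floating mode.  The
    zero-concentration entry reuses the baseline fit.  Non-converged
    fits are excluded with a warning.
    """
    if not baseline_fit.converged:
        raise ValueError("baseline fit did not converge")
    points: list[ApparentKmPoint] = []
    for trace in traces:
        conc = float(trace.condition.get("concentration", 0.0))
        if conc == 0.0:
            points.append(ApparentKmPoint(0.0, baseline_fit.km))
            continue
        if fix_vmax:
            fit = fit_transient(
                trace,
                floating=("da_per_pulse", "km"),
                fixed_values={"vmax": baseline_fit.vmax},
                init={"km": baseline_fit.km},
            )
        else:
            fit = fit_transient(trace, init={"km": baseline_fit.km})
        if not fit.converged:
            warnings.warn(
                f"drug fit at {conc} uM did not converge; point excluded", RuntimeWarning
            )
            continue
        points.append(ApparentKmPoint(conc, fit.km))
    points.sort(key=lambda p: p.concentration)
    return points


def estimate_ki(
    points: Sequence[ApparentKmPoint],
    baseline_km: float | None = None,
) -> PotencyResult:
    """Potency from the linear concentration-effect profile.

    OLS of apparent Km on drug concentration; Ki = baseline Km / slope.
    Points at zero concentration are excluded from the regression unless
    they are the caller's explicit origin anchor (they still inform
    ``baseline_km`` when it is not given).
    """
    nonzero = [p for p in points if p.concentration > 0]
    if baseline_km is None:
        zero = [p for p in points if p.concentration == 0]
        baseline_km = zero[0].apparent_km if zero else DEFAULT_BASELINE_KM
    if baseline_km <= 0:
        raise ValueError("baseline_km must be positive")
    if len(nonzero) < 3 or len({p.concentration for p in nonzero}) < 2:
        raise ValueError("need >= 3 points spanning >= 2 distinct concentrations")
    x = [p.concentration for p in nonzero]
    y = [p.apparent_km for p in nonzero]
    fit = stats.linear_fit(x, y)
    if fit.slope <= 0:
        raise PotencyUndefinedError(
            f"apparent-Km slope {fit.slope:.4g} is not positive; no uptake inhibition"
        )
    return PotencyResult(
        ki=baseline_km / fit.slope,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        baseline_km=float(baseline_km),
        n_points=len(nonzero),
    )


def release_by_protocol(
    traces: Mapping[str, VoltammetryTrace],
    reference: Mapping[str, VoltammetryTrace],
) -> dict[str, float]:
    """Percent-of-baseline peak height per stimulation protocol."""
    if not traces:
        raise ValueError("no drug traces supplied")
    out: dict[str, float] = {}
    for key, trace in traces.items():
        if key not in reference:
            raise KeyError(f"missing reference trace for protocol {key!r}")
        ref_peak = peak_height(reference[key])
        out[key] = float(percent_of_baseline([peak_height(trace)], ref_peak)[0])
    return out


def assemble_modulation_curve(
    levels: Sequence[object],
    per_slice: Mapping[object, Mapping[object, float]],
    baselines: Mapping[object, float],
) -> list[dict[str, float]]:
    """Across-slice mean ± SEM of percent-of-baseline peaks per level.

    ``per_slice`` maps slice id -> {level: peak μM}; ``baselines`` maps
    slice id -> baseline peak μM.  Levels are kept in input order.
    """
    curve = []
    for level in levels:
        pct = [
            float(percent_of_baseline([vals[level]], baselines[sid])[0])
            for sid, vals in per_slice.items()
            if level in vals
        ]
        if not pct:
            raise ValueError(f"no slices recorded at level {level!r}")
        arr = np.asarray(pct)
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
        curve.append(
            {"level": level, "mean_pct": float(arr.mean()), "sem": sem, "n": int(arr.size)}
        )
    return curve
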