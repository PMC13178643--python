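"""Fixed-step RK4 integrator for the pulsed-release / saturable-clearance ODE.

State: extracellular dopamine concentration C (μM), obeying

    dC/dt = -Vmax * C / (Km + C)

between stimulus pulses, with an instantaneous increment at each pulse
time.  The integrator marches on an internal 1 kHz grid (configurable)
and is down-sampled to the recording rate; this is the single forward
model shared by the simulator and the kinetic fitter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["IntegrationError", "integrate_transient", "INTERNAL_HZ"]

INTERNAL_HZ = 1000


class IntegrationError(RuntimeError):
    """Raised when the ODE state becomes non-finite."""


def _march(n_steps, dt, vmax, km, pulse_steps, pulse_amounts):  # pragma: no cover
    conc = np.zeros(n_steps)
    x = 0.0
    p = 0
    n_pulses = pulse_steps.size
    for i in range(n_steps):
        while p < n_pulses and pulse_steps[p] == i:
            x += pulse_amounts[p]
            p += 1
        conc[i] = x
        k1 = -vmax * x / (km + x)
        x2 = x + 0.5 * dt * k1
        k2 = -vmax * x2 / (km + x2)
        x3 = x + 0.5 * dt * k2
        k3 = -vmax * x3 / (km + x3)
        x4 = x + dt * k3
        k4 = -vmax * x4 / (km + x4)
        x = x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if x < 0.0:
            x = 0.0
    return conc


try:  # numba shaves two orders of magnitude off repeated fits; optional
    from numba import njit

    _march = njit(cache=False)(_march)
except ImportError:  # pragma: no cover
    pass


def integrate_transient(
    duration: float,
    scan_rate: float,
    vmax: float,
    km: float,
    pulse_times,
    pulse_amount: float,
    internal_hz: int = INTERNAL_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the transient and return ``(time, concentration)`` at scan_rate.

    ``pulse_times`` are snapped to the internal grid; each pulse adds
    ``pulse_amount`` μM instantaneously.
    """
    if km <= 0 or vmax < 0 or scan_rate <= 0 or duration <= 0:
        raise ValueError("require km > 0, vmax >= 0, scan_rate > 0, duration > 0")
    stride = internal_hz / scan_rate
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(
            f"internal_hz={internal_hz} must be an integer multiple of scan_rate={scan_rate}"
        )
    stride = int(round(stride))
    dt = 1.0 / internal_hz
    n_out = int(round(duration * scan_rate))
    n_steps = n_out * stride
    pulse_times = np.asarray(pulse_times, dtype=float)
    pulse_steps = np.sort(np.rint(pulse_times * internal_hz)).astype(np.int64)
    if pulse_steps.size and (pulse_steps[0] < 0 or pulse_steps[-1] >= n_steps):
        raise ValueError("pulse times must fall inside the trace duration")
    amounts = np.full(pulse_steps.size, float(pulse_amount))
    conc_internal = _march(n_steps, dt, float(vmax), float(km), pulse_steps, amounts)
    if not np.all(np.isfinite(conc_internal)):
        raise IntegrationError(
            f"non-finite concentration during integration (vmax={vmax}, km={km}, "
            f"pulse_amount={pulse_amount})"
        )
    conc = conc_internal[::stride].copy()
    t = np.arange(n_out) / scan_rate
    return t, conc
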