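"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own numerics: the
transient oracle is a plain forward-Euler march at a 0.1 ms step, and
the rank-test oracle enumerates label assignments exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def euler_transient_oracle(
    duration: float,
    scan_rate: float,
    vmax: float,
    km: float,
    pulse_times,
    pulse_amount: float,
    dt: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Fine-step forward-Euler integration of the clearance ODE."""
    n_steps = int(round(duration / dt))
    pulse_steps = sorted(int(round(t / dt)) for t in pulse_times)
    conc = np.empty(n_steps)
    x = 0.0
    p = 0
    for i in range(n_steps):
        while p < len(pulse_steps) and pulse_steps[p] == i:
            x += pulse_amount
            p += 1
        conc[i] = x
        x += dt * (-vmax * x / (km + x))
        x = max(x, 0.0)
    stride = int(round(1.0 / (scan_rate * dt)))
    t = np.arange(0, n_steps, stride) * dt
    return t, conc[::stride]


def exhaustive_u_pvalue(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Returns (U of the first sample, p).  Assumes tie-free pooled data.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y

    def u_of(first_idx: tuple[int, ...]) -> float:
        first = [pooled[i] for i in first_idx]
        rest = [pooled[i] for i in range(n1 + n2) if i not in first_idx]
        return sum(1.0 for a in first for b in rest if a > b)

    u_obs = sum(1.0 for a in x for b in y if a > b)
    us = [u_of(c) for c in itertools.combinations(range(n1 + n2), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


@pytest.fixture(scope="session")
def euler_oracle():
    return euler_transient_oracle


@pytest.fixture(scope="session")
def u_oracle():
    return exhaustive_u_pvalue
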