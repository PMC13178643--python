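"""Signal-detection scoring of vigilance sessions and dose-response assembly."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .stats import inverse_normal_cdf

__all__ = [
    "TrialEvent",
    "SessionSummary",
    "BaselineResult",
    "PercentChange",
    "DoseResponsePoint",
    "EVENT_VOCAB",
    "parse_event_log",
    "summarize_session",
    "d_prime",
    "baseline",
    "percent_change",
    "dose_response",
]

EVENT_VOCAB = frozenset(
    {"trial_start", "cue_on", "hit", "miss", "incorrect", "premature", "reward", "timeout"}
)
PORTS = frozenset({"left", "right", "none"})

OUTCOMES = ("hit", "miss", "incorrect", "premature")


@dataclass(frozen=True)
class TrialEvent:
    t: float
    event: str
    port: str = "none"


@dataclass(frozen=True)
class SessionSummary:
    n_trials: int
    hits: int
    misses: int
    incorrect: int
    premature: int
    hit_rate: float
    fa_rate: float
    d_prime: float


@dataclass(frozen=True)
class BaselineResult:
    mean_hit_rate: float
    mean_d_prime: float
    stable: bool


@dataclass(frozen=True)
class PercentChange:
    hit_rate_pct: float
    d_prime_pct: float
    flagged: bool = False


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float
    pct_change_hit_rate: float
    pct_change_dprime: float
    n_determinations: int


class EventLogError(ValueError):
    """Malformed event log (vocabulary or ordering violation)."""


def parse_event_log(path) -> list[TrialEvent]:
    """Read a TSV event log (columns t_s, event, port; header mandatory)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        warnings.warn(f"{path}: empty event log", RuntimeWarning)
        return []
    header = lines[0].split("\t")
    if header[:3] != ["t_s", "event", "port"]:
        raise EventLogError(f"{path}: expected header 't_s\\tevent\\tport', got {lines[0]!r}")
    events: list[TrialEvent] = []
    last_t = -np.inf
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise EventLogError(f"{path}:{lineno}: expected 3 tab-separated fields")
        t_str, event, port = parts
        try:
            t = float(t_str)
        except ValueError as exc:
            raise EventLogError(f"{path}:{lineno}: bad timestamp {t_str!r}") from exc
        if event not in EVENT_VOCAB:
            raise EventLogError(f"{path}:{lineno}: unknown event {event!r}")
        if port not in PORTS:
            raise EventLogError(f"{path}:{lineno}: unknown port {port!r}")
        if t < last_t:
            raise EventLogError(f"{path}:{lineno}: non-monotone timestamp {t}")
        last_t = t
        events.append(TrialEvent(t, event, port))
    return events


def summarize_session(
    events: Sequence[TrialEvent], combined_fa: bool = False
) -> SessionSummary:
    """Tally trial outcomes and compute rates and d'.

    ``fa_rate`` counts premature responses per trial; pass
    ``combined_fa=True`` to also fold incorrect-port responses into it.
    """
    tallies = {k: 0 for k in OUTCOMES}
    n_trials = 0
    for ev in events:
        if ev.event == "trial_start":
            n_trials += 1
        elif ev.event in tallies:
            tallies[ev.event] += 1
    if n_trials == 0:
        raise ValueError("session contains no trials")
    if sum(tallies.values()) != n_trials:
        raise ValueError(
            f"corrupted log: {sum(tallies.values())} outcomes for {n_trials} trials"
        )
    hit_rate = tallies["hit"] / n_trials
    fa = tallies["premature"] + (tallies["incorrect"] if combined_fa else 0)
    fa_rate = fa / n_trials
    return SessionSummary(
        n_trials=n_trials,
        hits=tallies["hit"],
        misses=tallies["miss"],
        incorrect=tallies["incorrect"],
        premature=tallies["premature"],
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=d_prime(hit_rate, fa_rate, n_trials),
    )


def d_prime(
    hit_rate: float, fa_rate: float, n_trials: int, correction: str = "half"
) -> float:
    """d' = z(hit rate) - z(false-alarm rate).

    Extreme rates are corrected before the quantile transform:
    ``"half"`` clamps exact 0 / 1 to 1/(2n) and 1 - 1/(2n);
    ``"loglinear"`` maps every rate r to (r*n + 0.5) / (n + 1).
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if correction == "half":
        lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
        h = min(max(hit_rate, lo), hi) if hit_rate in (0.0, 1.0) else hit_rate
        f = min(max(fa_rate, lo), hi) if fa_rate in (0.0, 1.0) else fa_rate
    elif correction == "loglinear":
        h = (hit_rate * n_trials + 0.5) / (n_trials + 1)
        f = (fa_rate * n_trials + 0.5) / (n_trials + 1)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(inverse_normal_cdf(h) - inverse_normal_cdf(f))


def baseline(
    sessions: Sequence[SessionSummary], max_variability: float = 0.30
) -> BaselineResult:
    """Mean hit rate / d' over the last 3 pre-drug sessions plus stability.

    Stable iff every session's hit rate is within ``max_variability``
    (fractional) of the 3-session mean.
    """
    if len(sessions) != 3:
        raise ValueError("baseline requires exactly 3 sessions")
    rates = np.array([s.hit_rate for s in sessions])
    mean_hr = float(rates.mean())
    if mean_hr <= 0:
        raise ValueError("baseline hit rate is zero")
    stable = bool(np.max(np.abs(rates - mean_hr)) / mean_hr < max_variability)
    mean_dp = float(np.mean([s.d_prime for s in sessions]))
    return BaselineResult(mean_hr, mean_dp, stable)


def percent_change(
    session: SessionSummary, base: BaselineResult, min_dprime_baseline: float = 0.1
) -> PercentChange:
    """Percent change from baseline: 100 * (value - baseline) / |baseline|.

    Sessions whose baseline d' is below ``min_dprime_baseline`` are
    flagged and the d' change reported as NaN rather than scaled.
    """
    if base.mean_hit_rate <= 0:
        raise ValueError("baseline hit rate must be positive")
    hr_pct = 100.0 * (session.hit_rate - base.mean_hit_rate) / abs(base.mean_hit_rate)
    if abs(base.mean_d_prime) < min_dprime_baseline:
        return PercentChange(hr_pct, float("nan"), flagged=True)
    dp_pct = 100.0 * (session.d_prime - base.mean_d_prime) / abs(base.mean_d_prime)
    return PercentChange(hr_pct, dp_pct)


def dose_response(
    determinations: Mapping[float, Sequence[tuple[SessionSummary, BaselineResult]]],
) -> list[DoseResponsePoint]:
    """Mean percent-change measures per dose across testing cycles.

    ``determinations`` maps dose (mg/kg; 0 = saline) to the per-cycle
    (session, cycle baseline) pairs.  Points come back dose-ascending,
    so saline leads.
    """
    points = []
    for dose in sorted(determinations):
        pairs = determinations[dose]
        if not pairs:
            raise ValueError(f"dose {dose} has no sessions")
        changes = [percent_change(s, b) for s, b in pairs]
        points.append(
            DoseResponsePoint(
                dose=float(dose),
                pct_change_hit_rate=float(np.mean([c.hit_rate_pct for c in changes])),
                pct_change_dprime=float(np.nanmean([c.d_prime_pct for c in changes])),
                n_determinations=len(pairs),
            )
        )
    return points
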