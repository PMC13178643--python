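"""Seeded generators for the three data modalities the analyses consume.

Every generator is the explicit forward model of the corresponding
analysis: evoked transients from pulsed release plus saturable clearance
under competitive inhibition, negative-binomial nuclear count matrices
with marker structure and planted sex effects, and trial-by-trial
vigilance sessions with configurable response probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from ._integrate import integrate_transient
from .behavior import TrialEvent
from .fscv import StimulusProtocol, VoltammetryTrace
from .transcriptomics import CountMatrix

__all__ = [
    "FscvSimParams",
    "MarkerDesign",
    "SexEffect",
    "CountSimParams",
    "BehaviorSimParams",
    "CYCLE_PRESETS",
    "simulate_fscv_trace",
    "simulate_concentration_series",
    "simulate_counts",
    "simulate_session",
]


@dataclass(frozen=True)
class FscvSimParams:
    """Forward-model parameters for one evoked transient."""

    da_per_pulse: float = 1.0  # μM released per pulse
    vmax: float = 2.5  # μM/s maximal uptake
    km: float = 0.16  # μM baseline Michaelis constant
    inhibitor_conc: float = 0.0  # μM drug
    ki_true: float = 2.0  # μM inhibition constant
    release_scale: float = 1.0
    noise_sd: float = 0.0  # nA, additive on the current signal
    calibration_factor: float = 5.0  # nA per μM
    scan_rate: float = 10.0  # Hz
    duration: float = 15.0  # s
    stim_onset: float = 5.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vmax < 0 or self.km <= 0 or self.ki_true <= 0:
            raise ValueError("require vmax >= 0, km > 0, ki_true > 0")
        if self.inhibitor_conc < 0 or self.scan_rate <= 0:
            raise ValueError("require inhibitor_conc >= 0, scan_rate > 0")
        if self.calibration_factor <= 0 or self.noise_sd < 0:
            raise ValueError("require calibration_factor > 0, noise_sd >= 0")
        if not (0 <= self.stim_onset < self.duration):
            raise ValueError("stim_onset must lie inside the trace")

    @property
    def km_apparent(self) -> float:
        """Competitive model: Km_app = Km * (1 + [I]/Ki)."""
        return self.km * (1.0 + self.inhibitor_conc / self.ki_true)


#: Hormonal-state presets: multiplicative modifiers applied to
#: (da_per_pulse, vmax, ki_true).  Directions follow the reported
#: physiology (high-estradiol states release more, clear faster and show
#: higher drug potency); magnitudes are placeholders, not measurements.
CYCLE_PRESETS: dict[str, tuple[float, float, float]] = {
    "male": (1.0, 1.0, 1.0),
    "pro_estrus": (1.4, 1.3, 0.7),
    "met_diestrus": (1.0, 1.0, 1.0),
    "ovx": (0.9, 0.85, 1.3),
    "ovx_estradiol": (1.3, 1.2, 0.75),
}


def apply_cycle_preset(params: FscvSimParams, stage: str) -> FscvSimParams:
    """Return params with the hormonal-state modifiers applied."""
    dap, vmax, ki = CYCLE_PRESETS[stage]
    return replace(
        params,
        da_per_pulse=params.da_per_pulse * dap,
        vmax=params.vmax * vmax,
        ki_true=params.ki_true * ki,
    )


def simulate_fscv_trace(
    params: FscvSimParams,
    protocol: StimulusProtocol | None = None,
    unit: str = "uM",
    condition: Mapping[str, object] | None = None,
) -> VoltammetryTrace:
    """Simulate one evoked transient.

    Integrates dC/dt = -Vmax*C/(Km_app + C) with instantaneous release
    of ``release_scale * da_per_pulse`` at each pulse.  Gaussian noise of
    sd ``noise_sd`` (nA) is added on the current signal; for μM output it
    enters as ``noise_sd / calibration_factor``.
    """
    protocol = protocol or StimulusProtocol()
    pulses = protocol.pulse_times(params.stim_onset)
    t, conc = integrate_transient(
        params.duration,
        params.scan_rate,
        params.vmax,
        params.km_apparent,
        pulses,
        params.release_scale * params.da_per_pulse,
    )
    rng = np.random.default_rng(params.seed)
    cond = dict(condition or {})
    cond.setdefault("concentration", params.inhibitor_conc)
    if unit == "nA":
        signal = conc * params.calibration_factor
        if params.noise_sd > 0:
            signal = signal + rng.normal(0.0, params.noise_sd, signal.size)
    elif unit == "uM":
        signal = conc.copy()
        if params.noise_sd > 0:
            signal = signal + rng.normal(
                0.0, params.noise_sd / params.calibration_factor, signal.size
            )
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return VoltammetryTrace(
        time=t,
        signal=signal,
        unit=unit,
        protocol=protocol,
        stim_onset=params.stim_onset,
        condition=cond,
    )


def simulate_concentration_series(
    params: FscvSimParams,
    concentrations: Sequence[float],
    protocol: StimulusProtocol | None = None,
    unit: str = "uM",
) -> list[VoltammetryTrace]:
    """One trace per drug concentration, with a drug-free baseline prepended."""
    if len(concentrations) == 0:
        raise ValueError("concentration list is empty")
    concs = list(concentrations)
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly increasing")
    ladder = [0.0] + concs
    seeds = np.random.SeedSequence(params.seed).spawn(len(ladder))
    traces = []
    for conc, child in zip(ladder, seeds):
        p = replace(
            params, inhibitor_conc=conc, seed=int(child.generate_state(1)[0])
        )
        traces.append(simulate_fscv_trace(p, protocol, unit=unit))
    return traces


@dataclass(frozen=True)
class MarkerDesign:
    """Which genes act as the projection markers and their class means."""

    calb1: int = 0
    sox6: int = 1
    aldh1a1: int = 2
    on_mean: float = 10.0
    off_mean: float = 0.0

    def class_means(self, projection: str) -> dict[int, float]:
        if projection == "core":  # Calb1+ Sox6+ Aldh1a1-
            return {self.calb1: self.on_mean, self.sox6: self.on_mean,
                    self.aldh1a1: self.off_mean}
        if projection == "shell":  # Calb1+ Aldh1a1+ Sox6-
            return {self.calb1: self.on_mean, self.aldh1a1: self.on_mean,
                    self.sox6: self.off_mean}
        raise ValueError(f"unknown projection {projection!r}")


@dataclass(frozen=True)
class SexEffect:
    """Planted sex-differential gene: female mean is scaled by 2**lfc."""

    gene: int
    lfc: float
    projection: str = "both"  # "core" | "shell" | "both"


@dataclass(frozen=True)
class CountSimParams:
    n_nuclei: int = 50  # per (sex x projection) group
    n_genes: int = 500
    baseline_mean: float = 2.0
    dispersion: float = 0.2  # NB: var = mu + dispersion * mu^2
    marker_design: MarkerDesign = field(default_factory=MarkerDesign)
    sex_effect: tuple[SexEffect, ...] = ()
    libsize_spread: float = 0.2  # sigma of the lognormal libsize multiplier
    gene_mean_spread: float = 0.5  # sigma of per-gene lognormal mean variation
    mito_genes: tuple[int, ...] = ()
    n_samples_per_sex: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1 or self.n_genes < 3:
            raise ValueError("need n_nuclei >= 1 and n_genes >= 3")
        if self.dispersion < 0 or self.baseline_mean <= 0:
            raise ValueError("require dispersion >= 0 and baseline_mean > 0")
        md = self.marker_design
        for idx in (md.calb1, md.sox6, md.aldh1a1, *self.mito_genes):
            if not (0 <= idx < self.n_genes):
                raise ValueError(f"gene index {idx} out of range for n_genes={self.n_genes}")
        for eff in self.sex_effect:
            if not (0 <= eff.gene < self.n_genes):
                raise ValueError(f"sex-effect gene {eff.gene} out of range")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(params: CountSimParams) -> CountMatrix:
    """Genes × nuclei integer count matrix with sex / projection structure."""
    rng = np.random.default_rng(params.seed)
    md = params.marker_design
    marker_idx = {md.calb1, md.sox6, md.aldh1a1}

    gene_means = params.baseline_mean * rng.lognormal(
        -params.gene_mean_spread**2 / 2.0, params.gene_mean_spread, params.n_genes
    )

    groups = [(sex, proj) for sex in ("F", "M") for proj in ("core", "shell")]
    blocks = []
    meta_rows = []
    for sex, proj in groups:
        mu = np.tile(gene_means[:, None], (1, params.n_nuclei))
        for idx, mean in md.class_means(proj).items():
            mu[idx, :] = mean
        if sex == "F":
            for eff in params.sex_effect:
                if eff.projection in ("both", proj) and eff.gene not in marker_idx:
                    mu[eff.gene, :] *= 2.0**eff.lfc
        libsize = rng.lognormal(
            -params.libsize_spread**2 / 2.0, params.libsize_spread, params.n_nuclei
        )
        counts = _nb_sample(rng, mu * libsize[None, :], params.dispersion)
        blocks.append(counts)
        samples = np.arange(params.n_nuclei) % params.n_samples_per_sex
        for j in range(params.n_nuclei):
            meta_rows.append(
                {"sex": sex, "sample": f"{sex}{samples[j] + 1}", "projection_truth": proj}
            )

    counts = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows)
    meta.insert(0, "nucleus_id", [f"nuc{i:05d}" for i in range(len(meta))])

    gene_ids = [f"gene{i:04d}" for i in range(params.n_genes)]
    gene_ids[md.calb1] = "Calb1"
    gene_ids[md.sox6] = "Sox6"
    gene_ids[md.aldh1a1] = "Aldh1a1"
    for k, idx in enumerate(params.mito_genes):
        gene_ids[idx] = f"mt-gene{k:02d}"

    return CountMatrix(
        counts=sparse.csr_matrix(counts), gene_ids=gene_ids, nucleus_meta=meta
    )


@dataclass(frozen=True)
class BehaviorSimParams:
    hit_prob: float = 0.7
    premature_rate: float = 0.005  # pokes per second of intertrial interval
    incorrect_prob: float = 0.1  # P(poke dark port | responded, not a hit)
    session_length: float = 3600.0
    iti_set: tuple[float, ...] = (15.0, 30.0, 45.0)
    response_window: float = 5.0
    timeout: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.hit_prob, self.incorrect_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.premature_rate < 0 or self.session_length <= 0:
            raise ValueError("require premature_rate >= 0, session_length > 0")
        if not self.iti_set or any(i <= 0 for i in self.iti_set):
            raise ValueError("iti_set must contain positive intervals")


def simulate_session(params: BehaviorSimParams) -> list[TrialEvent]:
    """Generate one session's event log.

    Per trial: ITI drawn uniformly from ``iti_set``; a premature poke may
    occur during the ITI (exponential hazard) and aborts the trial with a
    timeout; otherwise the cue lights one of two ports (P = 0.5 each) and
    the outcome is hit / incorrect / miss per the configured
    probabilities.  Trials are generated until the session clock runs out.
    """
    rng = np.random.default_rng(params.seed)
    events: list[TrialEvent] = []
    t = 0.0
    while t < params.session_length:
        events.append(TrialEvent(t, "trial_start", "none"))
        iti = float(rng.choice(params.iti_set))
        premature_at = (
            rng.exponential(1.0 / params.premature_rate)
            if params.premature_rate > 0
            else np.inf
        )
        if premature_at < iti:
            t += premature_at
            events.append(TrialEvent(t, "premature", "none"))
            events.append(TrialEvent(t, "timeout", "none"))
            t += params.timeout
            continue
        t += iti
        port = "left" if rng.random() < 0.5 else "right"
        events.append(TrialEvent(t, "cue_on", port))
        u = rng.random()
        if u < params.hit_prob:
            latency = rng.uniform(0.1, params.response_window)
            t += latency
            events.append(TrialEvent(t, "hit", port))
            events.append(TrialEvent(t, "reward", port))
            t += params.timeout  # house light off until the next trial
        elif u < params.hit_prob + (1.0 - params.hit_prob) * params.incorrect_prob:
            latency = rng.uniform(0.1, params.response_window)
            t += latency
            other = "right" if port == "left" else "left"
            events.append(TrialEvent(t, "incorrect", other))
            events.append(TrialEvent(t, "timeout", "none"))
            t += params.timeout
        else:
            t += params.response_window
            events.append(TrialEvent(t, "miss", "none"))
            events.append(TrialEvent(t, "timeout", "none"))
            t += params.timeout
    return events
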