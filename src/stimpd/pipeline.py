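"""End-to-end orchestration: configuration, seeding and the demo run.

A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so stages are independently reproducible.
All outputs are plain text and contain no timestamps or absolute paths,
making report bundles byte-identical across invocations with the same
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__, behavior, fscv, io as sio, synthetic, transcriptomics as tx

__all__ = ["RunConfig", "run_demo", "validate_inputs"]

AMPH_LADDER = (0.1, 0.3, 1.0, 3.0, 10.0)  # μM
MPH_LADDER = (1.0, 3.0, 10.0, 30.0)  # μM
DOSE_LADDER = (0.0, 0.01, 0.03, 0.3, 1.0, 3.0)  # mg/kg, 0 = saline

#: Demo dose-effect presets: hit probability per dose, per sex.  The
#: female curve sits above the male one at effective doses, mirroring
#: the reported direction of the sex difference.
HIT_PROB_PRESETS: Mapping[str, Mapping[float, float]] = {
    "F": {0.0: 0.60, 0.01: 0.62, 0.03: 0.66, 0.3: 0.74, 1.0: 0.82, 3.0: 0.70},
    "M": {0.0: 0.60, 0.01: 0.61, 0.03: 0.63, 0.3: 0.68, 1.0: 0.72, 3.0: 0.64},
}

_KNOWN_KEYS = {"seed", "report_format", "fscv", "counts", "behavior", "bootstrap"}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    report_format: str = "json"
    fscv: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    behavior: dict = field(default_factory=dict)
    bootstrap: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.report_format not in ("json", "tsv"):
            raise ValueError("report_format must be 'json' or 'tsv'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    return [int(c.generate_state(1)[0]) for c in np.random.SeedSequence(seed).spawn(n)]


def _fscv_stage(config: RunConfig, seed: int, outdir: Path) -> list[str]:
    outputs = []
    overrides = dict(config.fscv)
    noise_sd = overrides.pop("noise_sd", 0.01)  # nA; ~0.2% of a 1 uM peak
    params = synthetic.FscvSimParams(seed=seed, noise_sd=noise_sd, **overrides)
    for drug, ladder in (("amph", AMPH_LADDER), ("mph", MPH_LADDER)):
        traces = synthetic.simulate_concentration_series(params, ladder)
        baseline_fit = fscv.fit_transient(traces[0])
        points = fscv.apparent_km_series(traces, baseline_fit)
        potency = fscv.estimate_ki(points, baseline_km=baseline_fit.km)
        series_path = outdir / f"{drug}_apparent_km.tsv"
        with open(series_path, "w") as fh:
            fh.write("concentration_uM\tapparent_km_uM\n")
            for p in points:
                fh.write(f"{p.concentration:g}\t{p.apparent_km:.6g}\n")
        potency_path = outdir / f"{drug}_potency.json"
        sio.write_json(
            {"drug": drug, "baseline_fit": baseline_fit, "potency": potency}, potency_path
        )
        outputs += [series_path.name, potency_path.name]
    return outputs


def _counts_stage(config: RunConfig, seed: int, outdir: Path) -> list[str]:
    overrides = dict(config.counts)
    planted = overrides.pop("planted_core_genes", 30)
    planted_lfc = overrides.pop("planted_lfc", 1.5)
    defaults = dict(n_nuclei=60, n_genes=1000)
    defaults.update(overrides)
    n_genes = defaults["n_genes"]
    effects = tuple(
        synthetic.SexEffect(gene=n_genes - 1 - k, lfc=planted_lfc, projection="core")
        for k in range(planted)
    )
    params = synthetic.CountSimParams(seed=seed, sex_effect=effects, **defaults)
    cm = synthetic.simulate_counts(params)
    mtx_dir = outdir / "counts"
    sio.write_counts_mtx(cm, mtx_dir)

    mito = [g for g in cm.gene_ids if g.startswith("mt-")]
    filtered, qc_report = tx.qc_filter(cm, mito_gene_set=mito)
    norm = tx.normalize_log1p(filtered)
    labels = tx.classify_projection(norm)

    boot_cfg = tx.BootstrapConfig(seed=seed, **config.bootstrap)
    dists = {}
    for region in ("core", "shell"):
        dists[region] = tx.bootstrap_deg_counts(
            norm, config=boot_cfg, region=region, nucleus_mask=labels == region
        )
    test = tx.compare_regions(dists["core"], dists["shell"])
    result_path = outdir / "deg_bootstrap.json"
    sio.write_json(
        {
            "qc_report": qc_report,
            "n_core": int((labels == "core").sum()),
            "n_shell": int((labels == "shell").sum()),
            "core_counts": list(dists["core"].counts),
            "shell_counts": list(dists["shell"].counts),
            "mann_whitney_u": test.statistic,
            "p_value": test.p_value,
        },
        result_path,
    )
    return [f"counts/{name}" for name in
            ("matrix.mtx", "genes.tsv", "barcodes.tsv", "metadata.tsv")] + [result_path.name]


def _behavior_stage(config: RunConfig, seed: int, outdir: Path) -> list[str]:
    overrides = dict(config.behavior)
    sex = overrides.pop("sex", "F")
    presets = HIT_PROB_PRESETS[sex]
    children = np.random.SeedSequence(seed).spawn(2 * (3 + len(DOSE_LADDER)))
    seeds = iter(int(c.generate_state(1)[0]) for c in children)

    determinations: dict[float, list] = {d: [] for d in DOSE_LADDER}
    for _cycle in range(2):
        base_sessions = []
        for _ in range(3):
            p = synthetic.BehaviorSimParams(
                hit_prob=presets[0.0], seed=next(seeds), **overrides
            )
            base_sessions.append(behavior.summarize_session(synthetic.simulate_session(p)))
        base = behavior.baseline(base_sessions)
        for dose in DOSE_LADDER:
            p = synthetic.BehaviorSimParams(
                hit_prob=presets[dose], seed=next(seeds), **overrides
            )
            summary = behavior.summarize_session(synthetic.simulate_session(p))
            determinations[dose].append((summary, base))

    points = behavior.dose_response(determinations)
    out_path = outdir / "dose_response.tsv"
    with open(out_path, "w") as fh:
        fh.write("dose_mg_kg\tpct_change_hit_rate\tpct_change_dprime\tn_determinations\n")
        for pt in points:
            fh.write(
                f"{pt.dose:g}\t{pt.pct_change_hit_rate:.4f}\t"
                f"{pt.pct_change_dprime:.4f}\t{pt.n_determinations}\n"
            )
    return [out_path.name]


def run_demo(config: RunConfig, outdir) -> dict:
    """Run all three stages with one seed and write a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(config.resolved_yaml())
    seeds = _stage_seeds(config.seed)
    stages = [
        ("fscv_potency", _fscv_stage),
        ("deg_bootstrap", _counts_stage),
        ("dose_response", _behavior_stage),
    ]
    manifest = {"package_version": __version__, "seed": config.seed, "stages": []}
    for (name, fn), stage_seed in zip(stages, seeds):
        try:
            outputs = fn(config, stage_seed, outdir)
        except Exception as exc:  # preserve partial outputs, name the stage
            sio.write_json(manifest, outdir / "manifest.json")
            raise RuntimeError(f"demo stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "seed": stage_seed, "outputs": outputs})
    sio.write_json(manifest, outdir / "manifest.json")
    return manifest


def validate_inputs(paths: Sequence) -> dict[str, list[str]]:
    """Format diagnostics for trace CSVs, MTX triplets and event logs."""
    report: dict[str, list[str]] = {}
    for p in paths:
        p = Path(p)
        issues: list[str] = []
        if p.is_dir():
            issues.extend(_validate_mtx_dir(p))
        elif p.suffix == ".csv":
            issues.extend(_validate_trace_csv(p))
        elif p.suffix == ".tsv":
            issues.extend(_validate_event_log(p))
        else:
            issues.append("unrecognized input type (expect .csv trace, .tsv log, or MTX dir)")
        report[str(p)] = issues
    return report


def _validate_trace_csv(path: Path) -> list[str]:
    issues = []
    lines = path.read_text().splitlines()
    if not lines:
        return ["empty file"]
    if lines[0] != "time_s,value,unit":
        issues.append(f"line 1: expected header 'time_s,value,unit', got {lines[0]!r}")
        return issues
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 3:
            issues.append(f"line {i}: expected 3 fields")
        elif parts[2] not in ("nA", "uM"):
            issues.append(f"line {i}: unit must be nA or uM, got {parts[2]!r}")
    return issues


def _validate_mtx_dir(path: Path) -> list[str]:
    issues = []
    required = ["matrix.mtx", "genes.tsv", "barcodes.tsv", "metadata.tsv"]
    for name in required:
        if not (path / name).exists():
            issues.append(f"missing {name}")
    if issues:
        return issues
    header = None
    for line in (path / "matrix.mtx").read_text().splitlines():
        if not line.startswith("%"):
            header = line.split()
            break
    n_genes = len((path / "genes.tsv").read_text().splitlines())
    n_cells = len((path / "barcodes.tsv").read_text().splitlines())
    if header is None or len(header) < 2:
        issues.append("matrix.mtx: missing dimension header")
    else:
        if int(header[0]) != n_genes:
            issues.append(
                f"matrix.mtx: {header[0]} rows but genes.tsv has {n_genes} entries"
            )
        if int(header[1]) != n_cells:
            issues.append(
                f"matrix.mtx: {header[1]} cols but barcodes.tsv has {n_cells} entries"
            )
    return issues


def _validate_event_log(path: Path) -> list[str]:
    from .behavior import EventLogError, parse_event_log

    try:
        parse_event_log(path)
    except EventLogError as exc:
        return [str(exc)]
    return []
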