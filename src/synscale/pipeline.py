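"""Desk-scale study orchestration.

``run_study`` composes the full analysis from one declarative config:
simulate (or ingest) two cohorts of voltage-clamp recordings, detect
and summarize mEPSCs, run the rank-order scaling analysis, generate and
analyze current-step families, analyze drug-epoch neurograms, and write
a set of CSV report tables plus a human-readable summary.  Everything
is deterministic under the configured master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import bursts as bursts_mod
from . import detection, excitability, scaling, synthetic
from .trace_io import write_table


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


_ANALYSIS_DEFAULTS = {"threshold": 7.5, "n_per_neuron": 50, "alpha": 0.05}
_BURST_DEFAULTS = {
    "enabled": True,
    "burst_rate": 10.0,
    "epoch_s": 600.0,
    "sampling_rate": 50.0,
    # drug-epoch multipliers per group: the treated group's burst
    # amplitude is AMPA-dependent after scaling, the control group's is not
    "epoch_effects": {
        "control": {"baseline": {"amplitude": 1.0, "frequency": 1.0},
                    "drug": {"amplitude": 1.0, "frequency": 0.2},
                    "washout": {"amplitude": 1.0, "frequency": 0.8}},
        "treated": {"baseline": {"amplitude": 1.0, "frequency": 1.0},
                    "drug": {"amplitude": 0.6, "frequency": 0.2},
                    "washout": {"amplitude": 0.9, "frequency": 0.8}},
    },
}
_FI_DEFAULTS = {"enabled": True, "sampling_rate": 10_000.0}


@dataclass
class StudyConfig:
    mode: str = "simulate"
    group_labels: tuple = ("control", "treated")
    n_neurons: int = 16
    scaling_factor: float = 1.51
    seed: int = 0
    output_dir: str = "report"
    mepsc: dict = field(default_factory=dict)      # MiniTraceParams overrides
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))
    fi: dict = field(default_factory=lambda: dict(_FI_DEFAULTS))
    bursts: dict = field(default_factory=lambda: json.loads(json.dumps(_BURST_DEFAULTS)))
    ingest_paths: dict = field(default_factory=dict)


def validate_config(source) -> StudyConfig:
    """Normalize a config mapping or YAML path into a StudyConfig.

    All defaults are resolved so the echoed config is complete; unknown
    keys are rejected with their key path.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    errors = []
    known = {f.name for f in fields(StudyConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    cfg = StudyConfig(**{k: v for k, v in raw.items() if k in known})
    cfg.group_labels = tuple(cfg.group_labels)
    if len(cfg.group_labels) != 2:
        errors.append("group_labels: exactly two groups required")
    if cfg.mode not in ("simulate", "ingest"):
        errors.append(f"mode: unknown mode {cfg.mode!r}")
    if not isinstance(cfg.seed, int) or cfg.seed < 0:
        errors.append("seed: must be a non-negative integer")
    if cfg.n_neurons < 1:
        errors.append("n_neurons: must be >= 1")
    if cfg.scaling_factor <= 0:
        errors.append("scaling_factor: must be positive")
    cfg.analysis = {**_ANALYSIS_DEFAULTS, **cfg.analysis}
    for key in cfg.analysis:
        if key not in _ANALYSIS_DEFAULTS:
            errors.append(f"analysis.{key}: unknown key")
    cfg.fi = {**_FI_DEFAULTS, **cfg.fi}
    merged_bursts = json.loads(json.dumps(_BURST_DEFAULTS))
    merged_bursts.update(cfg.bursts)
    cfg.bursts = merged_bursts
    if cfg.mode == "ingest":
        for label in cfg.group_labels:
            paths = cfg.ingest_paths.get(label, [])
            if not paths:
                errors.append(f"ingest_paths.{label}: no input traces listed")
            for p in paths:
                if not Path(p).exists():
                    errors.append(f"ingest_paths.{label}: missing file {p}")
    if errors:
        raise ConfigError(errors)
    return cfg


@dataclass
class StudyReport:
    per_neuron: list
    scaling_result: scaling.RankOrderResult
    scaling_verdict: scaling.ScalingVerdict
    fi_comparison: dict | None
    epoch_summaries: dict
    stats_appendix: list
    provenance: dict
    output_dir: Path


def _config_digest(cfg: StudyConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _amplitudes_for_group(cohort, det_config, n_per_neuron):
    events_by_neuron, records = {}, []
    for trace, _truth in cohort:
        nid = trace.metadata.get("neuron_id", f"n{len(records):02d}")
        events = detection.detect_events(trace, det_config)
        rec = detection.summarize_neuron(
            events, record=detection.NeuronRecord(
                neuron_id=nid, group=trace.metadata.get("group", "")))
        records.append(rec)
        first = detection.first_n_amplitudes(events, n_per_neuron)
        events_by_neuron[nid] = first.amplitudes
    return events_by_neuron, records


def run_study(config: StudyConfig | dict | str) -> StudyReport:
    """Run the complete study described by ``config`` and persist a report."""
    cfg = config if isinstance(config, StudyConfig) else validate_config(config)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage, **params):
        log_lines.append(json.dumps({"stage": stage, **params}, default=str))

    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    det_config = detection.DetectionConfig(threshold=cfg.analysis["threshold"])
    scale_config = scaling.ScalingConfig(
        n_per_neuron=cfg.analysis["n_per_neuron"],
        threshold=cfg.analysis["threshold"],
        alpha=cfg.analysis["alpha"],
    )
    stats_appendix = []

    # --- cohorts -----------------------------------------------------
    if cfg.mode == "simulate":
        params = synthetic.MiniTraceParams(**cfg.mepsc)
        control_cohort, treated_cohort = synthetic.generate_scaled_cohorts(
            params, cfg.scaling_factor, cfg.n_neurons, seed=seeds[0])
        log("simulate_cohorts", n_neurons=cfg.n_neurons,
            factor=cfg.scaling_factor, params=asdict(params))
    else:
        from .trace_io import read_timeseries
        cohorts = []
        for label in cfg.group_labels:
            cohort = []
            for p in cfg.ingest_paths[label]:
                tr = read_timeseries(p)
                tr.metadata.setdefault("group", label)
                tr.metadata.setdefault("neuron_id", Path(p).stem)
                cohort.append((tr, None))
            cohorts.append(cohort)
        control_cohort, treated_cohort = cohorts
        log("ingest", groups={l: len(c) for l, c in
                              zip(cfg.group_labels, cohorts)})

    # --- detection + per-neuron summaries ----------------------------
    ctrl_amps, ctrl_records = _amplitudes_for_group(
        control_cohort, det_config, cfg.analysis["n_per_neuron"])
    treat_amps, treat_records = _amplitudes_for_group(
        treated_cohort, det_config, cfg.analysis["n_per_neuron"])
    per_neuron = ctrl_records + treat_records
    log("detect", threshold=det_config.threshold,
        n_events={r.neuron_id: r.n_events for r in per_neuron})

    from .stats import mann_whitney, unpaired_t
    amp_t = unpaired_t([r.mean_amplitude for r in ctrl_records],
                       [r.mean_amplitude for r in treat_records])
    amp_t.notes = (amp_t.notes + "; mean mEPSC amplitude").strip("; ")
    freq_mw = mann_whitney([r.frequency for r in ctrl_records],
                           [r.frequency for r in treat_records])
    freq_mw.notes = (freq_mw.notes + "; mEPSC frequency").strip("; ")
    stats_appendix += [amp_t, freq_mw]

    # --- rank-order scaling ------------------------------------------
    rank_result, verdict = scaling.scaling_pipeline(
        ctrl_amps, treat_amps, scale_config)
    log("scaling", slope=rank_result.scaling_factor,
        r2_linear=rank_result.linear.r2, r2_exponential=rank_result.exponential.r2,
        ks_raw_p=verdict.ks_raw.p, ks_down_p=verdict.ks_downscaled.p,
        n_excluded=verdict.n_excluded_below_threshold,
        multiplicative=verdict.multiplicative)

    # --- intrinsic excitability --------------------------------------
    fi_comparison = None
    if cfg.fi.get("enabled", True):
        rng_fi = np.random.default_rng(seeds[1])
        fams = {label: [] for label in cfg.group_labels}
        for label in cfg.group_labels:
            for _ in range(cfg.n_neurons):
                fam = synthetic.generate_fi_sweeps(
                    synthetic.LIFParams(),
                    sampling_rate=cfg.fi["sampling_rate"],
                    seed=rng_fi.integers(2**31))
                fams[label].append(fam)
        fi_comparison = excitability.compare_fi_slopes(
            fams[cfg.group_labels[0]], fams[cfg.group_labels[1]],
            labels=cfg.group_labels)
        stats_appendix += [fi_comparison["ancova"], fi_comparison["gain_t"]]
        log("fi", mean_gains=fi_comparison["mean_gains"],
            ancova_p=fi_comparison["ancova"].p)

    # --- burst epochs -------------------------------------------------
    epoch_summaries = {}
    if cfg.bursts.get("enabled", True):
        rng_b = np.random.default_rng(seeds[2])
        epoch_s = cfg.bursts["epoch_s"]
        epochs = {"baseline": (0.0, epoch_s),
                  "drug": (epoch_s, 2 * epoch_s),
                  "washout": (2 * epoch_s, 3 * epoch_s)}
        for label in cfg.group_labels:
            effects = cfg.bursts["epoch_effects"].get(
                label, cfg.bursts["epoch_effects"]["control"
                                                   if label == cfg.group_labels[0]
                                                   else "treated"])
            cnx, snii, _truth = synthetic.generate_neurogram(
                burst_rate=cfg.bursts["burst_rate"], epochs=epochs,
                epoch_effects=effects,
                sampling_rate=cfg.bursts["sampling_rate"],
                seed=rng_b.integers(2**31))
            detected = bursts_mod.detect_bursts(cnx, snii)
            resp = bursts_mod.respiratory_bursts(detected)
            epoch_summaries[label] = bursts_mod.epoch_compare(resp, epochs)
        log("bursts", epochs=epochs,
            counts={k: [s.n_bursts for s in v] for k, v in epoch_summaries.items()})

    # --- report -------------------------------------------------------
    provenance = {
        "config": asdict(cfg),
        "config_digest": _config_digest(cfg),
        "seed": cfg.seed,
        "package": "synscale 0.1.0",
    }
    report = StudyReport(
        per_neuron=per_neuron, scaling_result=rank_result,
        scaling_verdict=verdict, fi_comparison=fi_comparison,
        epoch_summaries=epoch_summaries, stats_appendix=stats_appendix,
        provenance=provenance, output_dir=outdir)
    _write_report(report, cfg, log_lines)
    return report


def _write_report(report: StudyReport, cfg: StudyConfig, log_lines) -> None:
    outdir = report.output_dir
    write_table(report.per_neuron, outdir / "per_neuron.csv")

    r = report.scaling_result
    v = report.scaling_verdict
    scaling_rows = [{
        "n_points": r.n_points,
        "slope": r.linear.slope,
        "intercept": r.linear.intercept,
        "r2_linear": r.linear.r2,
        "r2_exponential": r.exponential.r2,
        "ks_raw_D": v.ks_raw.D, "ks_raw_p": v.ks_raw.p,
        "ks_downscaled_D": v.ks_downscaled.D, "ks_downscaled_p": v.ks_downscaled.p,
        "n_excluded_below_threshold": v.n_excluded_below_threshold,
        "multiplicative": v.multiplicative,
    }]
    write_table(scaling_rows, outdir / "scaling.csv")

    stats_rows = [{
        "test": t.name, "statistic": t.statistic, "df": str(t.df),
        "p": t.p, "n": str(t.n), "notes": t.notes,
    } for t in report.stats_appendix]
    if stats_rows:
        stats_rows[-1]["notes"] += f" [{len(stats_rows)} tests run, uncorrected]"
    write_table(stats_rows, outdir / "stats.csv")

    epoch_rows = []
    for label, summaries in report.epoch_summaries.items():
        for s in summaries:
            epoch_rows.append({
                "group": label, "epoch": s.epoch,
                "window_start_s": s.window[0], "window_end_s": s.window[1],
                "n_bursts": s.n_bursts, "frequency_per_min": s.frequency,
                "mean_amplitude": s.mean_amplitude, "mean_area": s.mean_area,
                "pct_baseline_frequency": s.percent_of_baseline.get("frequency"),
                "pct_baseline_amplitude": s.percent_of_baseline.get("amplitude"),
                "pct_baseline_area": s.percent_of_baseline.get("area"),
            })
    if epoch_rows:
        write_table(epoch_rows, outdir / "burst_epochs.csv")

    with open(outdir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    lines = [
        "synscale study report",
        "=====================",
        f"groups: {cfg.group_labels[0]} vs {cfg.group_labels[1]} "
        f"({cfg.n_neurons} neurons each, seed {cfg.seed})",
        "",
        f"rank-order points: {r.n_points}",
        f"scaling factor (linear slope): {r.linear.slope:.3f} "
        f"(intercept {r.linear.intercept:.3f}, r2 {r.linear.r2:.4f})",
        f"exponential fit r2: {r.exponential.r2:.4f}",
        f"KS control vs treated: D={v.ks_raw.D:.3f}, p={v.ks_raw.p:.3g}",
        f"KS control vs down-scaled: D={v.ks_downscaled.D:.3f}, "
        f"p={v.ks_downscaled.p:.3g} "
        f"({v.n_excluded_below_threshold} scaled values below threshold excluded)",
        f"multiplicative scaling verdict: {v.multiplicative}",
    ]
    if report.fi_comparison is not None:
        fc = report.fi_comparison
        lines += [
            "",
            "F-I gains (Hz/pA): " + ", ".join(
                f"{k}={g:.4f}" for k, g in fc["mean_gains"].items()),
            f"ANCOVA slope interaction: F={fc['ancova'].statistic:.3f}, "
            f"p={fc['ancova'].p:.4f}",
        ]
    for label, summaries in report.epoch_summaries.items():
        lines.append("")
        lines.append(f"bursts [{label}]:")
        for s in summaries:
            pct = s.percent_of_baseline
            lines.append(
                f"  {s.epoch}: {s.n_bursts} bursts, {s.frequency:.2f}/min"
                + (f", amplitude {pct['amplitude']:.0f}% / "
                   f"frequency {pct['frequency']:.0f}% of baseline"
                   if pct.get("amplitude") is not None else ""))
    with open(outdir / "summary.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")
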