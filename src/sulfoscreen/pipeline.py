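"""End-to-end pipeline runs: simulate -> call hits -> classify, and
simulate traces -> process -> infer digests/binding.

Each run writes a self-contained directory: the datasets, intermediate
tables, a summary JSON, a plain-text log with stage timings, and the fully
resolved configuration (all defaults materialized) sufficient to reproduce
the run exactly. Runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ce, digest, hits, panel, simulate
from .kinetics import NoiseModel

__all__ = ["RunConfig", "run_screen_pipeline", "run_ce_pipeline", "load_config"]

logger = logging.getLogger("sulfoscreen")


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters for one pipeline run."""

    seed: int
    out_dir: str = "run"
    # screen stage
    n_plates: int = 5
    wells_per_plate: int = 384
    controls_per_plate: int = 16
    timepoints: tuple[float, ...] = simulate.DEFAULT_TIMEPOINTS
    class_frequencies: dict = field(
        default_factory=lambda: dict(simulate.DEFAULT_CLASS_FREQUENCIES))
    noise_sd: float = 5.0
    primary_sigma: float = 3.0
    primary_min_timepoints: int = 1
    secondary_sigma: float = 6.0
    secondary_min_timepoints: int = 2
    scope: str = "plate"
    panel_sigma: float = 3.0
    # CE stage
    trace_noise_sd: float = 2.0
    warp_slope: float = 1.0
    warp_intercept: float = 0.0
    assignment_tolerance_mtu: float = 1.0
    decrease_threshold: float = 0.20

    def screen_config(self) -> simulate.ScreenConfig:
        return simulate.ScreenConfig(
            n_plates=self.n_plates, wells_per_plate=self.wells_per_plate,
            controls_per_plate=self.controls_per_plate,
            timepoints=tuple(self.timepoints),
            class_frequencies=dict(self.class_frequencies),
            noise=NoiseModel(sd_additive=self.noise_sd), seed=self.seed)


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    if "timepoints" in raw:
        raw["timepoints"] = tuple(float(t) for t in raw["timepoints"])
    return RunConfig(**raw)


def _prepare_run_dir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = dataclasses.asdict(config)
    resolved["timepoints"] = list(config.timepoints)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    return out


class _StageLog:
    def __init__(self, out: Path):
        self.path = out / "run.log"
        self.lines: list[str] = []

    def stage(self, name: str):
        return _StageTimer(self, name)

    def write(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


class _StageTimer:
    def __init__(self, log: _StageLog, name: str):
        self.log, self.name = log, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        status = "FAILED" if exc_type else "ok"
        self.log.lines.append(f"stage={self.name} status={status} seconds={dt:.2f}")
        logger.info("stage %s: %s (%.2f s)", self.name, status, dt)
        return False


def run_screen_pipeline(config: RunConfig) -> Path:
    """Simulate a screen, call both hit stages, classify secondary hits.

    Writes screen.csv, truth.tsv, hits_{primary,secondary}.tsv, calls.tsv,
    summary.json and run.log into the run directory; returns the directory.
    """
    out = _prepare_run_dir(config)
    log = _StageLog(out)

    with log.stage("simulate-screen"):
        dataset, truth = simulate.simulate_screen(config.screen_config())
        simulate.write_screen_csv(dataset, out / "screen.csv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    with log.stage("call-hits"):
        stats = hits.control_stats(dataset, config.scope)
        primary = hits.call_primary(dataset, stats, config.primary_sigma,
                                    config.primary_min_timepoints)
        primary_ids = {c.well_id for c in primary if c.is_hit}
        # secondary stage re-screens only the primary hits (fresh stats)
        mask = (dataset.data["plate"] + "/" + dataset.data["well"]).isin(primary_ids)
        rescreen = simulate.ScreenDataset(pd.concat(
            [dataset.data[mask],
             dataset.data[dataset.data["role"] == "control"]]).drop_duplicates())
        stats2 = hits.control_stats(rescreen, config.scope)
        secondary = hits.call_secondary(rescreen, stats2, config.secondary_sigma,
                                        config.secondary_min_timepoints)
        hits.hits_to_frame(primary).to_csv(out / "hits_primary.tsv", sep="\t", index=False)
        hits.hits_to_frame(secondary).to_csv(out / "hits_secondary.tsv", sep="\t", index=False)

    with log.stage("classify"):
        secondary_ids = sorted(c.well_id for c in secondary if c.is_hit)
        truth_ix = truth.set_index(truth["plate"] + "/" + truth["well"])
        # controls must carry the same read noise as the clone panels:
        # noiseless controls would degenerate the threshold to the bare mean
        controls = simulate.simulate_panel_controls(
            n_controls=config.controls_per_plate, seed=config.seed,
            noise=NoiseModel(sd_additive=config.noise_sd))
        calls = []
        for i, wid in enumerate(secondary_ids):
            row = truth_ix.loc[wid]
            profile = simulate.WellProfile(
                well_id=wid, role="clone", true_class=row["true_class"],
                sulfatase_rate=float(row["sulfatase_rate"]),
                generic_sulfatase=bool(row["generic_sulfatase"]),
                hex_sulfated_rate=float(row["hex_sulfated_rate"]),
                hex_asulfated_rate=float(row["hex_asulfated_rate"]),
                autofluor_rate=float(row["autofluor_rate"]))
            pan = simulate.simulate_panel(
                profile, seed=config.seed * 7919 + i,
                noise=NoiseModel(sd_additive=config.noise_sd))
            pattern = panel.threshold_activities(pan, controls, config.panel_sigma)
            calls.append(panel.classify(pattern, wid))
        panel.calls_to_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)

    with log.stage("summarize"):
        n_clones = int((truth["role"] == "clone").sum())
        n_primary, n_secondary = len(primary_ids), len(secondary_ids)
        rate_full, rate_1dp = hits.hit_rate(n_secondary, n_clones)
        planted = truth[truth["role"] == "clone"]["true_class"].value_counts().to_dict()
        called = {}
        confusion: dict[str, dict[str, int]] = {}
        for c in calls:
            called[c.label] = called.get(c.label, 0) + 1
            true_cls = str(truth_ix.loc[c.clone_id, "true_class"])
            confusion.setdefault(true_cls, {})
            confusion[true_cls][c.label] = confusion[true_cls].get(c.label, 0) + 1
        summary = {
            "n_clone_wells": n_clones,
            "n_primary_hits": n_primary,
            "n_secondary_hits": n_secondary,
            "hit_rate_pct": rate_full,
            "hit_rate_pct_1dp": rate_1dp,
            "planted_classes": {k: int(v) for k, v in sorted(planted.items())},
            "called_classes": dict(sorted(called.items())),
            "confusion_planted_vs_called": confusion,
            "cohort": panel.summarize_cohort(calls),
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    log.write()
    return out


def run_ce_pipeline(config: RunConfig) -> Path:
    """Simulate digest/binding trace experiments and run the CE inference.

    Demonstrates the three characterized enzymes on the built-in glycan pool
    plus the calcium-free binding experiment; writes peak tables, digest and
    binding calls, a report and summary JSON.
    """
    out = _prepare_run_dir(config)
    log = _StageLog(out)
    library = simulate.builtin_glycan_library()
    enzymes = simulate.builtin_enzymes()
    pool = {"FA2G0-SO4": 60.0, "FA2G0": 40.0, "FA2G2-SO4": 30.0, "A2G0": 25.0}
    spec = simulate.TraceSpec(components=(), seed=config.seed,
                              warp_slope=config.warp_slope,
                              warp_intercept=config.warp_intercept,
                              noise_sd=config.trace_noise_sd)

    def process(trace):
        return ce.process_trace(trace, library, config.assignment_tolerance_mtu)

    report_lines = []
    digest_frames = []
    with log.stage("digests"):
        for name in ("F1_SULFATASE", "F10_HEXOSAMINIDASE", "BGLCNACASE_S"):
            enz = enzymes[name]
            pre, post = simulate.simulate_digest_pair(pool, enz, spec, library)
            pre_peaks, post_peaks = process(pre), process(post)
            ce.peaks_to_frame(pre_peaks).to_csv(out / f"peaks_{name}_pre.tsv",
                                                sep="\t", index=False)
            ce.peaks_to_frame(post_peaks).to_csv(out / f"peaks_{name}_post.tsv",
                                                 sep="\t", index=False)
            rules = [digest.TransitionRule(enz.name, s, p)
                     for s, p in enz.transitions]
            calls = digest.call_digest(pre_peaks, post_peaks, rules,
                                       config.decrease_threshold, library)
            frame = digest.digest_calls_to_frame(calls)
            frame.insert(0, "enzyme_run", name)
            digest_frames.append(frame)
            for c in calls:
                report_lines.append(
                    f"{name}: {c.substrate} -> {c.verdict}"
                    + (f" (product {c.rule.product})" if c.verdict == "hydrolyzed" else ""))
        pd.concat(digest_frames).to_csv(out / "digest_calls.tsv", sep="\t", index=False)

    with log.stage("binding"):
        apo = enzymes["F1_APO_BINDING"]
        binding_pool = {"FA2G0-SO4": 60.0, "FA2G0": 40.0}
        control_trace, _ = simulate.simulate_trace(
            dataclasses.replace(spec, components=tuple(
                simulate.TraceComponent(n, {e.name: e.mtu for e in library}[n], a)
                for n, a in sorted(binding_pool.items()))))
        _, direct_trace = simulate.simulate_digest_pair(binding_pool, apo, spec, library)
        protk_trace, _ = simulate.simulate_trace(
            dataclasses.replace(spec, seed=config.seed + 2, components=tuple(
                simulate.TraceComponent(n, {e.name: e.mtu for e in library}[n], a)
                for n, a in sorted(binding_pool.items()))))
        bind = digest.call_binding(
            process(control_trace), process(direct_trace), process(protk_trace),
            substrate="FA2G0-SO4",
            rules=[digest.TransitionRule("F1_SULFATASE", "FA2G0-SO4", "FA2G0")],
            decrease_threshold=config.decrease_threshold)
        report_lines.append(
            f"F1_APO (no calcium): FA2G0-SO4 -> {bind.verdict} "
            f"(control {bind.control_height:.1f}%, direct {bind.direct_height:.1f}%, "
            f"proteinase-K {bind.protk_height:.1f}%)")

    with log.stage("report"):
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        summary = {
            "digest_calls": {
                f"{r['enzyme_run']}:{r['substrate']}": r["verdict"]
                for f_ in digest_frames for r in f_.to_dict("records")},
            "binding_verdict": bind.verdict,
            "seed": config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    log.write()
    return out
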