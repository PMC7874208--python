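"""End-to-end runner: simulate/track -> cycle metrics -> temporal -> stats.

A run is described by a YAML/dict config::

    seed: 1
    out_dir: out
    protocol: {kind: standard, frequency: 0.53, fps: 30}
    threshold_deg: 5
    window: 5
    startle_deg: 45
    groups:                      # simulated larvae
      - genotype: wild_type
        n: 8
        params: {preset: wild_type}
    traces:                      # and/or pre-tracked trace CSVs
      - {larva_id: fish01, genotype: wild_type, path: fish01.csv}
    videos:                      # and/or PNG frame directories
      - {larva_id: fish02, genotype: wild_type, path: frames/fish02}
    compare_metrics: [normalized_integral_deg]

Each simulated larva gets its own child seed spawned from the run seed, so
a config + seed pair is fully deterministic.  Outputs per larva: a trace
CSV (simulated larvae), a per-cycle CSV and a trial-summary JSON; per run:
a combined cycles table, a group-stats CSV per compared metric, and a
plain-text run log.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    load_config,
    params_from_config,
    protocol_from_config,
    read_trace_csv,
    write_cycles_csv,
    write_trace_csv,
    write_trial_json,
)
from .metrics import (
    DEFAULT_THRESHOLD_DEG,
    DEFAULT_WINDOW,
    STARTLE_THRESHOLD_DEG,
    analyze_trace,
)
from .stats import compare_groups
from .synth import simulate_trace
from .temporal import summarize_trial
from .tracking import read_frames, track_video

__all__ = ["run_pipeline"]

log = logging.getLogger("vsrkit")

DEFAULT_COMPARE_METRICS = [
    "max_tail_angle_deg",
    "normalized_integral_deg",
    "pct_above_threshold",
]


def _setup_logging(out_dir: Path, verbose: bool) -> None:
    log.setLevel(logging.DEBUG)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(fmt)
    fh.setLevel(logging.DEBUG)
    log.addHandler(fh)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    sh.setLevel(logging.DEBUG if verbose else logging.WARNING)
    log.addHandler(sh)


def run_pipeline(
    config: dict[str, Any] | str | Path,
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> dict[str, Any]:
    """Execute a full analysis run; returns the collected results.

    The returned dict holds ``cycles`` (combined per-cycle table),
    ``trials`` (larva_id -> TrialResult) and ``stats`` (metric ->
    StatsResult, when at least two genotypes are present).  Per-larva
    errors are logged with the larva id and re-raised; outputs produced up
    to that point remain on disk.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "vsr_out"))
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)

    seed = int(cfg.get("seed", 0))
    protocol = protocol_from_config(cfg.get("protocol"))
    threshold = float(cfg.get("threshold_deg", DEFAULT_THRESHOLD_DEG))
    window = int(cfg.get("window", DEFAULT_WINDOW))
    startle = float(cfg.get("startle_deg", STARTLE_THRESHOLD_DEG))
    rests = protocol.rest_durations()

    log.info(
        "vsrkit %s | seed=%d | protocol %.2f Hz ±%.0f° %g fps, %d epoch(s), total %.1f s",
        __version__,
        seed,
        protocol.frequency,
        protocol.amplitude,
        protocol.fps,
        len(protocol.epoch_schedule()),
        protocol.total_duration_s(),
    )
    log.info("threshold=%g° window=%d startle=%g°", threshold, window, startle)

    jobs: list[tuple[str, str, Any]] = []  # (larva_id, genotype, trace-or-path)
    ss = np.random.SeedSequence(seed)
    for group in cfg.get("groups", []) or []:
        genotype = str(group["genotype"])
        n = int(group.get("n", 1))
        children = ss.spawn(n)
        for i, child in enumerate(children):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            params = params_from_config(
                {**(group.get("params") or {}), "seed": child_seed}
            )
            jobs.append((f"{genotype}_{i:02d}", genotype, ("simulate", params)))
    for spec in cfg.get("traces", []) or []:
        jobs.append(
            (str(spec["larva_id"]), str(spec.get("genotype", "unknown")),
             ("trace", Path(spec["path"])))
        )
    for spec in cfg.get("videos", []) or []:
        jobs.append(
            (str(spec["larva_id"]), str(spec.get("genotype", "unknown")),
             ("video", Path(spec["path"])))
        )
    if not jobs:
        raise ValueError("config defines no groups, traces or videos")

    all_cycles: list[pd.DataFrame] = []
    trials = {}
    t0 = time.time()
    for larva_id, genotype, (kind, payload) in jobs:
        try:
            if kind == "simulate":
                trace = simulate_trace(payload, protocol)
                write_trace_csv(trace, out / f"{larva_id}_trace.csv")
            elif kind == "trace":
                trace = read_trace_csv(payload, fps=protocol.fps)
            else:
                trace = track_video(read_frames(payload), protocol=protocol)
            cycles = analyze_trace(
                trace, threshold, window, startle, larva_id=larva_id
            )
            cycles.insert(1, "genotype", genotype)
            trial = summarize_trial(
                cycles, rests_s=rests if len(rests) > 1 else None,
                larva_id=larva_id, genotype=genotype,
            )
        except Exception:
            log.exception("larva %s (%s): stage failed", larva_id, genotype)
            raise
        write_cycles_csv(cycles, out / f"{larva_id}_cycles.csv")
        write_trial_json(trial, out / f"{larva_id}_trial.json")
        all_cycles.append(cycles)
        trials[larva_id] = trial
        log.info(
            "larva %s (%s): %d retained cycles, %.1f%% active",
            larva_id, genotype, trial.n_retained, trial.pct_active,
        )

    combined = pd.concat(all_cycles, ignore_index=True)
    write_cycles_csv(combined, out / "cycles.csv")

    stats_results = {}
    if combined["genotype"].nunique() >= 2:
        retained = combined[~combined["excluded"]]
        for metric in cfg.get("compare_metrics", DEFAULT_COMPARE_METRICS):
            res = compare_groups(retained, metric)
            stats_results[metric] = res
            tbl = res.contrasts.copy()
            tbl.insert(0, "metric", metric)
            tbl["F_genotype"] = float(res.anova.loc["genotype", "F"])
            tbl["p_genotype"] = res.genotype_p
            tbl.to_csv(out / f"stats_{metric}.csv", index=False, float_format="%.6g")
            log.info(
                "metric %s: genotype p=%.3g, %d/%d cycles significant (q<0.05)",
                metric, res.genotype_p, res.n_significant_cycles, len(tbl),
            )

    log.info("run complete in %.1f s; outputs in %s", time.time() - t0, out)
    return {"cycles": combined, "trials": trials, "stats": stats_results, "out_dir": out}
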