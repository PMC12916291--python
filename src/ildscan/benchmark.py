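"""Simulate -> scan validation benchmarks: false-positive rate and power.

``run_benchmark`` drives the forward simulator through a named scenario
suite, runs the full iLDS scan on every replicate, and aggregates:

* FPR — the pooled fraction of scored windows called significant in
  scenarios without positive selection (neutrality and the demographic /
  recombination confounders), with a binomial confidence interval;
* power — for sweep scenarios, the fraction of replicates in which any
  sweep call overlaps the true sweep site, tabulated over the
  ``(s_B, s_D)`` grid.

Replicates whose scan degenerates (too few scorable windows) or whose sweep
fails to establish are counted and reported, never silently dropped.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import scan as scan_mod
from . import simulator
from .errors import ConditioningError, DegenerateScanError, InsufficientDataError
from .types import BenchmarkReport, ScanConfig

logger = logging.getLogger(__name__)


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    lo, hi = sp_stats.beta.interval(level, k + 0.5, n - k + 0.5)  # Jeffreys
    return float(lo), float(hi)


def run_replicate(
    sim_cfg, scan_cfg: Optional[ScanConfig] = None
) -> tuple[Optional[simulator.SimulationResult], Optional[scan_mod.ScanResult], str]:
    """Simulate one replicate and scan it; returns (sim, scan, status).

    status is ``ok``, ``conditioning_failure`` (sweep never established) or
    ``degenerate_scan`` (too few scorable windows to standardize).
    """
    if scan_cfg is None:
        scan_cfg = ScanConfig(seed=sim_cfg.seed)
    try:
        sim_res = simulator.simulate(sim_cfg)
    except ConditioningError:
        return None, None, "conditioning_failure"
    try:
        scan_res = scan_mod.scan(sim_res.alignment, sim_res.genes, scan_cfg)
    except (DegenerateScanError, InsufficientDataError):
        return sim_res, None, "degenerate_scan"
    return sim_res, scan_res, "ok"


def _detected(sim_res, scan_res) -> tuple[bool, bool]:
    """(any sweep called, a called sweep contains the true sweep site)."""
    if scan_res is None or not scan_res.sweeps:
        return False, False
    if sim_res.sweep_site is None:
        return True, False
    hit = any(
        s.start <= sim_res.sweep_site < s.end
        and s.contig_id == sim_res.alignment.contig_id
        for s in scan_res.sweeps
    )
    return True, hit


def run_benchmark(
    suite: str,
    scale: float = 0.1,
    reps: int = 20,
    seed: int = 0,
    scan_cfg: Optional[ScanConfig] = None,
) -> BenchmarkReport:
    """Run a scenario suite end-to-end and report FPR / power.

    ``reps`` is the number of replicates per scenario configuration (per
    grid cell for ``sweep_grid``).  ``reps = 0`` returns an empty report.
    Deterministic given ``seed``.
    """
    t0 = time.time()
    configs = simulator.scenario_suite(suite, scale, n_replicates=reps, base_seed=seed)
    n_windows = 0
    n_sig = 0
    n_completed = 0
    status_counts: dict[str, int] = {}
    power_rows: dict[tuple[float, float], dict[str, int]] = {}

    for cfg in configs:
        rep_scan_cfg = (
            ScanConfig(**{**asdict(scan_cfg), "seed": cfg.seed})
            if scan_cfg is not None
            else ScanConfig(seed=cfg.seed)
        )
        sim_res, scan_res, status = run_replicate(cfg, rep_scan_cfg)
        status_counts[status] = status_counts.get(status, 0) + 1
        if status != "ok":
            logger.info("replicate seed=%d: %s", cfg.seed, status)
            continue
        n_completed += 1
        tab = scan_res.window_table()
        n_windows += len(tab)
        n_sig += int(tab["significant"].sum())
        key = (cfg.s_B, cfg.s_D)
        row = power_rows.setdefault(
            key, {"n": 0, "detected": 0, "located": 0}
        )
        row["n"] += 1
        det, hit = _detected(sim_res, scan_res)
        row["detected"] += int(det)
        row["located"] += int(hit)

    power = pd.DataFrame(
        [
            {
                "s_B": k[0],
                "s_D": k[1],
                "n": v["n"],
                "detected": v["detected"],
                # a power estimate from fewer than 20 completed replicates
                # is too coarse to report
                "power": v["detected"] / v["n"] if v["n"] >= 20 else np.nan,
                "locate_rate": (
                    v["located"] / v["detected"] if v["detected"] else np.nan
                ),
            }
            for k, v in sorted(power_rows.items())
        ]
    )
    fpr = n_sig / n_windows if n_windows else np.nan
    report = BenchmarkReport(
        scenario=suite,
        n_replicates=n_completed,
        fpr=fpr,
        fpr_ci=_binomial_ci(n_sig, n_windows),
        n_windows_total=n_windows,
        n_significant_total=n_sig,
        power_by_parameters=power,
        runtime_seconds=time.time() - t0,
        config={
            "suite": suite,
            "scale": scale,
            "reps": reps,
            "seed": seed,
            "statuses": status_counts,
        },
    )
    return report


def report_to_dict(report: BenchmarkReport) -> dict:
    """JSON-serializable view of a benchmark report."""
    return {
        "scenario": report.scenario,
        "n_replicates": report.n_replicates,
        "fpr": None if np.isnan(report.fpr) else report.fpr,
        "fpr_ci": list(report.fpr_ci),
        "n_windows_total": report.n_windows_total,
        "n_significant_total": report.n_significant_total,
        "power_by_parameters": report.power_by_parameters.to_dict("records"),
        "runtime_seconds": report.runtime_seconds,
        "config": report.config,
    }
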