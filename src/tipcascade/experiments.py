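"""Experiment driver: dispatch a config to the library and write tidy outputs.

Every run writes its result CSVs plus a JSON manifest recording the full
parameter set, master seed, package version and wall time, so any result
file can be regenerated from its manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import bifurcation_diagram, fixed_points_analytic, hysteresis_loop, min_stable_surface
from .cascade import replicate_seed, simulate_replicate, sweep_final_share
from .config import ExperimentConfig
from .emergent import analytic_curve, empirical_threshold_curve
from .partition import PopulationPartition

log = logging.getLogger("tipcascade")


def _log_a_grid(points: int, lo: float = 1e-3, hi: float = 1.0) -> np.ndarray:
    """Logarithmic grid in a, mirroring 'A varied logarithmically' sweeps."""
    return np.logspace(np.log10(lo), np.log10(hi), points)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run one configured experiment; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    outputs: list[str] = []

    def write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs.append(name)
        log.info("wrote %s (%d rows)", path, len(df))

    kind = config.kind
    fixed = {"a": config.a, "p": config.p, "rho": config.rho, "K": config.K}

    if kind == "simulate":
        rows, finals = [], []
        for rep in range(config.n):
            traj = simulate_replicate(
                config.N, config.K, config.a, config.p, config.rho,
                replicate_seed(config.seed, 0, rep), link_prob=config.link_prob,
            )
            rows += [{"replicate": rep, "t": t, "R": R} for t, R in enumerate(traj.R)]
            finals.append({"replicate": rep, "r_star": traj.r_star})
            log.debug("replicate %d: t_max=%d r*=%.4f", rep, traj.t_max, traj.r_star)
        write(pd.DataFrame(rows), "trajectories.csv")
        write(pd.DataFrame(finals), "final_shares.csv")

    elif kind == "threshold-dist":
        curve = analytic_curve(config.K, config.rho, grid_points=config.grid_points
                               if config.grid_points <= 2001 else 201, method=config.method)
        df = pd.DataFrame({"r": curve.r, "F": curve.F})
        df["method"], df["K"], df["rho"] = curve.method, config.K, config.rho
        write(df, "threshold_dist.csv")

    elif kind == "fixedpoints":
        fps = fixed_points_analytic(config.a, config.p, config.rho, config.K,
                                    grid_points=config.grid_points)
        write(
            pd.DataFrame(
                [{"r_star": r, "stability": s} for r, s in fps.points]
            ),
            "fixedpoints.csv",
        )

    elif kind == "bifurcation":
        diagram = bifurcation_diagram(
            config.scan_param, (config.scan_from, config.scan_to), fixed,
            steps=config.scan_steps,
        )
        write(diagram.branches, "bifurcation.csv")
        (out / "folds.json").write_text(json.dumps({"folds": diagram.folds}, indent=2))
        outputs.append("folds.json")

    elif kind == "hysteresis":
        loop = hysteresis_loop(
            config.scan_param, (config.scan_from, config.scan_to),
            fixed_params=fixed, steps=config.scan_steps,
        )
        write(loop.up.assign(direction="up"), "hysteresis_up.csv")
        write(loop.down.assign(direction="down"), "hysteresis_down.csv")
        (out / "loop.json").write_text(json.dumps({"loop_area": loop.loop_area}, indent=2))
        outputs.append("loop.json")

    elif kind == "figure2":
        a_grid = _log_a_grid(config.a_points, hi=config.p)
        sweep = sweep_final_share(
            config.N, config.K, config.rho_values, a_grid, [config.p],
            n=config.n, seed=config.seed,
        )
        write(sweep.runs, "sweep_runs.csv")
        write(sweep.summary, "sweep_summary.csv")

    elif kind == "figure3":
        scatter_rows = []
        for ci, rho in enumerate(config.rho_values):
            curve = analytic_curve(config.K, rho, method=config.method)
            df = pd.DataFrame({"r": curve.r, "F": curve.F})
            df["rho"] = rho
            write(df, f"analytic_rho{rho}.csv")
            a_grid = _log_a_grid(10, hi=config.p)
            for cj, a in enumerate(a_grid):
                for rep in range(max(1, config.n // 50)):
                    traj = simulate_replicate(
                        config.N, config.K, a, config.p, rho,
                        replicate_seed(config.seed, ci * 1000 + cj, rep),
                    )
                    part = PopulationPartition.from_fractions(config.N, a, config.p)
                    if part.C == 0 or traj.t_max < 1:
                        continue
                    emp = empirical_threshold_curve(traj, part)
                    for r_t, F_t in zip(emp.r, emp.F):
                        scatter_rows.append(
                            {"rho": rho, "a": a, "replicate": rep, "r": r_t, "F_emp": F_t}
                        )
        write(pd.DataFrame(scatter_rows), "empirical_scatter.csv")

    elif kind == "figure4":
        a_grid = np.linspace(0.0, 0.5, 51)
        p_grid = np.linspace(0.0, 1.0, 51)
        surface = min_stable_surface(a_grid, p_grid, config.rho, config.K,
                                     grid_points=2_001)
        rows = [
            {"a": a, "p": p, "min_r_star": surface[i, j]}
            for i, p in enumerate(p_grid)
            for j, a in enumerate(a_grid)
        ]
        write(pd.DataFrame(rows), "min_stable_surface.csv")

    manifest = {
        "config": config.to_dict(),
        "master_seed": config.seed,
        "version": __version__,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
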