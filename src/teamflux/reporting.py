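"""Run manifests and tidy on-disk reports for trajectories and sweeps."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .engine import Trajectory
from .sensitivity import SweepResult, classify_zones, extinction_time, SECRETION_TOL

__all__ = ["build_manifest", "write_trajectory_report", "write_sweep_report"]

SOLVER_ID = "scipy.optimize.linprog (HiGHS)"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def build_manifest(
    config, input_paths: Mapping[str, str | Path] | None = None,
    statuses: list[str] | None = None, wall_clock_s: float | None = None,
) -> dict:
    """Everything needed to re-run the identical computation, as plain JSON."""
    checksums = {}
    for name, p in (input_paths or {}).items():
        p = Path(p)
        if p.is_dir():
            checksums[name] = {f.name: _sha256(f) for f in sorted(p.iterdir()) if f.is_file()}
        elif p.exists():
            checksums[name] = _sha256(p)
    return {
        "software": {"name": "teamflux", "version": __version__},
        "solver": SOLVER_ID,
        "config": {k: v for k, v in config.__dict__.items()},
        "input_checksums": checksums,
        "step_statuses": statuses or [],
        "wall_clock_s": wall_clock_s,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def write_trajectory_report(
    traj: Trajectory, out_dir: str | Path,
    input_paths: Mapping[str, str | Path] | None = None,
    wall_clock_s: float | None = None,
) -> None:
    """Write concentrations/fluxes/penalties TSVs, a manifest and a summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj.concentrations_frame().to_csv(out / "concentrations.tsv", sep="\t", index=False)
    traj.fluxes_frame().to_csv(out / "fluxes.tsv", sep="\t", index=False)
    pen_rows = [(s.t, rid, s.penalties.c[j])
                for s in traj.steps for j, rid in enumerate(traj.model.reaction_ids)]
    pd.DataFrame(pen_rows, columns=["time", "reaction", "penalty"]).to_csv(
        out / "penalties.tsv", sep="\t", index=False)
    statuses = [s.status for s in traj.steps]
    manifest = build_manifest(traj.config, input_paths, statuses, wall_clock_s)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    lines = ["# Run summary", ""]
    model, media0 = traj.model, traj.states[0].e if traj.states else None
    if traj.steps:
        lines.append(f"- steps: {len(traj.steps)} (dt={traj.config.dt} hr), "
                     f"relaxed: {statuses.count('relaxed')}")
        lines.append(f"- final biomass: {traj.states[-1].BM:.4f} gDW")
        secreted, nutrients = [], []
        for j in sorted(model.exchange_set):
            mid = model.exchange_metabolite[j]
            if mid in traj.config.clamped_metabolites:
                continue
            series = traj.concentration_series(mid)
            if series[0] > 0:
                ext = extinction_time(traj, mid)
                nutrients.append(f"  - {mid}: initial {series[0]:.3g} mM, "
                                 f"extinct at {'never' if ext is None else f'{ext:g} hr'}")
            elif series.max() > SECRETION_TOL:
                secreted.append(f"  - {mid}: peak {series.max():.3g} mM, "
                                f"final {series[-1]:.3g} mM")
        lines += ["- nutrients:"] + (nutrients or ["  - none"])
        lines += ["- secreted intermediates:"] + (secreted or ["  - none"])
    else:
        lines.append("- empty trajectory (t_end = 0)")
    (out / "summary.md").write_text("\n".join(lines) + "\n")


def write_sweep_report(
    sweep: SweepResult, out_dir: str | Path, config=None,
    input_paths: Mapping[str, str | Path] | None = None,
    wall_clock_s: float | None = None,
) -> None:
    """Write the theta x summary table, a heatmap-ready long table and zones."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = sweep.to_frame()
    frame.to_csv(out / "sweep.tsv", sep="\t", index=False)
    long_rows = [(r.theta, m, v) for r in sweep.records for m, v in r.secreted.items()]
    pd.DataFrame(long_rows, columns=["theta", "metabolite", "total_concentration"]
                 ).to_csv(out / "sweep_long.tsv", sep="\t", index=False)
    zones = classify_zones(sweep)
    lines = ["# Sweep summary", "", f"- threshold type: {sweep.threshold_type}",
             f"- thetas: {len(sweep.records)}, failures: "
             f"{sum(r.error is not None for r in sweep.records)}", "", "## Zones", ""]
    for z in zones:
        label = ", ".join(sorted(z.secretion_set)) or "(nothing secreted)"
        lines.append(f"- theta {z.theta_start:g}..{z.theta_end:g}: {label}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    if config is not None:
        manifest = build_manifest(config, input_paths, wall_clock_s=wall_clock_s)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
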