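"""Threshold-percentile sensitivity sweep and trajectory summaries.

Sweeping the penalty percentile theta over its full range and summarizing
each trajectory (which intermediates were secreted, when nutrients ran out,
how well tracked metabolites match observations) exposes contiguous *zones*
of qualitatively distinct behavior; matching zone signatures against
observations is how a defensible theta range is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    SimulationConfig,
    Trajectory,
    _step_bounds,
    initialize_state,
    run_team,
    solve_max_biomass,
    solve_min_inconsistency,
    solve_min_total_flux,
)
from .expression import (
    ExpressionCompendium,
    ExpressionTimeSeries,
    compute_gene_penalties,
    compute_thresholds,
    propagate_reaction_penalties,
)
from .model import StoichiometricModel

__all__ = [
    "SweepResult",
    "sweep_thresholds",
    "total_secreted_carbon",
    "extinction_time",
    "classify_zones",
    "prediction_rss",
    "inconsistency_score",
    "single_step_inconsistency",
    "compare_threshold_types",
    "SECRETION_TOL",
    "EXTINCTION_TOL",
]

logger = logging.getLogger(__name__)

SECRETION_TOL = 1e-6  # mM; a metabolite counts as secreted above this
EXTINCTION_TOL = 1e-6  # mM; a nutrient counts as exhausted below this


def total_secreted_carbon(
    traj: Trajectory,
    metabolite_id: str,
    carbon_weighted: bool = False,
) -> float:
    """Sum of a metabolite's media concentration over all grid timepoints.

    Intended for secreted intermediates (initial concentration 0), matching
    the heatmap summary of the sweep. ``carbon_weighted`` multiplies by the
    metabolite's carbon count when the model carries one.
    """
    model = traj.model
    try:
        model.exchange_for(metabolite_id)
    except KeyError:
        raise ValueError(f"metabolite {metabolite_id!r} has no exchange reaction")
    total = float(traj.concentration_series(metabolite_id).sum())
    if carbon_weighted:
        total *= model.carbon_counts.get(metabolite_id, 1)
    return total


def extinction_time(
    traj: Trajectory, nutrient_id: str, tol: float = EXTINCTION_TOL
) -> float | None:
    """First grid time at which the nutrient pool is <= tol; None if never."""
    series = traj.concentration_series(nutrient_id)
    if series[0] <= tol:
        raise ValueError(f"{nutrient_id!r} not present in the initial media")
    hits = np.nonzero(series <= tol)[0]
    return float(traj.times[hits[0]]) if hits.size else None


def prediction_rss(traj: Trajectory, observed, metabolite_id: str) -> float:
    """Residual sum of squares between predicted and observed concentrations.

    ``observed`` is a pandas Series (index = times) or (times, values) pair;
    it must cover the simulation grid and is linearly interpolated onto it.
    """
    from .expression import interpolate_timeseries

    if isinstance(observed, pd.Series):
        times, values = np.asarray(observed.index, float), observed.to_numpy(float)
    else:
        times, values = (np.asarray(x, float) for x in observed)
    obs = interpolate_timeseries(times, values, traj.times)
    pred = traj.concentration_series(metabolite_id)
    return float(np.sum((pred - obs) ** 2))


def inconsistency_score(inconsistency: float, p_g: Mapping[str, float]) -> float:
    """Total penalty of a flux solution normalized by the mean gene penalty.

    Defined as 0 whenever the numerator is 0 (no penalized flux); with a zero
    mean penalty the numerator is necessarily 0 because every reaction
    penalty derives from the gene penalties.
    """
    if inconsistency <= 0.0:
        return 0.0
    mean_p = float(np.mean(list(p_g.values()))) if p_g else 0.0
    if mean_p <= 0.0:
        raise ValueError("nonzero inconsistency with zero mean gene penalty")
    return inconsistency / mean_p


@dataclass
class SweepRecord:
    theta: float
    secreted: dict[str, float]  # metabolite -> summed concentration
    extinction: dict[str, float | None]  # nutrient -> hours or None
    rss: dict[str, float]
    inconsistency_total: float  # sum over steps of stage-2 inconsistency
    is_total: float  # sum over steps of normalized inconsistency score
    secretion_set: frozenset[str] = field(default_factory=frozenset)
    error: str | None = None


@dataclass
class SweepResult:
    threshold_type: int
    records: list[SweepRecord]

    @property
    def theta_grid(self) -> np.ndarray:
        return np.array([r.theta for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {"theta": r.theta, "type": self.threshold_type,
                         "inconsistency_total": r.inconsistency_total,
                         "is_total": r.is_total,
                         "secretion_set": "|".join(sorted(r.secretion_set)),
                         "error": r.error or ""}
            for m, v in r.secreted.items():
                row[f"secreted_{m}"] = v
            for m, v in r.extinction.items():
                row[f"extinction_{m}"] = np.nan if v is None else v
            for m, v in r.rss.items():
                row[f"rss_{m}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _trajectory_summary(
    traj: Trajectory,
    theta: float,
    secretion_candidates: Sequence[str],
    nutrients: Sequence[str],
    observed: Mapping[str, object] | None,
    tol: float,
) -> SweepRecord:
    secreted = {m: total_secreted_carbon(traj, m) for m in secretion_candidates}
    extinct = {m: extinction_time(traj, m, tol) for m in nutrients}
    rss = {m: prediction_rss(traj, obs, m) for m, obs in (observed or {}).items()}
    inc_total = sum(s.solution.inconsistency for s in traj.steps)
    is_total = sum(
        inconsistency_score(s.solution.inconsistency, s.penalties.p_g) for s in traj.steps
    )
    return SweepRecord(
        theta=theta, secreted=secreted, extinction=extinct, rss=rss,
        inconsistency_total=inc_total, is_total=is_total,
        secretion_set=frozenset(m for m, v in secreted.items() if v > tol),
    )


def sweep_thresholds(
    model: StoichiometricModel,
    expression_ts: ExpressionTimeSeries,
    compendium: ExpressionCompendium,
    od_series,
    media: Mapping[str, float],
    config: SimulationConfig,
    theta_grid: Sequence[float] | None = None,
    threshold_type: int | None = None,
    secretion_candidates: Sequence[str] | None = None,
    nutrients: Sequence[str] | None = None,
    observed: Mapping[str, object] | None = None,
    tol: float = SECRETION_TOL,
) -> SweepResult:
    """Run the penalized simulation once per theta and summarize each run.

    Per-theta results are mutually independent (the sweep is embarrassingly
    parallel); individual failures are recorded without aborting the sweep.
    Secretion candidates default to exchangeable metabolites with zero initial
    concentration (excluding clamps); nutrients default to media metabolites
    with positive initial concentration (excluding clamps).
    """
    theta_grid = np.arange(1.0, 100.0) if theta_grid is None else np.asarray(theta_grid, float)
    ttype = config.threshold_type if threshold_type is None else threshold_type
    exchangeable = [model.exchange_metabolite[j] for j in sorted(model.exchange_set)]
    if secretion_candidates is None:
        secretion_candidates = [
            m for m in exchangeable
            if media.get(m, 0.0) == 0.0 and m not in config.clamped_metabolites
        ]
    if nutrients is None:
        nutrients = [
            m for m in exchangeable
            if media.get(m, 0.0) > 0.0 and m not in config.clamped_metabolites
        ]
    records = []
    for theta in theta_grid:
        cfg = SimulationConfig(**{**config.__dict__, "theta": float(theta),
                                  "threshold_type": ttype})
        try:
            traj = run_team(model, expression_ts, compendium, od_series, media, cfg)
            records.append(_trajectory_summary(
                traj, float(theta), secretion_candidates, nutrients, observed, tol))
        except Exception as exc:  # record, keep sweeping
            logger.warning("theta=%.1f failed: %s", theta, exc)
            records.append(SweepRecord(
                theta=float(theta), secreted={}, extinction={}, rss={},
                inconsistency_total=np.nan, is_total=np.nan, error=str(exc)))
    return SweepResult(threshold_type=ttype, records=records)


@dataclass
class Zone:
    """A maximal contiguous theta interval sharing one secretion signature."""

    theta_start: float
    theta_end: float
    secretion_set: frozenset[str]


def classify_zones(sweep: SweepResult) -> list[Zone]:
    """Group the theta grid into maximal contiguous runs of equal secretion sets."""
    zones: list[Zone] = []
    for r in sweep.records:
        if r.error is not None:
            continue
        if zones and zones[-1].secretion_set == r.secretion_set:
            zones[-1].theta_end = r.theta
        else:
            zones.append(Zone(r.theta, r.theta, r.secretion_set))
    return zones


# ---------------------------------------------------------------------------
# Single-iteration threshold-type comparison (validation-style readout)
# ---------------------------------------------------------------------------

def single_step_inconsistency(
    model: StoichiometricModel,
    compendium: ExpressionCompendium,
    expr_t: Mapping[str, float],
    media: Mapping[str, float],
    config: SimulationConfig,
    theta: float,
    threshold_type: int,
    od0: float = 1.0,
) -> float:
    """Normalized inconsistency score of one penalized iteration.

    The biomass floor is ``rmf_fraction`` x the FBA growth optimum (the mode
    used when no growth curve is available); the returned score is the stage-1
    optimum normalized by the mean gene penalty.
    """
    spec = compute_thresholds(compendium, threshold_type, theta)
    genes = sorted(model.genes())
    p_g = compute_gene_penalties(expr_t, spec, genes=genes)
    pen = propagate_reaction_penalties(p_g, model)
    state = initialize_state(media, od0, config, model)
    lb, ub = _step_bounds(state, model, config)
    vbm_max = solve_max_biomass(model, lb, ub)
    if vbm_max is None:
        raise RuntimeError("FBA biomass probe infeasible")
    lb[model.biomass_reaction] = max(lb[model.biomass_reaction],
                                     config.rmf_fraction * max(vbm_max, 0.0))
    stage1 = solve_min_inconsistency(model, lb, ub, pen.c)
    if stage1 is None:
        raise RuntimeError("single-step LP infeasible")
    stage2 = solve_min_total_flux(model, lb, ub, pen.c, stage1.inconsistency, config)
    return inconsistency_score(stage2.inconsistency, p_g)


def compare_threshold_types(
    model: StoichiometricModel,
    compendium: ExpressionCompendium,
    expr_t: Mapping[str, float],
    media: Mapping[str, float],
    config: SimulationConfig,
    theta_grid: Sequence[float] | None = None,
    types: Sequence[int] = (1, 2),
    od0: float = 1.0,
) -> pd.DataFrame:
    """Normalized inconsistency per theta for each thresholding type.

    Returns a tidy frame (theta, type, is_score) for comparing global vs
    gene-specific thresholds on a single penalized iteration.
    """
    theta_grid = np.arange(1.0, 100.0) if theta_grid is None else np.asarray(theta_grid, float)
    rows = []
    for ttype in types:
        for theta in theta_grid:
            score = single_step_inconsistency(
                model, compendium, expr_t, media, config, float(theta), ttype, od0)
            rows.append({"theta": float(theta), "type": ttype, "is_score": score})
    return pd.DataFrame(rows)
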