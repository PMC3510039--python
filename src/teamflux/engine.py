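"""The dynamic simulation loop: expression-penalized dFBA and a plain baseline.

Each time step solves two LPs over the flux vector V (S·V = 0, lb <= V <= ub):

1. minimize the *inconsistency* sum_i c_i |V_i| between flux and expression,
   where c_i is the reaction penalty propagated from gene penalties; a lower
   bound on the biomass flux (the required metabolic functionality, RMF,
   derived from the observed OD curve) makes the trivial V = 0 infeasible;
2. among the alternate optima of step 1, minimize the total flux sum_i |V_i|
   while locking the stage-1 objective.

The resulting exchange fluxes then advance the extracellular metabolite pools
and the biomass by an explicit Euler step of length dt, and the loop repeats.
Absolute values are linearized by splitting every flux into nonnegative
forward and reverse components.

Units: extracellular concentrations e_i in mM with a fixed working volume in
liters; specific bounds (mmol/gDW/hr) on biological reactions are scaled by
the current biomass to total fluxes (mmol/hr); exchange bounds are total
fluxes already. The biomass flux V_BM is in gDW/hr on the OD scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, hstack as sphstack

from .expression import (
    ExpressionCompendium,
    ExpressionTimeSeries,
    PenaltyVector,
    ThresholdSpec,
    compute_gene_penalties,
    compute_thresholds,
    interpolate_timeseries,
    propagate_reaction_penalties,
)
from .model import StoichiometricModel

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "FluxSolution",
    "StepRecord",
    "Trajectory",
    "InfeasibleStepError",
    "initialize_state",
    "media_exchange_bounds",
    "scale_bounds_to_total",
    "biomass_rmf_bound",
    "solve_min_inconsistency",
    "solve_min_total_flux",
    "solve_max_biomass",
    "update_state",
    "run_team",
    "run_dfba",
]

logger = logging.getLogger(__name__)


class InfeasibleStepError(RuntimeError):
    """A step's LP was infeasible and relaxation was disabled or also failed."""

    def __init__(self, msg: str, trajectory: "Trajectory | None" = None):
        super().__init__(msg)
        self.trajectory = trajectory


@dataclass
class SimulationConfig:
    """All knobs of a dynamic run.

    ``death_rate`` d (1/hr) enters the biomass RMF lower bound
    (lb_BM = dOD/dt + d·BM) and, when ``death_in_update`` is true, the biomass
    Euler update (BM += V_BM·dt − d·BM·dt). ``clamped_metabolites`` are held at
    a fixed concentration: mode "reset" restores the concentration after every
    update (a chemostat-like supply), mode "bound" only fixes the uptake bound.
    ``rmf_mode`` selects how the biomass floor is set: "od_derived" from the
    observed growth curve, or "fraction_of_max" as ``rmf_fraction`` times the
    step's FBA biomass optimum.
    """

    dt: float = 1.0  # hours
    t_end: float = 50.0  # hours
    death_rate: float = 0.06  # 1/hr
    working_volume: float = 1.0  # liters
    clamped_metabolites: dict[str, float] = field(default_factory=dict)
    clamp_mode: str = "reset"  # "reset" | "bound"
    rmf_mode: str = "od_derived"  # "od_derived" | "fraction_of_max"
    rmf_fraction: float = 0.5
    threshold_type: int = 2
    theta: float = 70.0
    od_scale: float = 1.0  # gDW per OD unit
    death_in_update: bool = True
    infeasible_rmf: str = "relax"  # "relax" | "error"
    solver_tolerance: float = 1e-9
    epsilon_lock: float = 1e-9  # relative + absolute slack on the stage-1 lock

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be nonnegative")
        if self.working_volume <= 0:
            raise ValueError("working_volume must be positive")
        if not 0 < self.rmf_fraction <= 1:
            raise ValueError("rmf_fraction must be in (0, 1]")


@dataclass
class SimulationState:
    """Concentrations (mM), biomass (gDW, OD-scaled) and time (hr)."""

    t: float
    e: np.ndarray  # per model metabolite, mM
    BM: float

    def __post_init__(self):
        self.e = np.asarray(self.e, dtype=float)
        if self.BM <= 0:
            raise ValueError("biomass must be positive")
        if np.any(self.e < 0):
            raise ValueError("concentrations must be nonnegative")

    def concentration(self, model: StoichiometricModel, metabolite_id: str) -> float:
        return float(self.e[model.metabolite_index(metabolite_id)])


@dataclass
class FluxSolution:
    """One LP solution: fluxes (mmol/hr) plus the two objective readouts."""

    V: np.ndarray
    inconsistency: float  # sum_i c_i |V_i|
    total_flux: float  # sum_i |V_i|
    status: str  # "optimal" | "relaxed"


@dataclass
class StepRecord:
    t: float
    solution: FluxSolution  # stage-2 (reported) solution
    penalties: PenaltyVector
    stage1_inconsistency: float
    stage1_total_flux: float
    lb: np.ndarray
    ub: np.ndarray
    floored_metabolites: tuple[str, ...]
    status: str


@dataclass
class Trajectory:
    """States on the grid 0, dt, ..., t_end plus one step record per interval."""

    model: StoichiometricModel
    config: SimulationConfig
    states: list[SimulationState]
    steps: list[StepRecord]

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def concentration_series(self, metabolite_id: str) -> np.ndarray:
        i = self.model.metabolite_index(metabolite_id)
        return np.array([s.e[i] for s in self.states])

    def biomass_series(self) -> np.ndarray:
        return np.array([s.BM for s in self.states])

    def exchange_flux_series(self, metabolite_id: str) -> np.ndarray:
        j = self.model.exchange_for(metabolite_id)
        return np.array([st.solution.V[j] for st in self.steps])

    def concentrations_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.states:
            for i, mid in enumerate(self.model.metabolite_ids):
                rows.append((s.t, mid, s.e[i]))
            rows.append((s.t, "__biomass__", s.BM))
        return pd.DataFrame(rows, columns=["time", "metabolite", "concentration"])

    def fluxes_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.steps:
            for j, rid in enumerate(self.model.reaction_ids):
                rows.append((st.t, rid, st.solution.V[j], st.penalties.c[j]))
        return pd.DataFrame(rows, columns=["time", "reaction", "flux", "penalty"])


# ---------------------------------------------------------------------------
# Per-step bound construction
# ---------------------------------------------------------------------------

def initialize_state(
    media: Mapping[str, float],
    od0: float,
    config: SimulationConfig,
    model: StoichiometricModel,
) -> SimulationState:
    """Initial state: concentrations from the media table, BM(0) = OD(0).

    Metabolites absent from ``media`` start at 0; clamped metabolites are set
    to their clamp value; unknown metabolite ids are an error.
    """
    if od0 <= 0:
        raise ValueError("initial OD must be positive")
    e = np.zeros(model.n_metabolites)
    for mid, conc in media.items():
        if mid not in model.metabolite_ids:
            raise KeyError(f"media metabolite {mid!r} not in model")
        if conc < 0:
            raise ValueError(f"negative media concentration for {mid!r}")
        e[model.metabolite_index(mid)] = conc
    for mid, conc in config.clamped_metabolites.items():
        if mid not in model.metabolite_ids:
            raise KeyError(f"clamped metabolite {mid!r} not in model")
        e[model.metabolite_index(mid)] = conc
    return SimulationState(t=0.0, e=e, BM=od0 * config.od_scale)


def media_exchange_bounds(
    state: SimulationState, model: StoichiometricModel, config: SimulationConfig
) -> dict[int, float]:
    """Lower bounds on exchange fluxes: uptake can at most drain the pool in dt.

    lb_j = max(lb0_j, -e_i · volume / dt) for the exchange of metabolite i;
    clamped metabolites use the clamp concentration.
    """
    out: dict[int, float] = {}
    for j in model.exchange_set:
        mid = model.exchange_metabolite[j]
        conc = config.clamped_metabolites.get(mid, state.e[model.metabolite_index(mid)])
        out[j] = max(model.lb0[j], -conc * config.working_volume / config.dt)
    return out


def scale_bounds_to_total(
    lb0: np.ndarray, ub0: np.ndarray, BM: float
) -> tuple[np.ndarray, np.ndarray]:
    """Specific (mmol/gDW/hr) -> total (mmol/hr) bounds at biomass ``BM``."""
    if BM <= 0:
        raise ValueError("biomass must be positive")
    return lb0 * BM, ub0 * BM


def biomass_rmf_bound(
    od_times: Sequence[float],
    od_values: Sequence[float],
    t: float,
    BM: float,
    config: SimulationConfig,
) -> float:
    """OD-derived lower bound on the biomass flux over [t, t+dt].

    lb_BM = (OD(t+dt) - OD(t)) / dt + d · BM(t), floored at 0: the culture must
    produce at least its observed net growth plus replacement of death losses.
    """
    od_times = np.asarray(od_times, dtype=float)
    od_values = np.asarray(od_values, dtype=float)
    grid = np.array([t, t + config.dt])
    od = interpolate_timeseries(od_times, od_values * config.od_scale, grid)
    return max(0.0, (od[1] - od[0]) / config.dt + config.death_rate * BM)


def _step_bounds(
    state: SimulationState, model: StoichiometricModel, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    lb, ub = scale_bounds_to_total(model.lb0, model.ub0, state.BM)
    exch = media_exchange_bounds(state, model, config)
    for j, val in exch.items():
        lb[j] = val
        ub[j] = model.ub0[j]  # exchange bounds are total units, unscaled
    return lb, ub


# ---------------------------------------------------------------------------
# LP core (forward/reverse flux splitting)
# ---------------------------------------------------------------------------

def _split_bounds(lb: np.ndarray, ub: np.ndarray) -> list[tuple[float, float]]:
    fwd = [(max(l, 0.0), max(u, 0.0)) for l, u in zip(lb, ub)]
    rev = [(max(-u, 0.0), max(-l, 0.0)) for l, u in zip(lb, ub)]
    return fwd + rev


def _solve_split_lp(
    model: StoichiometricModel,
    lb: np.ndarray,
    ub: np.ndarray,
    objective: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> np.ndarray | None:
    """Solve min objective·[f; r] s.t. S·(f − r) = 0, bounds, optional A_ub.

    Returns V = f − r, or None if infeasible.
    """
    n = model.n_reactions
    S = csr_matrix(model.S)
    A_eq = sphstack([S, -S], format="csr")
    res = linprog(
        objective,
        A_eq=A_eq,
        b_eq=np.zeros(model.n_metabolites),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=_split_bounds(lb, ub),
        method="highs",
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    x = res.x
    return x[:n] - x[n:]


def _score(V: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    absV = np.abs(V)
    return float(c @ absV), float(absV.sum())


def solve_min_inconsistency(
    model: StoichiometricModel, lb: np.ndarray, ub: np.ndarray, c: np.ndarray
) -> FluxSolution | None:
    """Stage 1: minimize sum_i c_i |V_i|; None if the bounds are infeasible."""
    if np.any(np.asarray(c) < 0):
        raise ValueError("reaction penalties must be nonnegative")
    obj = np.concatenate([c, c]).astype(float)
    V = _solve_split_lp(model, lb, ub, obj)
    if V is None:
        return None
    inc, tot = _score(V, c)
    return FluxSolution(V=V, inconsistency=inc, total_flux=tot, status="optimal")


def solve_min_total_flux(
    model: StoichiometricModel,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    inconsistency_star: float,
    config: SimulationConfig | None = None,
) -> FluxSolution:
    """Stage 2: minimize sum_i |V_i| with the stage-1 optimum locked.

    The lock is sum_i c_i |V_i| <= inconsistency_star + epsilon (relative +
    absolute), which is what makes the parsimonious solution unique-ish among
    the stage-1 alternate optima.
    """
    eps = (config.epsilon_lock if config else 1e-9)
    lock = inconsistency_star + eps + eps * abs(inconsistency_star)
    n = model.n_reactions
    A_ub = np.concatenate([c, c]).astype(float).reshape(1, 2 * n)
    V = _solve_split_lp(model, lb, ub, np.ones(2 * n), A_ub=A_ub, b_ub=np.array([lock]))
    if V is None:
        raise RuntimeError("stage-2 LP infeasible although stage 1 solved")
    inc, tot = _score(V, c)
    return FluxSolution(V=V, inconsistency=inc, total_flux=tot, status="optimal")


def solve_max_biomass(
    model: StoichiometricModel, lb: np.ndarray, ub: np.ndarray
) -> float | None:
    """Plain FBA: maximum achievable biomass flux; None if infeasible."""
    n = model.n_reactions
    obj = np.zeros(2 * n)
    obj[model.biomass_reaction] = -1.0
    obj[n + model.biomass_reaction] = +1.0
    V = _solve_split_lp(model, lb, ub, obj)
    if V is None:
        return None
    return float(V[model.biomass_reaction])


# ---------------------------------------------------------------------------
# State update and the run loop
# ---------------------------------------------------------------------------

def update_state(
    state: SimulationState,
    solution: FluxSolution,
    model: StoichiometricModel,
    config: SimulationConfig,
) -> tuple[SimulationState, tuple[str, ...]]:
    """Euler-advance concentrations and biomass by one dt.

    e_i += V_exch,i · dt / volume (floored at 0 with the flooring event
    reported); clamped metabolites are reset to the clamp value in "reset"
    mode; BM += V_BM · dt − d · BM · dt. Returns (new state, floored ids).
    """
    e = state.e.copy()
    floored = []
    for j in model.exchange_set:
        i = model.metabolite_index(model.exchange_metabolite[j])
        e[i] += solution.V[j] * config.dt / config.working_volume
    for i, mid in enumerate(model.metabolite_ids):
        if e[i] < 0:
            if e[i] < -1e-6:
                logger.warning("t=%.1f: %s floored from %.3g to 0", state.t, mid, e[i])
            floored.append(mid)
            e[i] = 0.0
    if config.clamp_mode == "reset":
        for mid, conc in config.clamped_metabolites.items():
            e[model.metabolite_index(mid)] = conc
    v_bm = solution.V[model.biomass_reaction]
    BM = state.BM + v_bm * config.dt
    if config.death_in_update:
        BM -= config.death_rate * state.BM * config.dt
    BM = max(BM, 1e-12)  # biomass stays positive even under pure decay
    return SimulationState(t=state.t + config.dt, e=e, BM=BM), tuple(floored)


def _time_grid(config: SimulationConfig) -> np.ndarray:
    n_steps = int(round(config.t_end / config.dt))
    return np.round(np.arange(n_steps + 1) * config.dt, 9)


def _run_loop(
    model: StoichiometricModel,
    penalty_fn: Callable[[float], PenaltyVector],
    od_series: tuple[np.ndarray, np.ndarray],
    media: Mapping[str, float],
    config: SimulationConfig,
    objective: str,
) -> Trajectory:
    """Shared dynamic loop for expression-penalized and baseline runs.

    ``objective``: "penalty" (two-stage penalty minimization with the RMF
    floor), "max_growth" (plain dFBA: maximize V_BM, then minimize total flux
    at the growth optimum).
    """
    od_times, od_values = od_series
    grid = _time_grid(config)
    if grid[-1] > od_times[-1] + 1e-9 or grid[0] < od_times[0] - 1e-9:
        raise ValueError("OD series does not cover the simulation interval")
    state = initialize_state(media, float(np.interp(0.0, od_times, od_values)), config, model)
    states = [state]
    steps: list[StepRecord] = []
    traj = Trajectory(model=model, config=config, states=states, steps=steps)
    bm = model.biomass_reaction

    for t in grid[:-1]:
        lb, ub = _step_bounds(state, model, config)
        pen = penalty_fn(t)
        status = "optimal"

        if objective == "max_growth":
            vbm_max = solve_max_biomass(model, lb, ub)
            if vbm_max is None:
                raise InfeasibleStepError(f"t={t}: dFBA step infeasible", traj)
            eps = config.epsilon_lock * (1 + abs(vbm_max))
            lb2 = lb.copy()
            lb2[bm] = max(lb[bm], vbm_max - eps)
            stage1 = FluxSolution(np.zeros(model.n_reactions), 0.0, 0.0, "optimal")
            stage2 = solve_min_total_flux(model, lb2, ub, np.zeros(model.n_reactions), 0.0, config)
            s1_inc, s1_tot = 0.0, stage2.total_flux
        else:
            if config.rmf_mode == "od_derived":
                rmf = biomass_rmf_bound(od_times, od_values, t, state.BM, config)
            else:
                vbm_max = solve_max_biomass(model, lb, ub)
                if vbm_max is None:
                    raise InfeasibleStepError(f"t={t}: FBA biomass probe infeasible", traj)
                rmf = config.rmf_fraction * max(vbm_max, 0.0)
            lb[bm] = max(lb[bm], rmf)
            stage1 = solve_min_inconsistency(model, lb, ub, pen.c)
            if stage1 is None:
                if config.infeasible_rmf == "error":
                    raise InfeasibleStepError(f"t={t}: RMF bound {rmf:.4g} infeasible", traj)
                lb_probe = lb.copy()
                lb_probe[bm] = model.lb0[bm] * state.BM
                vbm_max = solve_max_biomass(model, lb_probe, ub)
                if vbm_max is None:
                    raise InfeasibleStepError(f"t={t}: model infeasible even without RMF", traj)
                relaxed_rmf = max(0.0, vbm_max - config.epsilon_lock * (1 + abs(vbm_max)))
                logger.warning("t=%.1f: RMF %.4g infeasible, relaxed to %.4g", t, rmf, relaxed_rmf)
                lb[bm] = max(model.lb0[bm] * state.BM, relaxed_rmf)
                status = "relaxed"
                stage1 = solve_min_inconsistency(model, lb, ub, pen.c)
                if stage1 is None:
                    raise InfeasibleStepError(f"t={t}: infeasible after relaxation", traj)
            stage2 = solve_min_total_flux(model, lb, ub, pen.c, stage1.inconsistency, config)
            s1_inc, s1_tot = stage1.inconsistency, stage1.total_flux

        stage2 = replace(stage2, status=status)
        state, floored = update_state(state, stage2, model, config)
        steps.append(StepRecord(
            t=float(t), solution=stage2, penalties=pen,
            stage1_inconsistency=s1_inc, stage1_total_flux=s1_tot,
            lb=lb, ub=ub, floored_metabolites=floored, status=status,
        ))
        states.append(state)
    return traj


def _as_series(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, pd.Series):
        return np.asarray(series.index, float), np.asarray(series.values, float)
    times, values = series
    return np.asarray(times, float), np.asarray(values, float)


def run_team(
    model: StoichiometricModel,
    expression_ts: ExpressionTimeSeries,
    compendium: ExpressionCompendium,
    od_series,
    media: Mapping[str, float],
    config: SimulationConfig,
    thresholds: ThresholdSpec | None = None,
) -> Trajectory:
    """Full expression-penalized dynamic run on the grid 0, dt, ..., t_end.

    Thresholds are computed from the compendium at ``config.theta`` /
    ``config.threshold_type`` unless given explicitly; expression is
    interpolated to the simulation grid; each step builds penalties, solves
    the two-stage LP and advances the state. Deterministic for a fixed solver.
    """
    if thresholds is None:
        thresholds = compute_thresholds(compendium, config.threshold_type, config.theta)
    grid = _time_grid(config)
    genes = sorted(model.genes())
    expr = expression_ts.resample(grid) if len(grid) > 1 else expression_ts

    def penalty_fn(t: float) -> PenaltyVector:
        p_g = compute_gene_penalties(expr.at(t), thresholds, genes=genes)
        return propagate_reaction_penalties(p_g, model, time=t)

    return _run_loop(model, penalty_fn, _as_series(od_series), media, config, "penalty")


def run_dfba(
    model: StoichiometricModel,
    od_series,
    media: Mapping[str, float],
    config: SimulationConfig,
    objective: str = "max_growth",
) -> Trajectory:
    """Baseline dynamic FBA without expression inputs.

    ``objective="max_growth"``: classic dFBA (maximize V_BM, then minimize
    total flux at the optimum). ``objective="od_min_flux"``: the same loop as
    the penalized run with all penalties identically zero — the RMF floor
    tracks the OD curve and the flux distribution is the parsimonious one.
    """
    def zero_pen(t: float) -> PenaltyVector:
        return PenaltyVector(time=t, p_g={}, c=np.zeros(model.n_reactions))

    if objective == "max_growth":
        mode = "max_growth"
    elif objective == "od_min_flux":
        mode = "penalty"
    else:
        raise ValueError(f"unknown dFBA objective {objective!r}")
    return _run_loop(model, zero_pen, _as_series(od_series), media, config, mode)
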