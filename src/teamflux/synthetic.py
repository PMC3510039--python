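"""Self-contained synthetic inputs: toy overflow model, expression, OD, media.

The default scenario emulates aerobic batch growth on a lactate-limited
minimal medium by a microbe capable of overflow metabolism. A small central-
carbon skeleton (two lactate uptake routes feeding a pyruvate node, an
efficient O2-dependent respiratory branch, an inefficient fermentative branch
that releases an acetate-like intermediate, and an acetate-consuming salvage
reaction) is paired with a regulation program in which the respiratory and
salvage genes are transcriptionally repressed during the fast-growth window.
With gene-specific penalty thresholds at intermediate percentiles this makes
the penalized simulation secrete the intermediate and later re-import it,
while a growth-maximizing baseline never secretes anything -- the qualitative
overflow signature the method is designed to expose.

The expression compendium gives every gene its own stationary distribution;
means and standard deviations span more than two orders of magnitude across
genes, the regime in which a single global threshold misreads constitutively
low-expressed genes as "off" while per-gene thresholds do not.

Everything is deterministic under a fixed seed (numpy PCG64 via
``numpy.random.default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .engine import SimulationConfig
from .expression import ExpressionCompendium, ExpressionTimeSeries, build_compendium
from .model import StoichiometricModel, parse_gpr, write_model

__all__ = [
    "GeneSpec",
    "ScenarioSpec",
    "Scenario",
    "make_toy_overflow_model",
    "simulate_expression_timeseries",
    "simulate_compendium",
    "simulate_od_curve",
    "make_scenario",
    "make_random_network",
]


@dataclass(frozen=True)
class GeneSpec:
    """Stationary expression distribution and time profile of one gene.

    The time profile sits at the gene's own ``baseline_quantile`` except
    inside the optional dip window, where it drops to ``dip_quantile`` of the
    gene's distribution (quantiles on the normal approximation N(mean, sd)).
    """

    name: str
    mean: float
    sd: float
    dip_start: float | None = None
    dip_end: float | None = None
    dip_quantile: float = 0.40
    baseline_quantile: float = 0.90
    in_model: bool = True

    def level(self, t: float) -> float:
        q = self.baseline_quantile
        if self.dip_start is not None and self.dip_start <= t <= self.dip_end:
            q = self.dip_quantile
        return self.mean + self.sd * float(norm.ppf(q))


def _default_genes() -> tuple[GeneSpec, ...]:
    return (
        # lactate uptake/oxidation (complex + a constitutively low isozyme)
        GeneSpec("lldF", 20.0, 1.0),
        GeneSpec("lldG", 25.0, 1.2),
        GeneSpec("dld", 3.0, 0.15),
        # respiratory branch: repressed during the fast-growth window
        GeneSpec("sdhA", 50.0, 2.5, dip_start=10.0, dip_end=25.0),
        GeneSpec("sdhB", 55.0, 2.5),
        # fermentative overflow branch: constitutively high
        GeneSpec("pta", 80.0, 2.0),
        GeneSpec("ackA", 85.0, 2.5),
        # acetate salvage: repressed while overflow is active
        GeneSpec("acsA", 30.0, 1.5, dip_start=8.0, dip_end=30.0),
        GeneSpec("actP", 90.0, 2.0),
        GeneSpec("amtB", 70.0, 2.0),
        # measured but not in the model: stretch the pooled distribution
        GeneSpec("hypoA", 1.0, 0.05, in_model=False),
        GeneSpec("hypoB", 100.0, 6.0, in_model=False),
        GeneSpec("hypoC", 0.8, 0.2, in_model=False),
        GeneSpec("hypoD", 150.0, 10.0, in_model=False),
    )


@dataclass
class ScenarioSpec:
    """All generator parameters; fixed seed implies byte-identical outputs."""

    seed: int = 42
    genes: tuple[GeneSpec, ...] = field(default_factory=_default_genes)
    t_end: float = 50.0  # hours
    dt: float = 1.0
    n_expression_timepoints: int = 19  # arrays along the time course
    compendium_size: int = 291  # reference arrays per gene (291 + 19 = 310)
    noise_model: str = "lognormal"  # compendium sampling: "lognormal" | "normal"
    expression_noise_scale: float = 0.25  # time-course noise, in units of each gene's sd
    od0: float = 0.05
    od_lag: float = 3.0  # hours
    od_rate: float = 0.11  # 1/hr exponential growth rate
    od_plateau_time: float = 28.0  # hours
    media: dict[str, float] = field(default_factory=lambda: {
        "lacL_e": 36.0, "lacD_e": 13.0, "nh4_e": 9.0, "o2_e": 10.0,
    })
    o2_clamp: float = 10.0  # mM, reset each step
    uptake_capacity: float = 5.0  # mmol/gDW/hr per lactate route
    biomass_precursor_stoich: float = 50.0  # precursor mmol per gDW biomass
    biomass_nitrogen_stoich: float = 4.0  # ammonium mmol per gDW biomass


def make_toy_overflow_model(spec: ScenarioSpec | None = None) -> StoichiometricModel:
    """The overflow-capable toy network (14 reactions, 10 metabolites).

    Respiration yields 2 biomass precursors per pyruvate at the cost of O2;
    the overflow branch yields 1 precursor plus an acetate that can be
    secreted or, through the salvage reaction, re-assimilated.
    """
    spec = spec or ScenarioSpec()
    mets = ["lacL_e", "lacD_e", "pyr_c", "ac_c", "ac_e", "o2_e", "co2_e",
            "nh4_e", "nh4_c", "bm_pre_c"]
    carbons = {"lacL_e": 3, "lacD_e": 3, "pyr_c": 3, "ac_c": 2, "ac_e": 2,
               "co2_e": 1, "bm_pre_c": 1, "o2_e": 0, "nh4_e": 0, "nh4_c": 0}
    names = {"lacL_e": "L-lactate", "lacD_e": "D-lactate", "pyr_c": "pyruvate",
             "ac_c": "acetate (cytosol)", "ac_e": "acetate", "o2_e": "oxygen",
             "co2_e": "carbon dioxide", "nh4_e": "ammonium",
             "nh4_c": "ammonium (cytosol)", "bm_pre_c": "biomass precursor"}
    cap = spec.uptake_capacity
    # (id, {met: coeff}, lb0, ub0, gpr)
    rxns = [
        ("EX_lacL", {"lacL_e": -1}, -1000.0, 1000.0, None),
        ("EX_lacD", {"lacD_e": -1}, -1000.0, 1000.0, None),
        ("EX_ac", {"ac_e": -1}, -1000.0, 1000.0, None),
        ("EX_o2", {"o2_e": -1}, -1000.0, 0.0, None),
        ("EX_nh4", {"nh4_e": -1}, -1000.0, 0.0, None),
        ("EX_co2", {"co2_e": -1}, 0.0, 1000.0, None),
        ("LLD", {"lacL_e": -1, "pyr_c": 1}, 0.0, cap, "lldF AND lldG"),
        ("DLD", {"lacD_e": -1, "pyr_c": 1}, 0.0, cap, "dld"),
        ("TCA", {"pyr_c": -1, "o2_e": -1, "bm_pre_c": 2, "co2_e": 1},
         0.0, 1000.0, "sdhA AND sdhB"),
        ("PTA", {"pyr_c": -1, "bm_pre_c": 1, "ac_c": 1}, 0.0, 1000.0, "pta OR ackA"),
        ("ACS", {"ac_c": -1, "o2_e": -1, "bm_pre_c": 1, "co2_e": 1},
         0.0, 1000.0, "acsA"),
        ("ACT", {"ac_c": -1, "ac_e": 1}, -1000.0, 1000.0, "actP"),
        ("NT", {"nh4_e": -1, "nh4_c": 1}, 0.0, 1000.0, "amtB"),
        ("BM", {"bm_pre_c": -spec.biomass_precursor_stoich,
                "nh4_c": -spec.biomass_nitrogen_stoich}, 0.0, 1000.0, None),
    ]
    S = np.zeros((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    gpr = {}
    for j, (_, coeffs, _, _, rule) in enumerate(rxns):
        for m, c in coeffs.items():
            S[midx[m], j] = c
        if rule:
            gpr[j] = parse_gpr(rule)
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=[r[0] for r in rxns],
        S=S,
        lb0=np.array([r[2] for r in rxns]),
        ub0=np.array([r[3] for r in rxns]),
        biomass_reaction=len(rxns) - 1,
        gpr=gpr,
        metabolite_names=names,
        carbon_counts=carbons,
    )


def simulate_expression_timeseries(spec: ScenarioSpec | None = None) -> ExpressionTimeSeries:
    """Time-course arrays: per-gene profile plus seeded Gaussian noise.

    Measurement noise along the time course is ``expression_noise_scale``
    times each gene's compendium sd -- within-experiment scatter is smaller
    than cross-condition variation. Values are floored just above 0.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed + 1)
    times = np.linspace(0.0, spec.t_end, spec.n_expression_timepoints)
    values = np.empty((len(spec.genes), times.size))
    for i, g in enumerate(spec.genes):
        profile = np.array([g.level(t) for t in times])
        noise = rng.normal(0.0, spec.expression_noise_scale * g.sd, size=times.size)
        values[i] = np.maximum(profile + noise, 1e-6)
    return ExpressionTimeSeries([g.name for g in spec.genes], times, values)


def _sample_stationary(rng: np.random.Generator, g: GeneSpec, n: int, model: str) -> np.ndarray:
    if model == "normal":
        return rng.normal(g.mean, g.sd, size=n)
    if model == "lognormal":
        # match the requested mean and sd exactly
        cv2 = (g.sd / g.mean) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(g.mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_reference_frame(spec: ScenarioSpec | None = None) -> pd.DataFrame:
    """Reference arrays (genes x compendium_size), each gene from its own
    stationary distribution."""
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed + 2)
    data = {g.name: _sample_stationary(rng, g, spec.compendium_size, spec.noise_model)
            for g in spec.genes}
    frame = pd.DataFrame(data).T
    frame.columns = [f"ref{k:03d}" for k in range(spec.compendium_size)]
    return frame


def simulate_compendium(
    spec: ScenarioSpec | None = None,
    include_experiment: bool = True,
    model_genes: Sequence[str] | None = None,
) -> ExpressionCompendium:
    """Reference arrays pooled (by default) with the time-course arrays.

    Per-gene sample count is compendium_size + n_expression_timepoints when
    the experiment is included, mirroring how the per-gene CDFs are built.
    """
    spec = spec or ScenarioSpec()
    ref = simulate_reference_frame(spec)
    exp = None
    if include_experiment:
        ts = simulate_expression_timeseries(spec)
        exp = ts.to_frame()
        exp.columns = [f"t{c:g}" for c in exp.columns]
    extras = [g.name for g in spec.genes if not g.in_model]
    return build_compendium(ref, exp, model_genes=model_genes, extra_genes=extras)


def simulate_od_curve(spec: ScenarioSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Lag / exponential / plateau growth curve sampled hourly; strictly positive."""
    spec = spec or ScenarioSpec()
    times = np.round(np.arange(0.0, spec.t_end + spec.dt / 2, spec.dt), 9)
    ods = np.empty_like(times)
    for k, t in enumerate(times):
        if t <= spec.od_lag:
            ods[k] = spec.od0
        else:
            ods[k] = spec.od0 * np.exp(spec.od_rate * (min(t, spec.od_plateau_time) - spec.od_lag))
    return times, ods


@dataclass
class Scenario:
    """A mutually consistent input bundle ready for the simulation engine."""

    spec: ScenarioSpec
    model: StoichiometricModel
    expression_ts: ExpressionTimeSeries
    reference_frame: pd.DataFrame
    compendium: ExpressionCompendium
    od_series: tuple[np.ndarray, np.ndarray]
    media: dict[str, float]
    config: SimulationConfig


def make_scenario(
    spec: ScenarioSpec | None = None, out_dir: str | Path | None = None
) -> Scenario:
    """Build the default overflow scenario; optionally write it to disk.

    The on-disk layout is exactly what the command-line interface consumes:
    ``model/`` (tabular dialect), ``expression.tsv``, ``compendium.tsv``,
    ``od.tsv``, ``media.tsv`` and ``config.yaml``.
    """
    spec = spec or ScenarioSpec()
    model = make_toy_overflow_model(spec)
    ts = simulate_expression_timeseries(spec)
    ref = simulate_reference_frame(spec)
    exp_frame = ts.to_frame()
    exp_frame.columns = [f"t{c:g}" for c in exp_frame.columns]
    extras = [g.name for g in spec.genes if not g.in_model]
    comp = build_compendium(ref, exp_frame, model_genes=sorted(model.genes()),
                            extra_genes=extras)
    od = simulate_od_curve(spec)
    config = SimulationConfig(
        dt=spec.dt, t_end=spec.t_end,
        clamped_metabolites={"o2_e": spec.o2_clamp},
        threshold_type=2, theta=65.0,
    )
    scen = Scenario(spec=spec, model=model, expression_ts=ts, reference_frame=ref,
                    compendium=comp, od_series=od, media=dict(spec.media), config=config)
    if out_dir is not None:
        _write_scenario(scen, Path(out_dir))
    return scen


def _write_scenario(scen: Scenario, out: Path) -> None:
    import yaml

    out.mkdir(parents=True, exist_ok=True)
    write_model(scen.model, out / "model")
    expr = scen.expression_ts.to_frame()
    expr.index.name = "gene"
    expr.to_csv(out / "expression.tsv", sep="\t")
    ref = scen.reference_frame.copy()
    ref.index.name = "gene"
    ref.to_csv(out / "compendium.tsv", sep="\t")
    times, ods = scen.od_series
    pd.DataFrame({"time": times, "od": ods}).to_csv(out / "od.tsv", sep="\t", index=False)
    pd.DataFrame({"metabolite": list(scen.media), "mM": list(scen.media.values())}
                 ).to_csv(out / "media.tsv", sep="\t", index=False)
    cfg = {k: v for k, v in scen.config.__dict__.items()}
    cfg["paths"] = {"model": "model", "expression": "expression.tsv",
                    "compendium": "compendium.tsv", "od": "od.tsv", "media": "media.tsv"}
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


# ---------------------------------------------------------------------------
# Random small networks (round-trip and LP cross-check material)
# ---------------------------------------------------------------------------

def make_random_network(
    rng: np.random.Generator,
    n_extra_reactions: int = 3,
    chain_length: int = 3,
    forced_sink: float = 1.0,
) -> StoichiometricModel:
    """A random feasible toy network with a forced sink flux.

    A linear conversion chain m1 -> ... -> mk with an inflow exchange at the
    head and an outflow exchange (lower bound ``forced_sink`` > 0, so the
    zero flux vector is infeasible) at the tail, plus random extra
    conversions, some reversible. At most ~10 reactions; suitable for
    exhaustive sign-pattern cross-checks of the two-stage LP.
    """
    k = chain_length
    mets = [f"m{i}" for i in range(1, k + 1)]
    rxns: list[tuple[str, dict[str, float], float, float]] = [
        ("EX_in", {"m1": -1.0}, -10.0, 0.0),
        ("EX_out", {f"m{k}": -1.0}, forced_sink, 10.0),
    ]
    for i in range(1, k):
        rxns.append((f"C{i}", {f"m{i}": -1.0, f"m{i+1}": 1.0},
                     0.0, float(rng.uniform(2.0, 6.0))))
    for x in range(n_extra_reactions):
        a, b = rng.choice(k, size=2, replace=False)
        rev = bool(rng.random() < 0.5)
        ub = float(rng.uniform(1.0, 5.0))
        rxns.append((f"R{x}", {f"m{a+1}": -1.0, f"m{b+1}": 1.0},
                     -ub if rev else 0.0, ub))
    S = np.zeros((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_, coeffs, _, _) in enumerate(rxns):
        for m, c in coeffs.items():
            S[midx[m], j] = c
    return StoichiometricModel(
        metabolite_ids=mets,
        reaction_ids=[r[0] for r in rxns],
        S=S,
        lb0=np.array([r[2] for r in rxns]),
        ub0=np.array([r[3] for r in rxns]),
        biomass_reaction=2,  # first chain conversion stands in for growth
        gpr={},
    )
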