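"""Expression compendium, penalty thresholds, and gene/reaction penalties.

Gene penalties quantify the evidence, relative to a reference compendium of
expression measurements, that a gene is "off" at a given time. A percentile
theta of an empirical expression distribution defines a threshold; a gene
expressed below its threshold is penalized by the shortfall. Three threshold
flavours are supported:

* Type 1 -- one global threshold, the theta-percentile of *all* values pooled
  across genes and samples;
* Type 2 -- a per-gene threshold, the theta-percentile of that gene's own
  pooled reference + experiment samples;
* Type 3 -- as Type 2, with the shortfall additionally divided by the gene's
  sample standard deviation (a z-score-like penalty).

Reaction penalties are obtained by propagating gene penalties through GPR
Boolean rules: AND -> max, OR -> min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import StoichiometricModel, evaluate_gpr

__all__ = [
    "ExpressionCompendium",
    "ExpressionTimeSeries",
    "ThresholdSpec",
    "PenaltyVector",
    "read_expression_matrix",
    "build_compendium",
    "empirical_quantile",
    "compute_thresholds",
    "compute_gene_penalties",
    "propagate_reaction_penalties",
    "interpolate_timeseries",
]

logger = logging.getLogger(__name__)

#: Relative floor (vs the median per-gene std) applied to Type-3 stds so that
#: near-constant genes do not produce unbounded penalties.
SIGMA_FLOOR_FRACTION = 1e-3


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV/CSV (first column gene id, header samples)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


@dataclass
class ExpressionCompendium:
    """Pooled reference + experiment expression samples per gene."""

    gene_ids: list[str]
    values: np.ndarray  # genes x samples, no NaN
    source_labels: list[str]  # per sample: "reference" | "experiment"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError("compendium contains missing values after assembly")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_samples(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]


@dataclass
class ExpressionTimeSeries:
    """Genes x timepoints expression values on a (possibly irregular) grid."""

    gene_ids: list[str]
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray  # genes x timepoints
    interpolated: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time series times must be strictly increasing")

    def at(self, t: float) -> dict[str, float]:
        """Per-gene expression at time ``t`` (piecewise-linear, no extrapolation)."""
        vals = interpolate_timeseries(self.times, self.values, np.array([t]))[:, 0]
        return dict(zip(self.gene_ids, vals))

    def resample(self, grid: Sequence[float]) -> "ExpressionTimeSeries":
        grid = np.asarray(grid, dtype=float)
        return ExpressionTimeSeries(
            self.gene_ids, grid, interpolate_timeseries(self.times, self.values, grid),
            interpolated=True,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.times)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, interpolated: bool = False) -> "ExpressionTimeSeries":
        times = np.array([float(c) for c in frame.columns])
        return cls(list(frame.index), times, frame.to_numpy(float), interpolated)


def build_compendium(
    reference: pd.DataFrame | str | Path,
    experiment: pd.DataFrame | str | Path | None = None,
    model_genes: Sequence[str] | None = None,
    extra_genes: Sequence[str] = (),
) -> ExpressionCompendium:
    """Pool reference and experiment matrices column-wise into a compendium.

    Genes are restricted to those present in every contributing matrix,
    intersected with ``model_genes`` (plus ``extra_genes``) when given, so the
    per-gene sample count is uniform: n_reference + n_experiment.
    """
    if not isinstance(reference, pd.DataFrame):
        reference = read_expression_matrix(reference)
    frames = [("reference", reference)]
    if experiment is not None:
        if not isinstance(experiment, pd.DataFrame):
            experiment = read_expression_matrix(experiment)
        frames.append(("experiment", experiment))
    genes = set(frames[0][1].index)
    for _, f in frames[1:]:
        genes &= set(f.index)
    if model_genes is not None:
        genes &= set(model_genes) | set(extra_genes)
    if not genes:
        raise ValueError("empty gene intersection while assembling compendium")
    gene_ids = sorted(genes)
    blocks, labels = [], []
    for label, f in frames:
        block = f.loc[gene_ids].to_numpy(float)
        blocks.append(block)
        labels += [label] * block.shape[1]
    return ExpressionCompendium(gene_ids, np.hstack(blocks), labels)


def empirical_quantile(values: Sequence[float], theta: float) -> float:
    """Nearest-rank empirical quantile of ``values`` at percentile ``theta``.

    Convention: theta = 0 returns the minimum; otherwise the value at sorted
    (1-based) rank ``ceil(theta/100 * n)``; theta = 100 returns the maximum.
    This convention is monotone nondecreasing in theta and is used everywhere
    a threshold CDF is inverted.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empirical_quantile of empty vector")
    if not np.isfinite(v).all():
        raise ValueError("empirical_quantile requires finite values")
    if not 0.0 <= theta <= 100.0:
        raise ValueError(f"theta must be in [0, 100], got {theta}")
    if theta == 0.0:
        return float(v[0])
    rank = math.ceil(theta / 100.0 * v.size)
    return float(v[min(rank, v.size) - 1])


@dataclass
class ThresholdSpec:
    """Thresholds derived from a compendium at percentile ``theta``."""

    type: int  # 1, 2 or 3
    theta: float
    x_global: float | None = None
    x_g: dict[str, float] = field(default_factory=dict)
    sigma_g: dict[str, float] = field(default_factory=dict)

    def threshold_for(self, gene: str) -> float:
        if self.type == 1:
            return self.x_global
        return self.x_g[gene]


def compute_thresholds(comp: ExpressionCompendium, type: int, theta: float) -> ThresholdSpec:
    """Invert the empirical expression CDF(s) at percentile ``theta``.

    Type 1 pools all genes and samples into one CDF; Types 2 and 3 build one
    CDF per gene from that gene's pooled samples (Type 3 additionally records
    the per-gene standard deviation, floored at a small fraction of the median
    std so near-constant genes cannot blow up the normalized penalty).
    """
    if type not in (1, 2, 3):
        raise ValueError(f"threshold type must be 1, 2 or 3, got {type}")
    if type == 1:
        return ThresholdSpec(1, theta, x_global=empirical_quantile(comp.values.ravel(), theta))
    if type == 3 and comp.n_samples < 2:
        raise ValueError("Type 3 thresholds need >= 2 samples per gene")
    x_g = {g: empirical_quantile(comp.values[i], theta) for i, g in enumerate(comp.gene_ids)}
    spec = ThresholdSpec(type, theta, x_g=x_g)
    if type == 3:
        sig = comp.values.std(axis=1, ddof=1)
        floor = SIGMA_FLOOR_FRACTION * float(np.median(sig))
        for i, g in enumerate(comp.gene_ids):
            if sig[i] < floor:
                logger.info("sigma floor applied to gene %s (%.3g -> %.3g)", g, sig[i], floor)
            spec.sigma_g[g] = max(float(sig[i]), floor)
        if any(s <= 0 for s in spec.sigma_g.values()):
            raise ValueError("non-positive sigma after floor; compendium is degenerate")
    return spec


@dataclass
class PenaltyVector:
    """Gene penalties ``p_g`` and reaction penalties ``c`` at one time."""

    time: float
    p_g: dict[str, float]
    c: np.ndarray  # per reaction, 0 for exchanges / GPR-less reactions

    @property
    def mean_gene_penalty(self) -> float:
        return float(np.mean(list(self.p_g.values()))) if self.p_g else 0.0


def compute_gene_penalties(
    expr_t: Mapping[str, float], spec: ThresholdSpec, genes: Sequence[str] | None = None
) -> dict[str, float]:
    """Per-gene penalty at one time: ``max(0, threshold - expression)``.

    Type 3 divides the shortfall by the gene's std. Genes requested via
    ``genes`` but missing from ``expr_t`` get penalty 0 (absence of evidence
    does not block flux); this is logged once per call.
    """
    genes = list(genes) if genes is not None else list(expr_t)
    p: dict[str, float] = {}
    missing = []
    for g in genes:
        if g not in expr_t or (spec.type != 1 and g not in spec.x_g):
            missing.append(g)
            p[g] = 0.0
            continue
        shortfall = max(0.0, spec.threshold_for(g) - float(expr_t[g]))
        if spec.type == 3:
            sigma = spec.sigma_g[g]
            if sigma <= 0:
                raise RuntimeError(f"non-positive sigma for gene {g} after floor")
            shortfall /= sigma
        p[g] = shortfall
    if missing:
        logger.warning("%d gene(s) without expression/threshold data, penalty 0: %s",
                       len(missing), ", ".join(sorted(missing)[:10]))
    return p


def propagate_reaction_penalties(
    p_g: Mapping[str, float], model: StoichiometricModel, time: float = 0.0
) -> PenaltyVector:
    """Propagate gene penalties to reactions through GPR rules (AND=max, OR=min)."""
    c = np.zeros(model.n_reactions)
    for j, rule in model.gpr.items():
        if j in model.exchange_set:
            continue
        c[j] = evaluate_gpr(rule, p_g)
    return PenaltyVector(time=time, p_g=dict(p_g), c=c)


def interpolate_timeseries(
    times: Sequence[float], values: np.ndarray, grid: Sequence[float]
) -> np.ndarray:
    """Piecewise-linear resampling of row-wise series onto ``grid``.

    No extrapolation: every grid point must lie within ``[times[0], times[-1]]``.
    Values at sampled times are reproduced exactly. ``values`` may be 1-D (one
    series) or 2-D (series x time); the output matches that shape with the time
    axis replaced by the grid.
    """
    times = np.asarray(times, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if grid.size and (grid.min() < times[0] - 1e-12 or grid.max() > times[-1] + 1e-12):
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] outside sampled range [{times[0]}, {times[-1]}]"
        )
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(grid, times, values)
    return np.vstack([np.interp(grid, times, row) for row in values])
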