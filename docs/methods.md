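# Methods

## Model and assumptions

The simulation couples a quasi-steady-state metabolic model to a slowly
varying extracellular environment. Within each interval Δt the intracellular
network is assumed balanced (S·V = 0) and enzyme capacities are assumed
proportional to biomass, so specific bounds (mmol/gDW/hr) are scaled to
total fluxes (mmol/hr) by the current biomass BM. Exchange reactions are
source/sink columns touching exactly one metabolite (the declared biomass
drain is exempt from this auto-detection, and an explicit override list in
the model container wins over it); positive exchange flux is secretion.
Uptake in one step cannot exceed the pool: `lb_exch = max(lb⁰, −e·V/Δt)`
with working volume V in liters.

Expression enters only through the objective, never as a hard bound. The
penalty of gene g at time t is the shortfall of its expression below a
threshold read off an empirical CDF at percentile θ — pooled across all
genes (Type 1) or per gene (Types 2/3, with Type 3 dividing by the gene's
sample standard deviation so that the penalty is a z-score rather than an
intensity difference). The empirical CDFs pool a reference compendium with
the experiment's own time-course arrays; both inclusion of the experiment
arrays and the compendium size are configurable, since either choice is
defensible. Reaction penalties follow the GPR rules with AND → max and
OR → min. Genes present in GPRs but missing from the expression data are
treated as unpenalized (absence of evidence should not block flux) and
logged.

The trivial solution V = 0 is made infeasible by a biomass floor (the
required metabolic functionality). Two modes:

* `od_derived` (default): `lb_BM = max(0, (OD(t+Δt) − OD(t))/Δt + d·BM(t))` —
  the culture must produce its observed net growth plus replacement of death
  losses. The death rate default is d = 0.06 /hr.
* `fraction_of_max`: `lb_BM = p · max V_BM` with the maximum recomputed by
  plain FBA each step (default p = 0.5). This is the mode for data sets with
  no growth curve, and the mode used by the single-iteration threshold-type
  comparison.

The same death term is applied in the biomass Euler update
(`BM += V_BM·Δt − d·BM·Δt`); it can be switched off independently
(`death_in_update`), since whether decay acts on the state as well as on the
floor is a modeling choice rather than a constraint.

## The two-stage optimization

Stage 1 minimizes Σ cᵢ|Vᵢ|; stage 2 minimizes Σ|Vᵢ| subject to the stage-1
optimum locked within `epsilon_lock` (default 1e-9, applied relative +
absolute). Absolute values are linearized by splitting each flux into
nonnegative forward/reverse components; only reactions with lb < 0 get a
usable reverse component. Objectives are re-scored from the recomposed
V = f − r, so a forward/reverse overlap in a zero-penalty coordinate cannot
inflate the reported inconsistency. The LPs are solved with HiGHS through
`scipy.optimize.linprog`; with a fixed solver the whole trajectory is
deterministic. No tie-break is applied beyond stage 2 — degenerate vertices
(e.g. two interchangeable substrates) are accepted as the solver returns
them, and reproducibility is therefore per-solver.

If the OD-derived floor exceeds what the medium can support, the default
policy relaxes `lb_BM` to the step's FBA optimum (minus an epsilon), marks
the step `relaxed`, and continues; a hard-fail mode is available. This turns
the terminal substrate-exhaustion phase into an explicit death phase rather
than an abort.

Euler overshoot can drive a pool slightly negative in the update;
concentrations are floored at 0 and each flooring event is recorded (floored
metabolites are excluded from the exactness guarantee, which otherwise holds
to machine precision). Clamped metabolites (default: O₂ at 10 mM,
emulating a DO-controlled vessel) are reset to the set-point after every
update; a bound-only clamp mode is provided because a set-point can also be
read as a pure uptake limit.

## Numerical conventions

* Quantiles are **nearest-rank**: the value at 1-based sorted rank
  ⌈θ/100·n⌉, with θ = 0 ↦ minimum. This convention is monotone in θ, exact
  on small samples, and is used identically in the implementation and in
  every oracle.
* Type-3 stds are floored at 1e-3 × (median per-gene std) to keep
  near-constant genes from producing unbounded penalties.
* Interpolation of OD, expression and observed-concentration series onto
  the simulation grid is piecewise-linear with no extrapolation.
* `solver_tolerance` (1e-9) is the feasibility slack accepted when
  re-checking S·V = 0 and bounds.

## The baseline

`run_dfba` shares the loop. Its default objective is classic dFBA
(maximize V_BM, then minimize total flux at the growth optimum); an
`od_min_flux` objective runs the identical two-stage machinery with all
penalties ≡ 0 and the OD-derived floor, which is exactly what the penalized
run degenerates to at θ = 0 — the basis of the zero-penalty reduction check.

## What the synthetic scenario emulates — and what it does not

The generator produces the full input ensemble: a 14-reaction toy model, a
19-array expression time course over 50 h, a 291-array reference compendium
(310 samples per gene once pooled with the time course), an hourly
lag/exponential/plateau OD curve, and a lactate-limited minimal medium
(36 mM L-lactate, 13 mM D-lactate, 9 mM ammonium, O₂ clamped at 10 mM).

The toy network encodes the overflow trade-off: respiration converts
pyruvate + O₂ into 2 biomass precursors; the fermentative branch yields 1
precursor plus an acetate that can be secreted or re-assimilated (for the
same overall yield) through an O₂-dependent salvage reaction. Because the
carbon yields of "respire now" and "ferment, secrete, re-import later"
are equal, the baseline never secretes (parsimony prefers the short route),
and secretion appears only when the expression program makes the
respiratory *and* salvage genes expensive simultaneously — which is what
the regulation program does in hours 10–25 / 8–30 respectively.

Gene profiles are pinned to each gene's own distribution: baseline
expression at the gene's 90th percentile, repression dips at its 40th.
Keying levels to quantiles (rather than absolute intensities) is what makes
the θ at which a penalty switches on predictable and the zone boundaries
interpretable. Compendium means (0.8 to 150) and stds (0.05 to 10) span
more than two orders of magnitude across genes, reproducing the
heterogeneity regime in which a pooled global threshold misreads
constitutively low-expressed genes as "off" while per-gene thresholds do
not. Compendium sampling is lognormal by default (nonnegative,
right-skewed, matching the requested mean and sd exactly); a normal mode
exists for tests that need symmetric tails. Time-course noise is Gaussian
at 0.25 × each gene's compendium sd — within-experiment scatter is smaller
than cross-condition variation.

Scenario calibration (OD curve ending in a long plateau, biomass
stoichiometry of 50 precursor + 4 ammonium per gDW, uptake capacity
5 mmol/gDW/hr per lactate route) was chosen so that the carbon budget runs
out shortly before the end of the course: the plateau's maintenance demand
(d·BM) forces the secreted acetate to be fully re-imported, and the final
few steps are an explicit starvation/death phase. All defaults live in
`ScenarioSpec`; a fixed seed gives byte-identical outputs (numpy PCG64).

What passing on this scenario does **not** show: anything about real
genome-scale models (hundreds of genes, multi-subunit GPRs, maintenance
reactions), about microarray preprocessing (inputs are assumed normalized),
or about the quantitative accuracy of predicted concentrations against real
chromatography data. The scenario validates the machinery and the
qualitative phenomenology, not biological parameter values.

## Problem sizes used by the test suite and acceptance script

Simulations run 50 one-hour steps on the 14-reaction model; the θ sweep
covers 1…99 (step 1) plus a ×2-refined grid (step 0.5); oracle checks use
600 random GPR trees, 1000 random quantile vectors, 22 random ≤10-reaction
networks (sign-pattern enumeration oracle for both LP stages), and a
10,000-sample compendium for the threshold-convergence check.

## Known limitations

* Uptake kinetics are pool-exhaustion bounds, not Michaelis–Menten; there
  is no pH, temperature or byproduct-inhibition effect.
* mRNA is used as a direct proxy for catalytic capacity within each step;
  no translation/degradation delays.
* Alternate-optima degeneracy below stage 2 is solver-resolved; trajectories
  are reproducible per solver build, not across LP implementations.
* The tabular dialect stores reversibility implicitly as lb < 0; a model
  with a reversible arrow but nonnegative bounds round-trips to the
  equivalent irreversible form.
* History dependence is intrinsic: small early differences in secreted
  pools can reroute later carbon usage, so summaries should be read
  per-zone, not at a single θ.
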