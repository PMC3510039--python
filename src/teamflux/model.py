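"""Stoichiometric model container, GPR Boolean rules, and model I/O.

The model is the usual constraint-based object: a metabolites x reactions
stoichiometric matrix ``S``, per-reaction specific flux bounds (mmol/gDW/hr),
and a Boolean gene-protein-reaction (GPR) rule per catalysed reaction.
Reactions are partitioned into *exchange* reactions -- source/sink reactions
touching exactly one metabolite, with the convention that positive flux means
secretion and negative flux means uptake -- and *biological* reactions
(everything else, including transport and the biomass drain).

Two on-disk formats are supported: a plain-text tabular dialect owned by this
package (``reactions.tsv`` + ``metabolites.tsv`` + ``biomass.txt`` in one
directory, read/write) and SBML (read-only, via cobrapy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "GPRRule",
    "Gene",
    "BoolOp",
    "parse_gpr",
    "gpr_to_string",
    "gpr_genes",
    "evaluate_gpr",
    "StoichiometricModel",
    "classify_reactions",
    "validate_model",
    "ValidationReport",
    "load_model",
    "write_model",
    "ModelFormatError",
    "ModelValidationError",
]


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR Boolean expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """Leaf node of a GPR tree: a single gene identifier."""

    name: str


@dataclass(frozen=True)
class BoolOp:
    """Internal node of a GPR tree: AND (enzyme complex) or OR (isoenzymes)."""

    op: str  # "and" | "or"
    children: tuple["GPRRule", ...]


GPRRule = Union[Gene, BoolOp]

_GPR_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _GPR_TOKEN.match(text, pos)
        if m is None:  # only trailing whitespace left
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string like ``"a AND (b OR c)"`` into an expression tree.

    AND binds tighter than OR; keywords are case-insensitive; gene ids are any
    whitespace-free tokens other than parentheses and the keywords.

    Raises :class:`ModelFormatError` (with token position) on malformed input.
    """
    tokens = _tokenize_gpr(text)
    if not tokens:
        raise ModelFormatError("empty GPR expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg: str):
        raise ModelFormatError(f"GPR parse error at token {pos} in {text!r}: {msg}")

    def parse_or() -> GPRRule:
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else BoolOp("or", tuple(terms))

    def parse_and() -> GPRRule:
        nonlocal pos
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else BoolOp("and", tuple(factors))

    def parse_atom() -> GPRRule:
        nonlocal pos
        tok = peek()
        if tok is None:
            fail("unexpected end of expression")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                fail("unbalanced parentheses")
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            fail(f"unexpected {tok!r}")
        pos += 1
        return Gene(tok)

    rule = parse_or()
    if pos != len(tokens):
        fail(f"trailing tokens {tokens[pos:]!r}")
    return rule


def gpr_to_string(rule: GPRRule) -> str:
    """Render a GPR tree back to text, parenthesizing OR under AND."""
    if isinstance(rule, Gene):
        return rule.name
    sep = f" {rule.op.upper()} "
    parts = []
    for child in rule.children:
        s = gpr_to_string(child)
        # OR child under AND needs parentheses to survive re-parsing
        if rule.op == "and" and isinstance(child, BoolOp) and child.op == "or":
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_genes(rule: GPRRule) -> set[str]:
    """All gene identifiers appearing in the rule."""
    if isinstance(rule, Gene):
        return {rule.name}
    out: set[str] = set()
    for child in rule.children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(rule: GPRRule, penalties: Mapping[str, float]) -> float:
    """Propagate gene penalties through a GPR tree.

    AND takes the maximum of its children (the most-penalized complex subunit
    limits the reaction); OR takes the minimum (the least-penalized isoenzyme
    carries the flux). Genes absent from ``penalties`` contribute 0.
    """
    if isinstance(rule, Gene):
        return float(penalties.get(rule.name, 0.0))
    vals = [evaluate_gpr(c, penalties) for c in rule.children]
    return max(vals) if rule.op == "and" else min(vals)


# ---------------------------------------------------------------------------
# Stoichiometric model
# ---------------------------------------------------------------------------

@dataclass
class StoichiometricModel:
    """A validated constraint-based model.

    ``lb0``/``ub0`` are *specific* bounds (mmol/gDW/hr) for biological
    reactions; exchange reaction bounds are interpreted as total fluxes
    (mmol/hr) and are not biomass-scaled by the simulation engine.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray  # metabolites x reactions
    lb0: np.ndarray
    ub0: np.ndarray
    biomass_reaction: int
    gpr: dict[int, GPRRule] = field(default_factory=dict)
    metabolite_names: dict[str, str] = field(default_factory=dict)
    carbon_counts: dict[str, int] = field(default_factory=dict)
    exchange_override: set[str] | None = None

    exchange_set: set[int] = field(init=False)
    biological_set: set[int] = field(init=False)
    exchange_metabolite: dict[int, str] = field(init=False)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb0 = np.asarray(self.lb0, dtype=float)
        self.ub0 = np.asarray(self.ub0, dtype=float)
        self.exchange_set, self.biological_set = classify_reactions(self)
        self.exchange_metabolite = {}
        for j in self.exchange_set:
            (i,) = np.nonzero(self.S[:, j])[0]
            self.exchange_metabolite[j] = self.metabolite_ids[i]
        report = validate_model(self)
        if report.errors:
            raise ModelValidationError("; ".join(report.errors))

    # -- conveniences -------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversible(self) -> np.ndarray:
        return self.lb0 < 0

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)

    def metabolite_index(self, mid: str) -> int:
        return self.metabolite_ids.index(mid)

    def exchange_for(self, metabolite_id: str) -> int:
        """Index of the exchange reaction sourcing/sinking ``metabolite_id``."""
        for j, mid in self.exchange_metabolite.items():
            if mid == metabolite_id:
                return j
        raise KeyError(f"no exchange reaction for metabolite {metabolite_id!r}")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rule in self.gpr.values():
            out |= gpr_genes(rule)
        return out


def classify_reactions(model: StoichiometricModel) -> tuple[set[int], set[int]]:
    """Partition reactions into (exchange, biological) index sets.

    A reaction is an exchange if it touches exactly one metabolite (a pure
    source/sink), unless an explicit ``exchange_override`` id list is present,
    in which case that list wins. Positive exchange flux = secretion.
    """
    nnz = np.count_nonzero(model.S, axis=0)
    if np.any(nnz == 0) and model.S.shape[1] > 0:
        j = int(np.nonzero(nnz == 0)[0][0])
        raise ModelValidationError(
            f"reaction {model.reaction_ids[j]!r} has no nonzero stoichiometric coefficients"
        )
    if model.exchange_override is not None:
        exchange = {j for j, rid in enumerate(model.reaction_ids) if rid in model.exchange_override}
        for j in exchange:
            if nnz[j] != 1:
                raise ModelValidationError(
                    f"override exchange reaction {model.reaction_ids[j]!r} touches {nnz[j]} metabolites"
                )
    else:
        exchange = {int(j) for j in np.nonzero(nnz == 1)[0]}
        # the declared biomass drain is a biological flux by construction,
        # even when it consumes a single pooled precursor
        exchange.discard(model.biomass_reaction)
    biological = set(range(model.S.shape[1])) - exchange
    return exchange, biological


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_model(
    model: StoichiometricModel,
    expression_genes: Iterable[str] | None = None,
    check_biomass_feasibility: bool = False,
) -> ValidationReport:
    """Check structural invariants; return a report (never raises).

    Errors: bound inversions, duplicate ids, biomass outside the biological
    set. Warnings: GPR genes absent from ``expression_genes`` (if given) and a
    structurally blocked biomass reaction (no feasible positive flux with all
    exchange bounds opened), probed by a small LP when requested.
    """
    rep = ValidationReport()
    if len(set(model.reaction_ids)) != len(model.reaction_ids):
        rep.errors.append("duplicate reaction ids")
    if len(set(model.metabolite_ids)) != len(model.metabolite_ids):
        rep.errors.append("duplicate metabolite ids")
    bad = np.nonzero(model.lb0 > model.ub0)[0]
    for j in bad:
        rep.errors.append(f"lb0 > ub0 for reaction {model.reaction_ids[j]!r}")
    if not (0 <= model.biomass_reaction < model.n_reactions):
        rep.errors.append("biomass_reaction index out of range")
    elif model.biomass_reaction in model.__dict__.get("exchange_set", set()):
        rep.errors.append("biomass reaction classified as exchange")
    if expression_genes is not None:
        missing = sorted(model.genes() - set(expression_genes))
        if missing:
            rep.warnings.append(
                f"{len(missing)} GPR gene(s) absent from expression data "
                f"(treated as unpenalized): {', '.join(missing)}"
            )
    if check_biomass_feasibility and not rep.errors:
        from scipy.optimize import linprog

        lb, ub = model.lb0.copy(), model.ub0.copy()
        for j in model.exchange_set:  # open the boundary for the probe
            lb[j], ub[j] = -1000.0, 1000.0
        c = np.zeros(model.n_reactions)
        c[model.biomass_reaction] = -1.0
        res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                      bounds=list(zip(lb, ub)), method="highs")
        if not res.success or -res.fun < 1e-9:
            rep.warnings.append("biomass reaction is structurally blocked (max V_BM = 0)")
    return rep


# ---------------------------------------------------------------------------
# Tabular dialect (read/write)
# ---------------------------------------------------------------------------
#
# reactions.tsv : id <TAB> formula <TAB> lb <TAB> ub <TAB> gpr
#   formula: "2 a + b -> c", "<->" marks reversible direction arrows, an empty
#   side marks a pure source/sink, e.g. "lac_e ->" (secretion-positive sink).
# metabolites.tsv : id <TAB> name [<TAB> carbons]
# biomass.txt : single line, the biomass reaction id.

_ARROWS = ("<->", "<=>", "->", "=>")


def _parse_formula(formula: str, line: str) -> tuple[dict[str, float], bool]:
    arrow = next((a for a in _ARROWS if a in formula), None)
    if arrow is None:
        raise ModelFormatError(f"no reaction arrow in formula on line {line!r}")
    lhs, rhs = formula.split(arrow, 1)
    reversible = arrow in ("<->", "<=>")
    coeffs: dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                raise ModelFormatError(f"empty term in formula on line {line!r}")
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ModelFormatError(f"bad term {term!r} on line {line!r}")
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return coeffs, reversible


def _format_formula(coeffs: Mapping[str, float], reversible: bool) -> str:
    def side(sign):
        terms = []
        for met, c in coeffs.items():
            v = sign * c
            if v > 0:
                terms.append(met if v == 1 else f"{v:.17g} {met}")
        return " + ".join(terms)

    arrow = "<->" if reversible else "->"
    return f"{side(-1)} {arrow} {side(+1)}".strip()


def load_model(path: str | Path, format: str = "tabular", **kwargs) -> StoichiometricModel:
    """Load a model from ``path``.

    ``format="tabular"``: ``path`` is a directory holding ``reactions.tsv``,
    ``metabolites.tsv`` and ``biomass.txt``. ``format="sbml"``: ``path`` is an
    SBML file, read through cobrapy (read-only support).
    """
    if format == "tabular":
        return _load_tabular(Path(path), **kwargs)
    if format == "sbml":
        return _load_sbml(Path(path), **kwargs)
    raise ValueError(f"unknown model format {format!r}")


def _load_tabular(root: Path, exchange_override: set[str] | None = None) -> StoichiometricModel:
    rxn_path, met_path, bm_path = root / "reactions.tsv", root / "metabolites.tsv", root / "biomass.txt"
    for p in (rxn_path, met_path):
        if not p.exists():
            raise ModelFormatError(f"missing model file {p}")
    met_ids: list[str] = []
    met_names: dict[str, str] = {}
    carbons: dict[str, int] = {}
    for ln, line in enumerate(met_path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or (ln == 1 and line.split("\t")[0] == "id"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 1 or not parts[0]:
            raise ModelFormatError(f"{met_path}:{ln}: bad metabolite line")
        mid = parts[0]
        if mid in met_ids:
            raise ModelValidationError(f"{met_path}:{ln}: duplicate metabolite id {mid!r}")
        met_ids.append(mid)
        if len(parts) > 1:
            met_names[mid] = parts[1]
        if len(parts) > 2 and parts[2]:
            carbons[mid] = int(parts[2])

    rxn_ids: list[str] = []
    cols: list[dict[str, float]] = []
    lbs: list[float] = []
    ubs: list[float] = []
    gprs: dict[int, GPRRule] = {}
    for ln, line in enumerate(rxn_path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or (ln == 1 and line.split("\t")[0] == "id"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ModelFormatError(f"{rxn_path}:{ln}: expected id/formula/lb/ub[/gpr]")
        rid, formula, lb, ub = parts[0], parts[1], float(parts[2]), float(parts[3])
        if rid in rxn_ids:
            raise ModelValidationError(f"{rxn_path}:{ln}: duplicate reaction id {rid!r}")
        coeffs, _rev = _parse_formula(formula, f"{rxn_path}:{ln}")
        unknown = set(coeffs) - set(met_ids)
        if unknown:
            raise ModelFormatError(f"{rxn_path}:{ln}: unknown metabolite(s) {sorted(unknown)}")
        if len(parts) > 4 and parts[4].strip():
            gprs[len(rxn_ids)] = parse_gpr(parts[4])
        rxn_ids.append(rid)
        cols.append(coeffs)
        lbs.append(lb)
        ubs.append(ub)

    if not bm_path.exists():
        raise ModelFormatError(f"missing biomass id file {bm_path} (configuration error)")
    bm_id = bm_path.read_text().strip()
    if bm_id not in rxn_ids:
        raise ModelFormatError(f"biomass reaction {bm_id!r} not among reactions")

    S = np.zeros((len(met_ids), len(rxn_ids)))
    midx = {m: i for i, m in enumerate(met_ids)}
    for j, coeffs in enumerate(cols):
        for met, c in coeffs.items():
            S[midx[met], j] = c
    return StoichiometricModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lb0=np.array(lbs), ub0=np.array(ubs),
        biomass_reaction=rxn_ids.index(bm_id), gpr=gprs,
        metabolite_names=met_names, carbon_counts=carbons,
        exchange_override=exchange_override,
    )


def _load_sbml(path: Path, biomass_id: str | None = None) -> StoichiometricModel:
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    midx = {m: i for i, m in enumerate(met_ids)}
    lbs, ubs = [], []
    gprs: dict[int, GPRRule] = {}
    for j, r in enumerate(cm.reactions):
        for met, c in r.metabolites.items():
            S[midx[met.id], j] = c
        lbs.append(r.lower_bound)
        ubs.append(r.upper_bound)
        rule = r.gene_reaction_rule
        if rule and rule.strip():
            gprs[j] = parse_gpr(rule)
    if biomass_id is None:
        candidates = [r.id for r in cm.reactions if "biomass" in r.id.lower()]
        if cm.objective is not None:
            obj = [r.id for r in cm.reactions if r.objective_coefficient]
            candidates = obj or candidates
        if not candidates:
            raise ModelFormatError("cannot infer biomass reaction; pass biomass_id")
        biomass_id = candidates[0]
    return StoichiometricModel(
        metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
        lb0=np.array(lbs), ub0=np.array(ubs),
        biomass_reaction=rxn_ids.index(biomass_id), gpr=gprs,
    )


def write_model(model: StoichiometricModel, root: str | Path) -> None:
    """Write the tabular dialect (inverse of ``load_model(format='tabular')``)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcarbons\n")
        for mid in model.metabolite_ids:
            fh.write(f"{mid}\t{model.metabolite_names.get(mid, mid)}\t"
                     f"{model.carbon_counts.get(mid, '')}\n")
    with open(root / "reactions.tsv", "w") as fh:
        fh.write("id\tformula\tlb\tub\tgpr\n")
        for j, rid in enumerate(model.reaction_ids):
            coeffs = {model.metabolite_ids[i]: model.S[i, j]
                      for i in np.nonzero(model.S[:, j])[0]}
            formula = _format_formula(coeffs, model.lb0[j] < 0)
            gpr = gpr_to_string(model.gpr[j]) if j in model.gpr else ""
            fh.write(f"{rid}\t{formula}\t{model.lb0[j]:.17g}\t{model.ub0[j]:.17g}\t{gpr}\n")
    (root / "biomass.txt").write_text(model.reaction_ids[model.biomass_reaction] + "\n")
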