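"""Model ingestion and template construction.

Reads genome-scale metabolic models (SBML or a tabular fixture format),
builds the unit-free *template* model in which every finite flux bound is
replaced by 0 or +/-T, opens carbon-source exchanges according to the DC
(determined carbon source) or AC (all possible carbon sources) policy, and
splits reversible reactions into paired irreversible columns so that all
fluxes are nonnegative.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MetabolicModel",
    "IrreversibleTemplate",
    "read_sbml",
    "read_tabular",
    "template_bounds",
    "formula_carbon_count",
    "identify_carbon_exchanges",
    "build_template",
    "split_reversible",
    "fold_solution",
]

DEFAULT_T = 1000.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds, GPR rules and subsystem labels.

    ``S`` is the dense m x n stoichiometric matrix; ``gpr`` holds one boolean
    expression string per reaction (lowercase ``and``/``or``), empty when the
    reaction has no gene association.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gpr: list[str]
    subsystem: list[str]
    objective_reaction: str
    exchange_flags: np.ndarray
    metabolite_formulas: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.exchange_flags = np.asarray(self.exchange_flags, dtype=bool)
        m, n = self.S.shape
        if len(self.reaction_ids) != n or len(self.metabolite_ids) != m:
            raise ValueError("S shape inconsistent with id lists")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower bound exceeds upper bound")
        if self.objective_reaction not in self.reaction_ids:
            raise ValueError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    def reaction_index(self, rid: str) -> int:
        return self.reaction_ids.index(rid)


@dataclass
class ColumnOrigin:
    reaction_id: str
    direction: str  # forward | backward | irreversible


@dataclass
class IrreversibleTemplate:
    """Irreversible split of a template-bounded model.

    Columns are ordered [irreversible | reversible-forward | reversible-
    backward]; every backward column is the exact negation of its forward
    sibling and carries bounds [0, T].
    """

    base: MetabolicModel
    mode: str  # DC | AC
    T: float
    L_hat: np.ndarray
    U_hat: np.ndarray
    S_bar: np.ndarray
    column_origin: list[ColumnOrigin]
    c_bar: np.ndarray
    rev_pairs: list[tuple[int, int]]
    carbon_exchanges: set[str] = field(default_factory=set)

    @property
    def n_columns(self) -> int:
        return self.S_bar.shape[1]

    @property
    def column_upper(self) -> np.ndarray:
        """Template upper bound per split column (before expression caps)."""
        ub = np.empty(self.n_columns)
        for j, origin in enumerate(self.column_origin):
            i = self.base.reaction_index(origin.reaction_id)
            if origin.direction == "backward":
                ub[j] = -self.L_hat[i]
            else:
                ub[j] = self.U_hat[i]
        return ub

    def columns_for_reaction(self, rid: str) -> list[int]:
        return [j for j, o in enumerate(self.column_origin) if o.reaction_id == rid]

    def column_gpr(self) -> list[str]:
        """GPR string per split column (siblings share the rule)."""
        idx = {r: i for i, r in enumerate(self.base.reaction_ids)}
        return [self.base.gpr[idx[o.reaction_id]] for o in self.column_origin]

    def to_json(self, path: str) -> None:
        payload = {
            "mode": self.mode,
            "T": self.T,
            "reaction_ids": self.base.reaction_ids,
            "metabolite_ids": self.base.metabolite_ids,
            "L_hat": self.L_hat.tolist(),
            "U_hat": self.U_hat.tolist(),
            "S_bar": self.S_bar.tolist(),
            "column_origin": [
                {"reaction_id": o.reaction_id, "direction": o.direction}
                for o in self.column_origin
            ],
            "c_bar": self.c_bar.tolist(),
            "rev_pairs": [list(p) for p in self.rev_pairs],
            "carbon_exchanges": sorted(self.carbon_exchanges),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _normalize_gpr(rule: str) -> str:
    rule = rule.strip()
    if not rule:
        return ""
    rule = re.sub(r"\bAND\b", "and", rule, flags=re.IGNORECASE)
    rule = re.sub(r"\bOR\b", "or", rule, flags=re.IGNORECASE)
    return rule


def read_sbml(path: str, objective: str | None = None) -> MetabolicModel:
    """Read an SBML model (Level 3 + FBC preferred) into a MetabolicModel.

    Parameters
    ----------
    path:
        SBML file path.
    objective:
        Reaction id to use as the biomass objective when the file does not
        declare one (or to override the declared one).
    """
    import cobra.io

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = cobra.io.read_sbml_model(path)
    except Exception as exc:  # pragma: no cover - passthrough of parser detail
        raise ValueError(f"could not parse SBML file {path!r}: {exc}") from exc

    metabolite_ids = [m.id for m in model.metabolites]
    reaction_ids = [r.id for r in model.reactions]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = coef

    lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
    upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
    gpr = [_normalize_gpr(r.gene_reaction_rule) for r in model.reactions]
    subsystem = [(r.subsystem or "") for r in model.reactions]
    exchange = np.array([r.boundary for r in model.reactions], dtype=bool)
    formulas = [(m.formula or "") for m in model.metabolites]

    if objective is None:
        obj_ids = [
            r.id
            for r in model.reactions
            if getattr(r, "objective_coefficient", 0.0)
        ]
        if not obj_ids:
            raise ValueError(
                "model declares no objective reaction; pass one explicitly "
                "(e.g. the biomass reaction id)"
            )
        objective = obj_ids[0]

    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower_bounds=lower,
        upper_bounds=upper,
        gpr=gpr,
        subsystem=subsystem,
        objective_reaction=objective,
        exchange_flags=exchange,
        metabolite_formulas=formulas,
    )


_ARROWS = ("<->", "<=>", "-->", "->", "<--", "<-")


def _parse_side(side: str) -> list[tuple[float, str]]:
    terms = []
    side = side.strip()
    if not side:
        return terms
    for chunk in side.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split()
        if len(parts) == 2:
            terms.append((float(parts[0]), parts[1]))
        elif len(parts) == 1:
            terms.append((1.0, parts[0]))
        else:
            raise ValueError(f"cannot parse equation term {chunk!r}")
    return terms


def read_tabular(
    path: str,
    objective: str | None = None,
    formulas: dict[str, str] | None = None,
) -> MetabolicModel:
    """Read the fixture tabular model format.

    Tab-separated columns: reaction id, equation string (``A + 2 B -> C``,
    ``<->`` for reversible, empty side for exchanges), lower bound, upper
    bound, GPR, subsystem.  ``formulas`` optionally maps metabolite ids to
    chemical formula strings.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"reaction", "equation", "lower", "upper", "gpr", "subsystem"}
    if not required.issubset(df.columns):
        raise ValueError(f"tabular model must have columns {sorted(required)}")

    reaction_ids = list(df["reaction"])
    stoich: list[dict[str, float]] = []
    met_ids: list[str] = []
    seen: set[str] = set()
    for eq in df["equation"]:
        arrow = next((a for a in _ARROWS if a in eq), None)
        if arrow is None:
            raise ValueError(f"equation {eq!r} has no reaction arrow")
        lhs, rhs = eq.split(arrow)
        coeffs: dict[str, float] = {}
        for coef, met in _parse_side(lhs):
            coeffs[met] = coeffs.get(met, 0.0) - coef
        for coef, met in _parse_side(rhs):
            coeffs[met] = coeffs.get(met, 0.0) + coef
        stoich.append(coeffs)
        for met in coeffs:
            if met not in seen:
                seen.add(met)
                met_ids.append(met)

    S = np.zeros((len(met_ids), len(reaction_ids)))
    met_index = {m: i for i, m in enumerate(met_ids)}
    for j, coeffs in enumerate(stoich):
        for met, coef in coeffs.items():
            S[met_index[met], j] = coef

    # exchange = single-metabolite reaction (system boundary)
    exchange = np.array([len(c) == 1 for c in stoich], dtype=bool)
    formulas = formulas or {}
    if objective is None:
        biomass_like = [r for r in reaction_ids if "biomass" in r.lower()]
        if not biomass_like:
            raise ValueError("no objective reaction; pass one explicitly")
        objective = biomass_like[0]

    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=reaction_ids,
        S=S,
        lower_bounds=df["lower"].astype(float).to_numpy(),
        upper_bounds=df["upper"].astype(float).to_numpy(),
        gpr=[_normalize_gpr(g) for g in df["gpr"]],
        subsystem=list(df["subsystem"]),
        objective_reaction=objective,
        exchange_flags=exchange,
        metabolite_formulas=[formulas.get(m, "") for m in met_ids],
    )


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def template_bounds(L: float, U: float, T: float) -> tuple[float, float]:
    """Map original bounds (L, U) to template bounds.

    The template discards flux magnitudes, keeping only directionality:
    the lower bound becomes 0 when the reaction cannot run backward and -T
    when it can; the upper bound becomes T when it can run forward and 0
    when it cannot.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if L > U:
        raise ValueError("L must not exceed U")
    L_hat = 0.0 if L >= 0 else -T
    U_hat = T if U > 0 else 0.0
    return L_hat, U_hat


_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_carbon_count(formula: str) -> int:
    """Number of carbon atoms in a chemical formula string.

    Tokenizes by element symbol so that Ca, Cl, Co, Cu ... do not count as
    carbon.  Unparseable formulas yield 0.
    """
    count = 0
    for sym, num in _ELEMENT_RE.findall(formula or ""):
        if sym == "C":
            count += int(num) if num else 1
    return count


def identify_carbon_exchanges(model: MetabolicModel) -> set[str]:
    """Exchange reactions whose exchanged metabolite contains carbon."""
    carbon: set[str] = set()
    for j, rid in enumerate(model.reaction_ids):
        if not model.exchange_flags[j]:
            continue
        mets = np.flatnonzero(model.S[:, j])
        if len(mets) != 1:
            continue
        formula = model.metabolite_formulas[mets[0]]
        if not formula:
            warnings.warn(
                f"exchange {rid} skipped: no formula for its metabolite"
            )
            continue
        if formula_carbon_count(formula) >= 1:
            carbon.add(rid)
    return carbon


def split_reversible(
    model: MetabolicModel,
    L_hat: np.ndarray,
    U_hat: np.ndarray,
    objective_reaction: str | None = None,
) -> tuple[np.ndarray, list[ColumnOrigin], list[tuple[int, int]], np.ndarray]:
    """Split template-bounded reactions into nonnegative columns.

    Reversible reactions (L_hat < 0 < U_hat) contribute a forward column and
    a negated backward column; backward-only reactions a single negated
    column; forward-only reactions pass through.  Returns (S_bar,
    column_origin, rev_pairs, c_bar).
    """
    objective_reaction = objective_reaction or model.objective_reaction
    irr_cols: list[np.ndarray] = []
    irr_origin: list[ColumnOrigin] = []
    fwd_cols: list[np.ndarray] = []
    fwd_origin: list[ColumnOrigin] = []
    bwd_cols: list[np.ndarray] = []
    bwd_origin: list[ColumnOrigin] = []

    for j, rid in enumerate(model.reaction_ids):
        col = model.S[:, j]
        if L_hat[j] < 0 and U_hat[j] > 0:
            fwd_cols.append(col)
            fwd_origin.append(ColumnOrigin(rid, "forward"))
            bwd_cols.append(-col)
            bwd_origin.append(ColumnOrigin(rid, "backward"))
        elif U_hat[j] <= 0:
            irr_cols.append(-col)
            irr_origin.append(ColumnOrigin(rid, "backward"))
        else:
            irr_cols.append(col)
            irr_origin.append(ColumnOrigin(rid, "irreversible"))

    cols = irr_cols + fwd_cols + bwd_cols
    origin = irr_origin + fwd_origin + bwd_origin
    S_bar = (
        np.column_stack(cols) if cols else np.zeros((model.n_metabolites, 0))
    )
    n_irr, n_rev = len(irr_cols), len(fwd_cols)
    rev_pairs = [(n_irr + k, n_irr + n_rev + k) for k in range(n_rev)]
    c_bar = np.array(
        [1.0 if o.reaction_id == objective_reaction else 0.0 for o in origin]
    )
    return S_bar, origin, rev_pairs, c_bar


def build_template(
    model: MetabolicModel,
    mode: str = "DC",
    carbon_source: str | Iterable[str] | None = None,
    T: float = DEFAULT_T,
) -> IrreversibleTemplate:
    """Build the DC or AC irreversible template of a model.

    DC opens only the named carbon-source exchange(s) for uptake (lower
    bound -T) and closes uptake on every other carbon exchange; AC opens
    uptake on all carbon exchanges.  Non-carbon exchanges and internal
    reactions follow the plain template-bound rule.
    """
    mode = mode.upper()
    if mode not in {"DC", "AC"}:
        raise ValueError("mode must be 'DC' or 'AC'")
    if T <= 0:
        raise ValueError("T must be positive")

    carbon = identify_carbon_exchanges(model)
    L_hat = np.empty(model.n_reactions)
    U_hat = np.empty(model.n_reactions)
    for j in range(model.n_reactions):
        L_hat[j], U_hat[j] = template_bounds(
            model.lower_bounds[j], model.upper_bounds[j], T
        )

    if mode == "DC":
        if carbon_source is None:
            raise ValueError("DC mode requires a carbon_source reaction id")
        sources = (
            {carbon_source} if isinstance(carbon_source, str) else set(carbon_source)
        )
        unknown = sources - set(model.reaction_ids)
        if unknown:
            raise ValueError(f"unknown carbon source reaction(s): {sorted(unknown)}")
        for rid in carbon:
            j = model.reaction_index(rid)
            L_hat[j] = -T if rid in sources else 0.0
        for rid in sources:
            j = model.reaction_index(rid)
            L_hat[j] = -T
    else:  # AC
        for rid in carbon:
            j = model.reaction_index(rid)
            L_hat[j] = -T

    S_bar, origin, rev_pairs, c_bar = split_reversible(model, L_hat, U_hat)
    return IrreversibleTemplate(
        base=model,
        mode=mode,
        T=T,
        L_hat=L_hat,
        U_hat=U_hat,
        S_bar=S_bar,
        column_origin=origin,
        c_bar=c_bar,
        rev_pairs=rev_pairs,
        carbon_exchanges=carbon,
    )


def fold_solution(
    v_bar: Sequence[float], template: IrreversibleTemplate
) -> np.ndarray:
    """Fold a nonnegative split-column flux vector back to reaction space.

    Reversible reactions report forward - backward; backward-only columns
    report the negated value so signs match the original model orientation.
    """
    v_bar = np.asarray(v_bar, dtype=float)
    if v_bar.shape[0] != template.n_columns:
        raise ValueError(
            f"expected {template.n_columns} column fluxes, got {v_bar.shape[0]}"
        )
    net = np.zeros(template.base.n_reactions)
    idx = {r: i for i, r in enumerate(template.base.reaction_ids)}
    for j, origin in enumerate(template.column_origin):
        i = idx[origin.reaction_id]
        if origin.direction == "backward":
            net[i] -= v_bar[j]
        else:
            net[i] += v_bar[j]
    return net
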