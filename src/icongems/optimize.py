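"""Optimization core: E-flux LP, the co-expression quadratic program, FVA.

The quadratic program maximizes the sum of products q_i * q_j over the
reaction-pair set R (pairs of reactions whose genes are linked in the
co-expression network), where q_j = 1 + v_j / M_j maps a column flux into
[1, 2].  Constraints: steady state S_bar v = 0, E-flux expression caps
0 <= v_j <= f(g_j), biomass >= alpha * z* with z* the E-flux optimum, and
per-pair complementarity v_fw * v_bw = 0 for the two columns of every split
reversible reaction.

Maximizing an indefinite quadratic with complementarity is NP-hard, so the
solver enumerates the complementarity disjunctions (which side of each
reversible pair may carry flux) when the pair count is small and, within
each branch, runs seeded multistart local optimization from LP vertices.
The folded E-flux optimizer is always included as a candidate, so the
returned objective never falls below the E-flux solution's.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import (
    Bounds,
    LinearConstraint,
    NonlinearConstraint,
    linprog,
    minimize,
)

from .gpr_map import ReactionBounds, ReactionPairSet
from .model_io import IrreversibleTemplate, fold_solution

__all__ = [
    "IconProblem",
    "FluxSolution",
    "FlexibilityReport",
    "solve_eflux",
    "solve_icon",
    "icon_objective",
    "flexibility_fva",
    "subsystem_flexibility",
    "check_solution",
]

FEAS_TOL = 1e-6
OBJECTIVE_PIN_REL = 1e-6  # stage-2 FVA: quadratic objective >= Z*(1 - this)


# ---------------------------------------------------------------------------
# Problem and solution containers
# ---------------------------------------------------------------------------

@dataclass
class IconProblem:
    template: IrreversibleTemplate
    bounds: ReactionBounds
    R: ReactionPairSet
    alpha: float = 1.0
    z_star: float | None = None
    n_starts: int = 10
    seed: int = 0
    max_branches: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        rev = {frozenset(p) for p in self.template.rev_pairs}
        if any(frozenset(p) in rev for p in self.R.pairs):
            raise ValueError("R must not contain reversible sibling pairs")


@dataclass
class FluxSolution:
    v_bar: np.ndarray
    q: np.ndarray
    objective: float
    biomass: float
    status: str
    net_flux: np.ndarray
    z_star: float

    def net_flux_by_reaction(self, template: IrreversibleTemplate) -> dict[str, float]:
        return dict(zip(template.base.reaction_ids, self.net_flux))


@dataclass
class FlexibilityReport:
    """Per-reaction flux ranges at a pinned stage-1 objective."""

    reaction_ids: list[str]
    v_min: np.ndarray
    v_max: np.ndarray
    subsystem: list[str]
    condition: str = ""

    @property
    def F(self) -> np.ndarray:
        return np.abs(self.v_max - self.v_min)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reaction_id": self.reaction_ids,
                "v_min": self.v_min,
                "v_max": self.v_max,
                "F": self.F,
                "subsystem": self.subsystem,
            }
        )


# ---------------------------------------------------------------------------
# LP machinery
# ---------------------------------------------------------------------------

def _lp(
    template: IrreversibleTemplate,
    upper: np.ndarray,
    c: np.ndarray,
    sense: str = "max",
    extra_ub: list[tuple[np.ndarray, float]] | None = None,
) -> tuple[float, np.ndarray] | None:
    """Solve optimize c.v over {S_bar v = 0, 0 <= v <= upper, A x <= b}."""
    obj = -c if sense == "max" else c
    A_ub = b_ub = None
    if extra_ub:
        A_ub = np.vstack([row for row, _ in extra_ub])
        b_ub = np.array([rhs for _, rhs in extra_ub])
    res = linprog(
        obj,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=template.S_bar,
        b_eq=np.zeros(template.S_bar.shape[0]),
        bounds=list(zip(np.zeros_like(upper), upper)),
        method="highs",
    )
    if not res.success:
        return None
    val = -res.fun if sense == "max" else res.fun
    return float(val), np.maximum(res.x, 0.0)


def solve_eflux(
    template: IrreversibleTemplate, bounds: ReactionBounds
) -> tuple[float, np.ndarray]:
    """Maximize biomass under E-flux expression caps.

    Returns (z_star, optimizer).  The optimizer has any simultaneous flow on
    reversible sibling columns canceled (min subtracted from both sides),
    which leaves the steady state and all net fluxes unchanged.
    """
    out = _lp(template, bounds.f, template.c_bar, "max")
    if out is None:
        raise RuntimeError(
            "E-flux LP infeasible or unbounded: check template bounds and "
            "expression caps (all-zero caps on the biomass path give z*=0, "
            "not infeasibility, so this indicates a structural problem)"
        )
    z_star, v = out
    v = _cancel_rev_pairs(v, template)
    return z_star, v


def _cancel_rev_pairs(
    v: np.ndarray, template: IrreversibleTemplate
) -> np.ndarray:
    v = v.copy()
    for a, b in template.rev_pairs:
        m = min(v[a], v[b])
        if m > 0:
            v[a] -= m
            v[b] -= m
    return v


# ---------------------------------------------------------------------------
# Quadratic objective
# ---------------------------------------------------------------------------

def _objective_terms(
    problem: IconProblem,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Expand sum of (1 + w_i v_i)(1 + w_j v_j) to const + g.v + 1/2 v'Hv."""
    n = problem.template.n_columns
    w = np.zeros(n)
    mapped = problem.bounds.mapped_columns()
    w[mapped] = 1.0 / problem.bounds.M[mapped]
    g = np.zeros(n)
    H = np.zeros((n, n))
    for i, j in problem.R.pairs:
        g[i] += w[i]
        g[j] += w[j]
        H[i, j] += w[i] * w[j]
        H[j, i] += w[i] * w[j]
    return float(len(problem.R.pairs)), g, H


def icon_objective(problem: IconProblem, v_bar: np.ndarray) -> float:
    """Evaluate the quadratic co-activation objective at a flux vector."""
    const, g, H = _objective_terms(problem)
    v = np.asarray(v_bar, dtype=float)
    return const + float(g @ v) + 0.5 * float(v @ H @ v)


def _q_vector(problem: IconProblem, v_bar: np.ndarray) -> np.ndarray:
    q = np.ones(problem.template.n_columns)
    mapped = problem.bounds.mapped_columns()
    M = problem.bounds.M
    q[mapped] = 1.0 + np.asarray(v_bar)[mapped] / M[mapped]
    return q


# ---------------------------------------------------------------------------
# Branch-and-multistart QP solver
# ---------------------------------------------------------------------------

def _active_patterns(problem: IconProblem, upper: np.ndarray, hint: np.ndarray):
    """Complementarity disjunction patterns to explore.

    Each pattern assigns every reversible sibling pair the side allowed to
    carry flux.  Full enumeration when 2^p fits in max_branches; otherwise
    the hint's sign pattern plus its single-pair flips.
    """
    pairs = problem.template.rev_pairs
    # pairs where one side is already shut by bounds need no branching
    open_pairs = [
        (a, b) for a, b in pairs if upper[a] > FEAS_TOL and upper[b] > FEAS_TOL
    ]
    fixed = [(a, b) for a, b in pairs if (a, b) not in open_pairs]
    if 2 ** len(open_pairs) <= problem.max_branches:
        patterns = list(itertools.product((0, 1), repeat=len(open_pairs)))
    else:
        base = tuple(
            0 if hint[a] >= hint[b] else 1 for a, b in open_pairs
        )
        patterns = [base]
        for k in range(len(open_pairs)):
            flipped = list(base)
            flipped[k] = 1 - flipped[k]
            patterns.append(tuple(flipped))
    for pat in patterns:
        ub = upper.copy()
        for (a, b), side in zip(open_pairs, pat):
            ub[b if side == 0 else a] = 0.0
        for a, b in fixed:
            if upper[a] <= FEAS_TOL:
                ub[a] = 0.0
            if upper[b] <= FEAS_TOL:
                ub[b] = 0.0
        yield ub


def _is_feasible(
    problem: IconProblem, v: np.ndarray, upper: np.ndarray, alpha_z: float
) -> bool:
    t = problem.template
    scale = 1.0 + float(np.max(np.abs(v), initial=0.0))
    if np.max(np.abs(t.S_bar @ v), initial=0.0) > FEAS_TOL * scale:
        return False
    if np.any(v < -1e-9) or np.any(v > upper + 1e-9 * (1 + upper)):
        return False
    if t.c_bar @ v < alpha_z - FEAS_TOL * (1.0 + alpha_z):
        return False
    for a, b in t.rev_pairs:
        if min(v[a], v[b]) > FEAS_TOL * scale:
            return False
    return True


def solve_icon(problem: IconProblem) -> FluxSolution:
    """Solve the co-expression quadratic program.

    Returns the best feasible point found across complementarity branches
    and multistart local solves; status is "heuristic" (local certificates
    only) or "degenerate" when R is empty, in which case any point
    attaining the biomass pin is returned with objective 0.
    """
    template = problem.template
    upper = np.asarray(problem.bounds.f, dtype=float).copy()
    if problem.z_star is None:
        z_star, v_eflux = solve_eflux(template, problem.bounds)
    else:
        z_star = problem.z_star
        _, v_eflux = solve_eflux(template, problem.bounds)
    alpha_z = problem.alpha * z_star
    biomass_row = [(-template.c_bar, -alpha_z)]

    if len(problem.R.pairs) == 0:
        v = v_eflux
        return FluxSolution(
            v_bar=v,
            q=_q_vector(problem, v),
            objective=0.0,
            biomass=float(template.c_bar @ v),
            status="degenerate: no co-expression pairs",
            net_flux=fold_solution(v, template),
            z_star=z_star,
        )

    const, g, H = _objective_terms(problem)

    def neg_obj(v):
        return -(const + g @ v + 0.5 * v @ H @ v)

    def neg_grad(v):
        return -(g + H @ v)

    rng = np.random.default_rng(problem.seed)
    n = template.n_columns
    best_v = v_eflux
    best_obj = icon_objective(problem, v_eflux)

    for ub in _active_patterns(problem, upper, v_eflux):
        # candidate starts: E-flux point if it fits this branch, the LP
        # maximizing the linear objective part, and random-objective vertices
        starts: list[np.ndarray] = []
        if np.all(v_eflux <= ub + 1e-12):
            starts.append(v_eflux)
        for c_try in [g, template.c_bar] + [
            rng.random(n) for _ in range(max(0, problem.n_starts - 2))
        ]:
            out = _lp(template, ub, c_try, "max", extra_ub=biomass_row)
            if out is None:
                break
            starts.append(out[1])
        if not starts:
            continue  # branch infeasible at the biomass pin

        constraints = [
            LinearConstraint(template.S_bar, 0.0, 0.0),
            LinearConstraint(template.c_bar, alpha_z, np.inf),
        ]
        box = Bounds(np.zeros(n), ub)
        seen: set[bytes] = set()
        for x0 in starts:
            key = np.round(x0, 6).tobytes()
            if key in seen:
                continue
            seen.add(key)
            cand = [x0]
            try:
                res = minimize(
                    neg_obj,
                    np.clip(x0, 0, ub),
                    jac=neg_grad,
                    hess=lambda v: -H,
                    method="trust-constr",
                    bounds=box,
                    constraints=constraints,
                    options={"maxiter": 300, "gtol": 1e-10, "xtol": 1e-12},
                )
                cand.append(np.clip(res.x, 0, ub))
            except Exception:  # pragma: no cover - solver hiccup, keep x0
                pass
            for v in cand:
                v = _cancel_rev_pairs(v, template)
                if _is_feasible(problem, v, upper, alpha_z):
                    obj = icon_objective(problem, v)
                    if obj > best_obj + 1e-12:
                        best_obj, best_v = obj, v

    return FluxSolution(
        v_bar=best_v,
        q=_q_vector(problem, best_v),
        objective=best_obj,
        biomass=float(template.c_bar @ best_v),
        status="heuristic",
        net_flux=fold_solution(best_v, template),
        z_star=z_star,
    )


# ---------------------------------------------------------------------------
# Two-stage FVA flexibility
# ---------------------------------------------------------------------------

def _net_flux_row(template: IrreversibleTemplate, rid: str) -> np.ndarray:
    d = np.zeros(template.n_columns)
    for j, origin in enumerate(template.column_origin):
        if origin.reaction_id == rid:
            d[j] = -1.0 if origin.direction == "backward" else 1.0
    return d


def flexibility_fva(
    problem: IconProblem,
    solution: FluxSolution | None = None,
    reactions: Sequence[str] | None = None,
    condition: str = "",
) -> FlexibilityReport:
    """Stage-2 flux variability at the pinned stage-1 objective.

    For every original reaction the net flux is maximized and minimized
    subject to the full stage-1 system plus the quadratic objective held at
    Z*(1 - 1e-6) and biomass >= alpha z*.  With R empty the quadratic pin is
    vacuous and the ranges are exact LP values; otherwise stage 2 inherits
    the heuristic local solver, starting from the stage-1 point.
    """
    template = problem.template
    if solution is None:
        solution = solve_icon(problem)
    upper = np.asarray(problem.bounds.f, dtype=float)
    alpha_z = problem.alpha * solution.z_star
    biomass_row = [(-template.c_bar, -alpha_z)]
    rids = list(reactions) if reactions else list(template.base.reaction_ids)
    sub_by_rid = dict(zip(template.base.reaction_ids, template.base.subsystem))

    pin_tol = OBJECTIVE_PIN_REL
    z_pin = solution.objective * (1.0 - pin_tol) - 1e-9
    have_pairs = len(problem.R.pairs) > 0
    const, g, H = _objective_terms(problem)

    def quad(v):
        return const + g @ v + 0.5 * v @ H @ v

    v_min = np.empty(len(rids))
    v_max = np.empty(len(rids))
    for k, rid in enumerate(rids):
        d = _net_flux_row(template, rid)
        if not have_pairs:
            lo = _lp(template, upper, d, "min", extra_ub=biomass_row)
            hi = _lp(template, upper, d, "max", extra_ub=biomass_row)
            if lo is None or hi is None:
                raise RuntimeError(f"stage-2 LP infeasible for reaction {rid}")
            v_min[k], v_max[k] = lo[0], hi[0]
            continue
        v_min[k] = _fva_one(problem, d, "min", solution, z_pin, alpha_z, quad, g, H)
        v_max[k] = _fva_one(problem, d, "max", solution, z_pin, alpha_z, quad, g, H)
        if v_min[k] > v_max[k]:  # numerical crossing at a pinned point
            v_min[k] = v_max[k] = float(d @ solution.v_bar)

    return FlexibilityReport(
        reaction_ids=rids,
        v_min=v_min,
        v_max=v_max,
        subsystem=[sub_by_rid.get(r, "") for r in rids],
        condition=condition,
    )


def _fva_one(
    problem: IconProblem,
    d: np.ndarray,
    sense: str,
    solution: FluxSolution,
    z_pin: float,
    alpha_z: float,
    quad,
    g: np.ndarray,
    H: np.ndarray,
) -> float:
    """One stage-2 bound: optimize d.v under the pinned quadratic objective."""
    template = problem.template
    n = template.n_columns
    upper = np.asarray(problem.bounds.f, dtype=float)
    sign = -1.0 if sense == "max" else 1.0

    best = float(d @ solution.v_bar)  # stage-1 point is always feasible
    rng = np.random.default_rng(problem.seed + 1)

    for ub in _active_patterns(problem, upper, solution.v_bar):
        starts = []
        if np.all(solution.v_bar <= ub + 1e-12):
            starts.append(solution.v_bar)
        out = _lp(
            template, ub, d, sense,
            extra_ub=[(-template.c_bar, -alpha_z)],
        )
        if out is None:
            continue
        starts.append(out[1])
        out2 = _lp(template, ub, g, "max", extra_ub=[(-template.c_bar, -alpha_z)])
        if out2 is not None:
            starts.append(out2[1])

        constraints = [
            LinearConstraint(template.S_bar, 0.0, 0.0),
            LinearConstraint(template.c_bar, alpha_z, np.inf),
            NonlinearConstraint(
                quad, z_pin, np.inf, jac=lambda v: g + H @ v, hess=lambda v, l: l * H
            ),
        ]
        for x0 in starts:
            try:
                res = minimize(
                    lambda v: sign * (d @ v),
                    np.clip(x0, 0, ub),
                    jac=lambda v: sign * d,
                    hess=lambda v: np.zeros((n, n)),
                    method="trust-constr",
                    bounds=Bounds(np.zeros(n), ub),
                    constraints=constraints,
                    options={"maxiter": 300, "gtol": 1e-10, "xtol": 1e-12},
                )
            except Exception:  # pragma: no cover
                continue
            v = _cancel_rev_pairs(np.clip(res.x, 0, ub), template)
            if not _is_feasible(problem, v, upper, alpha_z):
                continue
            if quad(v) < z_pin - 1e-6 * (1 + abs(z_pin)):
                continue
            val = float(d @ v)
            if (sense == "max" and val > best) or (sense == "min" and val < best):
                best = val
    return best


def subsystem_flexibility(
    reports: Mapping[str, FlexibilityReport] | Sequence[FlexibilityReport],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-reaction flexibility to subsystems across conditions.

    Returns (raw, normalized): raw holds the arithmetic mean F of each
    subsystem's member reactions per condition; normalized is the same
    matrix min-max scaled to [0, 1] over all entries (all-equal matrices
    normalize to 0 with a warning).  Subsystems with no member reactions are
    omitted with a warning.
    """
    if not isinstance(reports, Mapping):
        reports = {r.condition or str(i): r for i, r in enumerate(reports)}

    rows: dict[str, dict[str, float]] = {}
    for cond, rep in reports.items():
        frame = rep.to_frame()
        labeled = frame[frame["subsystem"] != ""]
        dropped = frame.shape[0] - labeled.shape[0]
        if dropped:
            warnings.warn(f"{dropped} reaction(s) without subsystem label omitted")
        for sub, grp in labeled.groupby("subsystem"):
            rows.setdefault(sub, {})[cond] = float(grp["F"].mean())

    raw = pd.DataFrame(rows).T.sort_index()
    raw = raw[list(reports.keys())]
    lo, hi = np.nanmin(raw.values), np.nanmax(raw.values)
    if hi - lo == 0:
        warnings.warn("degenerate flexibility range: all entries equal, normalized to 0")
        norm = raw * 0.0
    else:
        norm = (raw - lo) / (hi - lo)
    return raw, norm


# ---------------------------------------------------------------------------
# Feasibility audit (used by the test suite on every solve)
# ---------------------------------------------------------------------------

def check_solution(
    problem: IconProblem, sol: FluxSolution, atol: float = FEAS_TOL
) -> dict[str, float]:
    """Audit a solution against every model constraint; returns residuals."""
    t = problem.template
    v = sol.v_bar
    scale = 1.0 + float(np.max(np.abs(v), initial=0.0))
    residuals = {
        "steady_state": float(np.max(np.abs(t.S_bar @ v), initial=0.0)) / scale,
        "lower_bound": float(max(0.0, -np.min(v, initial=0.0))),
        "upper_bound": float(
            np.max(v - problem.bounds.f, initial=0.0)
        ),
        "complementarity": max(
            (min(v[a], v[b]) for a, b in t.rev_pairs), default=0.0
        )
        / scale,
        "biomass_pin": max(
            0.0,
            problem.alpha * sol.z_star - sol.biomass,
        )
        / (1.0 + sol.z_star),
    }
    mapped = problem.bounds.mapped_columns()
    q = sol.q[mapped]
    residuals["q_range"] = float(
        max(np.max(q - 2.0, initial=0.0), np.max(1.0 - q, initial=0.0))
    )
    return residuals
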