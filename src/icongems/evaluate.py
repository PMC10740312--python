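"""Scoring predicted fluxes against measured (13C-MFA style) fluxes.

Measured fluxes rarely map one-to-one onto model reactions.  Two mapping
cases reconcile them: a *chain* entry (AND) stands for a measured conversion
that the model realizes as several sequential reactions, scored as the
minimum absolute net flux along the chain; a *parallel* entry (OR) stands
for several model reactions sharing the measured substrates/products,
scored as the signed sum of their net fluxes.  Agreement is the uncentered
Pearson correlation, which is invariant to the overall flux scale and so
tolerant of unit mismatches between prediction and measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MappingEntry",
    "FluxMappingSpec",
    "AccuracyResult",
    "map_fluxes",
    "uncentered_pearson",
    "predictive_accuracy",
    "module_concordance",
]


@dataclass
class MappingEntry:
    measured_id: str
    mode: str  # chain | parallel
    steps: list[str]  # model reaction ids, "-" prefix flips orientation

    def __post_init__(self) -> None:
        if self.mode not in {"chain", "parallel"}:
            raise ValueError(f"unknown mapping mode {self.mode!r}")
        if len(self.steps) < 1:
            raise ValueError(f"mapping entry {self.measured_id!r} has no steps")


@dataclass
class FluxMappingSpec:
    entries: list[MappingEntry]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [e.measured_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate measured reaction ids in mapping spec")

    @classmethod
    def from_tsv(cls, path: str) -> "FluxMappingSpec":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = [
            MappingEntry(
                measured_id=row["measured_id"],
                mode=row["mode"],
                steps=[s.strip() for s in row["steps"].split(";") if s.strip()],
            )
            for _, row in df.iterrows()
        ]
        return cls(entries=entries, source=str(path))


@dataclass
class AccuracyResult:
    measured_ids: list[str]
    v_p: np.ndarray
    v_m: np.ndarray
    R_u: float
    trace: list[str]


def _step(step: str) -> tuple[str, float]:
    return (step[1:], -1.0) if step.startswith("-") else (step, 1.0)


def map_fluxes(
    spec: FluxMappingSpec, predicted: Mapping[str, float]
) -> np.ndarray:
    """Map predicted reaction fluxes onto the measured-flux entries.

    Chain entries take the minimum |net flux| over their steps (a reversible
    intermediate running backward still carries the pathway); parallel
    entries sum the signed net fluxes, each step oriented toward the
    measured product via an optional ``-`` prefix.
    """
    v_p = np.empty(len(spec.entries))
    for k, entry in enumerate(spec.entries):
        vals = []
        for step in entry.steps:
            rid, sign = _step(step)
            if rid not in predicted:
                raise KeyError(
                    f"mapping entry {entry.measured_id!r} references unknown "
                    f"reaction {rid!r}"
                )
            vals.append(sign * predicted[rid])
        if entry.mode == "chain":
            v_p[k] = min(abs(v) for v in vals)
        else:
            v_p[k] = sum(vals)
    return v_p


def uncentered_pearson(v_p: Sequence[float], v_m: Sequence[float]) -> float:
    """Uncentered Pearson correlation: dot product over the norm product.

    Scale-invariant: multiplying either vector by a positive constant leaves
    the value unchanged.  Zero vectors make the correlation undefined and
    raise rather than silently returning 0.
    """
    v_p = np.asarray(v_p, dtype=float)
    v_m = np.asarray(v_m, dtype=float)
    if v_p.shape != v_m.shape or v_p.ndim != 1 or v_p.size == 0:
        raise ValueError("vectors must be 1-D, nonempty and of equal length")
    np_, nm = np.linalg.norm(v_p), np.linalg.norm(v_m)
    if np_ == 0 or nm == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float(np.clip(v_p @ v_m / (np_ * nm), -1.0, 1.0))


def predictive_accuracy(
    spec: FluxMappingSpec,
    predicted: Mapping[str, float],
    measured: Mapping[str, float],
) -> AccuracyResult:
    """Map predictions onto the measured entries and score them."""
    v_p = map_fluxes(spec, predicted)
    ids = [e.measured_id for e in spec.entries]
    missing = [i for i in ids if i not in measured]
    if missing:
        raise KeyError(f"measured values missing for {missing}")
    v_m = np.array([measured[i] for i in ids], dtype=float)
    trace = [
        f"{e.measured_id}: {e.mode}({';'.join(e.steps)}) -> {v:.6g}"
        for e, v in zip(spec.entries, v_p)
    ]
    return AccuracyResult(
        measured_ids=ids, v_p=v_p, v_m=v_m,
        R_u=uncentered_pearson(v_p, v_m), trace=trace,
    )


# ---------------------------------------------------------------------------
# Module / flux concordance
# ---------------------------------------------------------------------------

def _minmax_rows(mat: np.ndarray, label: str) -> np.ndarray:
    out = np.zeros_like(mat, dtype=float)
    for i in range(mat.shape[0]):
        row = mat[i]
        if np.all(np.isnan(row)):
            out[i] = row
            continue
        lo, hi = np.nanmin(row), np.nanmax(row)
        if hi - lo == 0:
            warnings.warn(f"degenerate {label} row {i}: constant, normalized to 0")
            out[i] = 0.0
        else:
            out[i] = (row - lo) / (hi - lo)
    return out


def module_concordance(
    modules: Mapping[str, str],
    expr: "object",
    fluxes_by_condition: Mapping[str, Mapping[str, float]],
    reaction_genes: Mapping[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Compare per-module mean expression against per-module mean |flux|.

    For each module and condition, matrix 1 averages the expression of the
    module's genes and matrix 2 averages |net flux| over reactions whose GPR
    references at least one module gene.  Both are row-wise min-max
    normalized to [0, 1]; the per-module Pearson correlation between the two
    row patterns is the concordance score.
    """
    conditions = list(fluxes_by_condition.keys())
    labels = sorted(set(modules.values()), key=lambda s: (len(s), s))
    gene_idx = {g: i for i, g in enumerate(expr.genes)}

    expr_mat = np.full((len(labels), len(conditions)), np.nan)
    flux_mat = np.full((len(labels), len(conditions)), np.nan)
    for r, mod in enumerate(labels):
        mod_genes = {g for g, lab in modules.items() if lab == mod}
        rows = [gene_idx[g] for g in mod_genes if g in gene_idx]
        mod_rxns = [
            rid for rid, gset in reaction_genes.items() if gset & mod_genes
        ]
        if not mod_rxns:
            warnings.warn(f"module {mod} maps to no reactions; flux row missing")
        for c, cond in enumerate(conditions):
            if rows:
                col = expr.conditions.index(cond) if cond in expr.conditions else c
                expr_mat[r, c] = float(np.mean(expr.values[rows, col]))
            if mod_rxns:
                flux = fluxes_by_condition[cond]
                flux_mat[r, c] = float(
                    np.mean([abs(flux[rid]) for rid in mod_rxns])
                )

    expr_norm = pd.DataFrame(
        _minmax_rows(expr_mat, "expression"), index=labels, columns=conditions
    )
    flux_norm = pd.DataFrame(
        _minmax_rows(flux_mat, "flux"), index=labels, columns=conditions
    )

    scores: dict[str, float] = {}
    for mod in labels:
        e = expr_norm.loc[mod].to_numpy()
        f = flux_norm.loc[mod].to_numpy()
        if np.any(np.isnan(f)) or e.std() == 0 or f.std() == 0:
            scores[mod] = float("nan")
        else:
            scores[mod] = float(np.corrcoef(e, f)[0, 1])
    return expr_norm, flux_norm, scores
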