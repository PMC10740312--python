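"""Self-contained synthetic fixtures: toy metabolic models and expression.

The toy model is a substrate-uptake exchange feeding ``n_pathways`` parallel
linear pathways that converge on a biomass reaction; every internal reaction
carries a unique gene so GPR-mediated expression caps and network lifting
are exercised end to end.  One pathway contains a reversible step so the
irreversible split and the complementarity constraint are always active.

The expression generator emulates the statistical structure the
co-expression network assumes: groups of genes driven by a shared latent
condition profile plus independent Gaussian noise, with the latent scaled so
the expected within-block Pearson correlation equals ``block_correlation``.
It does not emulate count noise, library-size effects or batch structure of
real RNA-seq data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coexpr_net import CoexpressionNetwork, ExpressionMatrix, binarize, correlation_matrix
from .evaluate import uncentered_pearson
from .gpr_map import build_pair_set, reaction_bounds_for_condition
from .model_io import MetabolicModel, build_template
from .optimize import FluxSolution, IconProblem, solve_icon

__all__ = [
    "ToySpec",
    "gen_toy_model",
    "default_blocks",
    "gen_expression",
    "ground_truth_fluxes",
    "write_fixture_files",
    "run_pipeline",
    "recovery_experiment",
    "robustness_curve",
]

# Binarization threshold for the tiny toy networks: must sit well between
# the between-block correlation (~0) and the within-block target
# (block_correlation, default 0.9) so that missing true edges is rare and
# the dominant error mode is spurious between-block edges, whose
# probability falls steeply with the number of conditions.
TOY_THRESHOLD = 0.5


@dataclass
class ToySpec:
    n_pathways: int = 2
    pathway_length: int = 2
    n_conditions: int = 8
    block_correlation: float = 0.9
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.pathway_length, self.n_conditions) < 1:
            raise ValueError("all sizes must be positive")
        if not 0 < self.block_correlation < 1:
            raise ValueError("block_correlation must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# Toy model
# ---------------------------------------------------------------------------

def gen_toy_model(spec: ToySpec) -> MetabolicModel:
    """Build the parallel-pathway toy model.

    Reactions: EX_glc (reversible substrate exchange), P{p}R{i} internal
    steps with gene g{p}_{i} each, BIOMASS (gene g_bio) consuming the
    converged precursor, and EX_bio draining the biomass metabolite.  The
    last pathway's last step is reversible.
    """
    P, L = spec.n_pathways, spec.pathway_length
    rows = []  # (rid, equation, lower, upper, gpr, subsystem)
    rows.append(("EX_glc", "glc <->", -10.0, 1000.0, "", "Exchange"))
    for p in range(1, P + 1):
        prev = "glc"
        for i in range(1, L + 1):
            met = "X" if i == L else f"m{p}_{i}"
            reversible = p == P and i == L
            arrow = "<->" if reversible else "->"
            lb = -1000.0 if reversible else 0.0
            rows.append(
                (
                    f"P{p}R{i}",
                    f"{prev} {arrow} {met}",
                    lb,
                    1000.0,
                    f"g{p}_{i}",
                    f"Pathway {p}",
                )
            )
            prev = met
    rows.append(("BIOMASS", "X -> bio", 0.0, 1000.0, "g_bio", "Biomass"))
    rows.append(("EX_bio", "bio ->", 0.0, 1000.0, "", "Exchange"))

    met_ids: list[str] = []
    stoich: list[dict[str, float]] = []
    from .model_io import _ARROWS, _parse_side  # fixture format shares the grammar

    for _, eq, *_ in rows:
        arrow = next(a for a in _ARROWS if a in eq)
        lhs, rhs = eq.split(arrow)
        coeffs: dict[str, float] = {}
        for coef, met in _parse_side(lhs):
            coeffs[met] = coeffs.get(met, 0.0) - coef
        for coef, met in _parse_side(rhs):
            coeffs[met] = coeffs.get(met, 0.0) + coef
        stoich.append(coeffs)
        for met in coeffs:
            if met not in met_ids:
                met_ids.append(met)

    S = np.zeros((len(met_ids), len(rows)))
    midx = {m: i for i, m in enumerate(met_ids)}
    for j, coeffs in enumerate(stoich):
        for met, coef in coeffs.items():
            S[midx[met], j] = coef

    formulas = {"glc": "C6H12O6", "bio": "R"}
    for m in met_ids:
        formulas.setdefault(m, "C3H6O3")

    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=[r[0] for r in rows],
        S=S,
        lower_bounds=np.array([r[2] for r in rows]),
        upper_bounds=np.array([r[3] for r in rows]),
        gpr=[r[4] for r in rows],
        subsystem=[r[5] for r in rows],
        objective_reaction="BIOMASS",
        exchange_flags=np.array([len(c) == 1 for c in stoich]),
        metabolite_formulas=[formulas[m] for m in met_ids],
    )


def default_blocks(model: MetabolicModel) -> dict[str, int]:
    """Per-pathway gene blocks; the biomass gene joins pathway 1's block."""
    blocks: dict[str, int] = {}
    for rule in model.gpr:
        if not rule:
            continue
        if rule == "g_bio":
            blocks[rule] = 0
        else:
            pathway = int(rule[1:].split("_")[0])
            blocks[rule] = pathway - 1
    return blocks


def ground_truth_fluxes(model: MetabolicModel, pathway: int = 1) -> dict[str, float]:
    """Unit-flux route through one pathway (the recovery target pattern)."""
    truth = {rid: 0.0 for rid in model.reaction_ids}
    truth["EX_glc"] = -1.0
    truth["BIOMASS"] = 1.0
    truth["EX_bio"] = 1.0
    for rid in model.reaction_ids:
        if rid.startswith(f"P{pathway}R"):
            truth[rid] = 1.0
    return truth


def write_fixture_files(model: MetabolicModel, outdir: str | Path) -> dict[str, Path]:
    """Emit the model as both the tabular fixture format and SBML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tab = outdir / "toy_model.tsv"
    with open(tab, "w") as fh:
        fh.write("reaction\tequation\tlower\tupper\tgpr\tsubsystem\n")
        for j, rid in enumerate(model.reaction_ids):
            lhs, rhs = [], []
            for i in np.flatnonzero(model.S[:, j]):
                coef = model.S[i, j]
                term = (
                    model.metabolite_ids[i]
                    if abs(coef) == 1
                    else f"{abs(coef):g} {model.metabolite_ids[i]}"
                )
                (lhs if coef < 0 else rhs).append(term)
            arrow = "<->" if model.lower_bounds[j] < 0 < model.upper_bounds[j] else "->"
            eq = f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()
            fh.write(
                f"{rid}\t{eq}\t{model.lower_bounds[j]:g}\t{model.upper_bounds[j]:g}"
                f"\t{model.gpr[j]}\t{model.subsystem[j]}\n"
            )

    sbml = outdir / "toy_model.xml"
    _write_sbml(model, sbml)
    return {"tabular": tab, "sbml": sbml}


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra
    from cobra.io import write_sbml_model

    cm = cobra.Model("toy")
    mets = {}
    for i, mid in enumerate(model.metabolite_ids):
        met = cobra.Metabolite(
            mid, formula=model.metabolite_formulas[i] or None, compartment="c"
        )
        mets[mid] = met
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bounds[j])
        rxn.upper_bound = float(model.upper_bounds[j])
        rxn.subsystem = model.subsystem[j]
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {
                mets[model.metabolite_ids[i]]: model.S[i, j]
                for i in np.flatnonzero(model.S[:, j])
            }
        )
        if model.gpr[j]:
            rxn.gene_reaction_rule = model.gpr[j]
    cm.objective = model.objective_reaction
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        write_sbml_model(cm, str(path))


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

def gen_expression(
    spec: ToySpec,
    genes: list[str],
    blocks: dict[str, int],
    gene_scale: dict[str, float] | None = None,
) -> ExpressionMatrix:
    """Block-correlated expression across ``spec.n_conditions`` conditions.

    Genes in one block share a latent standard-normal condition profile; the
    latent is scaled against ``noise_sd`` so the expected within-block
    Pearson correlation equals ``block_correlation`` (exactly 1 when
    noise_sd = 0).  Values are shifted per gene to a positive baseline and
    multiplied by a per-gene scale (default drawn from U(0.5, 1.5)), neither
    of which changes any correlation.
    """
    if spec.n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    missing = set(genes) - set(blocks)
    if missing:
        raise ValueError(f"blocks do not cover genes: {sorted(missing)}")

    rng = np.random.default_rng(spec.seed)
    N = spec.n_conditions
    rho = spec.block_correlation
    latents = {b: rng.standard_normal(N) for b in sorted(set(blocks.values()))}
    if spec.noise_sd > 0:
        signal_sd = spec.noise_sd * np.sqrt(rho / (1.0 - rho))
    else:
        signal_sd = 1.0

    values = np.empty((len(genes), N))
    for k, gene in enumerate(genes):
        x = signal_sd * latents[blocks[gene]]
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(N)
        x = x - x.min() + 1.0  # positive baseline, correlation-preserving
        scale = (
            gene_scale.get(gene) if gene_scale and gene in gene_scale else None
        )
        if scale is None:
            scale = rng.uniform(0.5, 1.5)
        values[k] = scale * x

    return ExpressionMatrix(
        genes=list(genes),
        conditions=[f"C{i + 1}" for i in range(N)],
        values=values,
    )


# ---------------------------------------------------------------------------
# End-to-end composition and the two headline synthetic experiments
# ---------------------------------------------------------------------------

def run_pipeline(
    model: MetabolicModel,
    expression: ExpressionMatrix,
    condition: str,
    threshold: float = TOY_THRESHOLD,
    alpha: float = 1.0,
    carbon_source: str = "EX_glc",
    mode: str = "DC",
    seed: int = 0,
    network: CoexpressionNetwork | None = None,
) -> tuple[IconProblem, FluxSolution]:
    """Template -> bounds -> network -> pair set -> quadratic solve."""
    T = max(1000.0, 10.0 * float(expression.values.max()))
    template = build_template(model, mode=mode, carbon_source=carbon_source, T=T)
    bounds = reaction_bounds_for_condition(template, expression, condition)
    if network is None:
        C = correlation_matrix(expression)
        network = CoexpressionNetwork(
            genes=list(expression.genes),
            adjacency=binarize(C, threshold),
            threshold=threshold,
        )
    R = build_pair_set(network, template, bounds)
    problem = IconProblem(template=template, bounds=bounds, R=R, alpha=alpha, seed=seed)
    return problem, solve_icon(problem)


def recovery_experiment(
    n_conditions: int = 8,
    seed: int = 0,
    noise_sd: float | None = None,
    network_conditions: int | None = None,
) -> dict:
    """Route-recovery on the two-pathway branch fixture.

    Pathway 1's genes are co-expressed with the biomass gene; the biomass
    gene's expression scale (0.8 vs 1.0) makes the biomass cap the E-flux
    bottleneck, so the whole optimum z* can run through either pathway.
    The network pairs reward pathway 1, which should therefore carry the
    flux; accuracy is the uncentered correlation with that target route.

    ``network_conditions`` restricts the co-expression network to the first
    k conditions of the dataset while expression caps and the condition of
    interest stay fixed, isolating the effect of network quality (the
    varying-N robustness design).
    """
    spec = ToySpec(n_pathways=2, pathway_length=2, n_conditions=n_conditions, seed=seed)
    if noise_sd is not None:
        spec.noise_sd = noise_sd
    model = gen_toy_model(spec)
    blocks = default_blocks(model)
    genes = sorted(blocks)
    scale = {g: (0.8 if g == "g_bio" else 1.0) for g in genes}
    expression = gen_expression(spec, genes, blocks, gene_scale=scale)
    condition = expression.conditions[-1]

    network = None
    if network_conditions is not None:
        if not 2 <= network_conditions <= n_conditions:
            raise ValueError("network_conditions must lie in [2, n_conditions]")
        sub = ExpressionMatrix(
            genes=list(expression.genes),
            conditions=expression.conditions[:network_conditions],
            values=expression.values[:, :network_conditions],
        )
        network = CoexpressionNetwork(
            genes=list(sub.genes),
            adjacency=binarize(correlation_matrix(sub), TOY_THRESHOLD),
            threshold=TOY_THRESHOLD,
        )
    problem, solution = run_pipeline(
        model, expression, condition, seed=seed, network=network
    )

    truth = ground_truth_fluxes(model, pathway=1)
    predicted = solution.net_flux_by_reaction(problem.template)
    order = model.reaction_ids
    accuracy = uncentered_pearson(
        [predicted[r] for r in order], [truth[r] for r in order]
    )
    z = solution.z_star
    share = predicted["P1R1"] / z if z > 0 else float("nan")
    return {
        "model": model,
        "expression": expression,
        "condition": condition,
        "problem": problem,
        "solution": solution,
        "accuracy": accuracy,
        "pathway1_share": share,
    }


def robustness_curve(
    n_conditions_list: tuple[int, ...] = (3, 5, 10, 20),
    seed: int = 0,
    replicates: int = 40,
) -> dict[int, float]:
    """Prediction accuracy versus the number of network conditions N.

    Paired design emulating a subsampled-dataset robustness study: each
    replicate draws one dataset with max(N) conditions, then builds the
    co-expression network from its first N conditions for every N while the
    expression caps and the condition of interest stay fixed, so accuracy
    differences across N reflect network quality alone.  Accuracies are
    averaged over replicate dataset draws seeded from the master seed;
    deterministic for a given seed.
    """
    n_max = max(n_conditions_list)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(replicates)
    accs_by_n: dict[int, list[float]] = {N: [] for N in n_conditions_list}
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        for N in n_conditions_list:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = recovery_experiment(
                    n_conditions=n_max, seed=rep_seed, network_conditions=N
                )
            accs_by_n[N].append(out["accuracy"])
    return {N: float(np.mean(accs_by_n[N])) for N in n_conditions_list}
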