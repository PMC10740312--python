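import numpy as np
import pytest

from icongems import (
    MetabolicModel,
    ToySpec,
    build_template,
    gen_toy_model,
)


@pytest.fixture
def toy_spec():
    return ToySpec(n_pathways=2, pathway_length=2, n_conditions=8, seed=0)


@pytest.fixture
def toy_model(toy_spec):
    return gen_toy_model(toy_spec)


@pytest.fixture
def toy_template(toy_model):
    return build_template(toy_model, mode="DC", carbon_source="EX_glc", T=1000.0)


def branch_setup(f1=10.0, f2=10.0, fb=10.0, pair="r1-bm"):
    """Two parallel single-step routes A -> B feeding biomass.

    Returns (template, bounds, R); R rewards the r1/biomass pair, or is
    empty for pair=None.  Expression caps: f(r1)=f1, f(r2)=f2, f(BM)=fb.
    """
    from icongems.coexpr_net import ExpressionMatrix
    from icongems.gpr_map import ReactionPairSet, reaction_bounds_for_condition

    S = np.array(
        [
            # EX_A  r1    r2    BM   EX_bio
            [-1.0, -1.0, -1.0, 0.0, 0.0],   # A
            [0.0, 1.0, 1.0, -1.0, 0.0],     # B
            [0.0, 0.0, 0.0, 1.0, -1.0],     # bio
        ]
    )
    model = MetabolicModel(
        metabolite_ids=["A", "B", "bio"],
        reaction_ids=["EX_A", "r1", "r2", "BIOMASS", "EX_bio"],
        S=S,
        lower_bounds=np.array([-10.0, 0.0, 0.0, 0.0, 0.0]),
        upper_bounds=np.array([1000.0] * 5),
        gpr=["", "g1", "g2", "gb", ""],
        subsystem=["Exchange", "Route 1", "Route 2", "Biomass", "Exchange"],
        objective_reaction="BIOMASS",
        exchange_flags=np.array([True, False, False, False, True]),
        metabolite_formulas=["C6H12O6", "C3H6O3", "R"],
    )
    template = build_template(model, "DC", carbon_source="EX_A", T=1000.0)
    genes = {"g1": f1, "g2": f2, "gb": fb}
    expr = ExpressionMatrix(
        genes=sorted(genes),
        conditions=["c1", "c2"],
        values=np.array([[genes[g]] * 2 for g in sorted(genes)]),
    )
    bounds = reaction_bounds_for_condition(template, expr, "c1")
    if pair is None:
        R = ReactionPairSet(pairs=set())
    else:
        c_r1 = template.columns_for_reaction("r1")[0]
        c_bm = template.columns_for_reaction("BIOMASS")[0]
        R = ReactionPairSet(pairs={(min(c_r1, c_bm), max(c_r1, c_bm))})
    return template, bounds, R


@pytest.fixture
def chain_model():
    """EX -> A -> B -> biomass linear chain, all irreversible."""
    # reactions: EX_s (uptake, reversible), R1: s->a, R2: a->b, BIOMASS: b->bio, EX_bio
    S = np.array(
        [
            # EX_s  R1   R2   BM  EX_bio
            [-1.0, -1.0, 0.0, 0.0, 0.0],  # s (negative EX flux = uptake)
            [0.0, 1.0, -1.0, 0.0, 0.0],   # a
            [0.0, 0.0, 1.0, -1.0, 0.0],   # b
            [0.0, 0.0, 0.0, 1.0, -1.0],   # bio
        ]
    )
    return MetabolicModel(
        metabolite_ids=["s", "a", "b", "bio"],
        reaction_ids=["EX_s", "R1", "R2", "BIOMASS", "EX_bio"],
        S=S,
        lower_bounds=np.array([-10.0, 0.0, 0.0, 0.0, 0.0]),
        upper_bounds=np.array([1000.0] * 5),
        gpr=["", "g1", "g2", "gb", ""],
        subsystem=["Exchange", "Upper", "Lower", "Biomass", "Exchange"],
        objective_reaction="BIOMASS",
        exchange_flags=np.array([True, False, False, False, True]),
        metabolite_formulas=["C6H12O6", "C3H6O3", "C3H6O3", "R"],
    )
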