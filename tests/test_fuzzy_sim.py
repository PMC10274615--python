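"""Fuzzy-logic Boolean-network compilation, simulation and impact scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkpath.fi_classifier import FIScoreTable
from darkpath.fuzzy_sim import (
    BooleanNetwork,
    Perturbation,
    ReactionNode,
    auc_impact,
    default_initial_state,
    hill,
    pathway_to_network,
    simulate,
    simulation_scores,
)
from darkpath.pathway_model import pathway_db_from_dict


def chain_network(hill_K=0.5, hill_n=4.0):
    """A -> B: single reaction, A clamped source, B produced."""
    return BooleanNetwork(
        entity_nodes=["A", "B"],
        reactions=[ReactionNode(id="r", inputs=("A",), outputs=("B",))],
        hill_K=hill_K,
        hill_n=hill_n,
    )


# -- hill --------------------------------------------------------------------


def test_hill_half_saturation():
    assert hill(0.5, 0.5, 4) == pytest.approx(0.5)
    assert hill(0.3, 0.3, 2) == pytest.approx(0.5)


def test_hill_zero_and_unit_input():
    assert hill(0.0, 0.5, 4) == 0.0
    assert hill(1.0, 0.5, 4) == pytest.approx(1 / 1.0625)


@pytest.mark.parametrize("x,K,n", [(-0.1, 0.5, 4), (1.1, 0.5, 4),
                                   (0.5, 0.0, 4), (0.5, 0.5, 0.5)])
def test_hill_domain_violations(x, K, n):
    with pytest.raises(ValueError):
        hill(x, K, n)


# -- compilation -------------------------------------------------------------


def test_single_reaction_compilation(toy_db):
    net = pathway_to_network(toy_db, "top")
    assert net.reaction_nodes == ["r1"]
    assert set(net.entity_nodes) == {"eA", "eB", "cx"}
    roles = {(s, t, r) for s, t, r in net.edges}
    assert ("eA", "r1", "input") in roles
    assert ("eB", "r1", "catalyst") in roles
    assert ("r1", "cx", "output") in roles


def test_compilation_deterministic_order(synth_db):
    pid = synth_db.top_level[0]
    n1 = pathway_to_network(synth_db, pid)
    n2 = pathway_to_network(synth_db, pid)
    assert n1.entity_nodes == n2.entity_nodes
    assert n1.reaction_nodes == n2.reaction_nodes


def test_pathway_without_reactions_rejected():
    db = pathway_db_from_dict(
        {"schema_version": 1,
         "pathways": [{"id": "p", "name": "p", "children": []}],
         "top_level": ["p"]}
    )
    with pytest.raises(ValueError, match="no reactions"):
        pathway_to_network(db, "p")


# -- simulation --------------------------------------------------------------


def test_chain_converges_to_hill_of_one():
    net = chain_network()
    trace = simulate(net, steps=100, tol=1e-6)
    assert trace.converged
    assert trace.series("A")[-1] == 1.0
    assert trace.series("B")[-1] == pytest.approx(hill(1.0, 0.5, 4), abs=1e-6)


def test_null_perturbation_reproduces_baseline():
    net = chain_network()
    base = simulate(net, steps=50, tol=0.0)
    null1 = simulate(net, steps=50, tol=0.0, pert=Perturbation("none"))
    null2 = simulate(net, steps=50, tol=0.0,
                     pert=Perturbation("activation", {"A": 0.0, "B": 0.0}))
    assert np.array_equal(base.values, null1.values)
    assert np.array_equal(base.values, null2.values)


def test_large_tolerance_converges_fast():
    net = chain_network()
    trace = simulate(net, steps=100, tol=0.95)
    assert trace.converged and trace.steps <= 2


def test_invalid_initial_state():
    with pytest.raises(ValueError):
        simulate(chain_network(), init={"A": 1.5, "B": 0.0})


def test_perturbation_validation():
    with pytest.raises(ValueError):
        Perturbation("activation", {"A": 1.5})
    with pytest.raises(ValueError):
        Perturbation("sideways")


def random_network(rng: np.random.Generator) -> BooleanNetwork:
    n_ent = int(rng.integers(3, 8))
    ents = [f"e{i}" for i in range(n_ent)]
    n_rxn = int(rng.integers(1, 5))
    reactions = []
    for j in range(n_rxn):
        picks = list(rng.permutation(ents))
        n_in = int(rng.integers(1, 3))
        inputs = tuple(picks[:n_in])
        outputs = tuple(picks[n_in:n_in + 1 + int(rng.integers(0, 2))])
        rest = picks[n_in + len(outputs):]
        catalysts = tuple(rest[:1]) if rng.random() < 0.5 and rest else ()
        rest = rest[len(catalysts):]
        inhibitors = tuple(rest[:1]) if rng.random() < 0.4 and rest else ()
        rest = rest[len(inhibitors):]
        activators = tuple(rest[:1]) if rng.random() < 0.3 and rest else ()
        reactions.append(ReactionNode(f"r{j}", inputs, outputs, catalysts,
                                      activators, inhibitors))
    return BooleanNetwork(ents, reactions,
                          hill_K=float(rng.uniform(0.2, 0.8)),
                          hill_n=float(rng.integers(1, 6)))


def test_activities_bounded_and_null_impact_zero_on_random_networks():
    rng = np.random.default_rng(12345)
    for _ in range(100):
        net = random_network(rng)
        init = {e: float(rng.uniform(0, 1)) for e in net.entity_nodes}
        base = simulate(net, init=init, steps=30, tol=0.0)
        assert (base.values >= 0).all() and (base.values <= 1).all()
        strengths = {e: 0.0 for e in net.entity_nodes}
        for mode in ("activation", "inhibition"):
            pert = simulate(net, init=init, steps=30, tol=0.0,
                            pert=Perturbation(mode, strengths))
            assert (pert.values >= 0).all() and (pert.values <= 1).all()
            for node in net.output_entities():
                assert abs(auc_impact(base, pert, node)) <= 1e-12


def test_determinism_bit_identical_traces():
    rng = np.random.default_rng(7)
    net = random_network(rng)
    t1 = simulate(net, steps=40, tol=0.0)
    t2 = simulate(net, steps=40, tol=0.0)
    assert np.array_equal(t1.values, t2.values)


# -- impact ------------------------------------------------------------------


def const_trace(nodes, value, steps):
    vals = np.full((steps + 1, len(nodes)), value, dtype=float)
    from darkpath.fuzzy_sim import SimulationTrace

    return SimulationTrace(nodes, vals, converged=True)


def test_auc_impact_extremes():
    nodes = ["x"]
    base0 = const_trace(nodes, 0.0, 10)
    base1 = const_trace(nodes, 1.0, 10)
    assert auc_impact(base0, base0, "x") == 0.0
    assert auc_impact(base0, base1, "x") == pytest.approx(1.0)
    assert auc_impact(base1, base0, "x") == pytest.approx(-1.0)


def test_auc_impact_mismatched_traces():
    with pytest.raises(ValueError):
        auc_impact(const_trace(["x"], 0, 10), const_trace(["x"], 0, 5), "x")


# -- gene-pathway scores -----------------------------------------------------


def linear_db():
    """A -> B -> C chain over three proteins plus a fourth protein partner."""
    return pathway_db_from_dict(
        {
            "schema_version": 1,
            "genes": [{"symbol": s} for s in "ABCP"],
            "entities": [
                {"id": f"e{s}", "kind": "protein", "gene": s} for s in "ABCP"
            ],
            "reactions": [
                {"id": "r1", "inputs": ["eA"], "outputs": ["eB"]},
                {"id": "r2", "inputs": ["eB"], "outputs": ["eC"]},
            ],
            "pathways": [
                {"id": "p", "name": "chain", "children": ["r1", "r2"]}
            ],
            "top_level": ["p"],
        }
    )


def test_zero_strength_scores_are_zero():
    db = linear_db()
    scores = FIScoreTable({("A", "P"): 0.0})
    res = simulation_scores("P", scores, db, "p")
    assert res.average_activation == 0.0 and res.average_inhibition == 0.0


def test_activation_positive_inhibition_negative_on_chain():
    db = linear_db()
    # P's single partner is A, the clamped source of the chain: activating A
    # cannot raise it above 1, so perturb the produced node B instead by
    # pairing P with B
    scores = FIScoreTable({("B", "P"): 1.0})
    res = simulation_scores("P", scores, db, "p", steps=50)
    assert res.average_activation > 0
    assert res.average_inhibition < 0
    outputs = set(res.per_output_activation)
    assert outputs == {"eB", "eC"}
    assert res.average_activation == pytest.approx(
        np.mean(list(res.per_output_activation.values()))
    )
    assert res.average_inhibition == pytest.approx(
        np.mean(list(res.per_output_inhibition.values()))
    )


def test_activation_strength_sweep_monotone():
    db = linear_db()
    values = []
    for s in np.linspace(0, 1, 6):
        res = simulation_scores("P", FIScoreTable({("B", "P"): float(s)}),
                                db, "p", steps=50)
        values.append(res.average_activation)
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
    assert values[0] == 0.0 and values[-1] > 0


def test_gene_without_pathway_partner_warns():
    db = linear_db()
    scores = FIScoreTable({("P", "Z"): 0.9})
    with pytest.warns(UserWarning, match="no FI partner"):
        res = simulation_scores("P", scores, db, "p")
    assert res.average_activation == 0.0 and res.average_inhibition == 0.0


def test_default_initial_state_fully_active():
    net = chain_network()
    init = default_initial_state(net)
    assert init == {"A": 1.0, "B": 1.0}
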