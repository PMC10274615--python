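"""Fuzzy-logic Boolean-network simulation of pathways.

A pathway's reactions compile into a bipartite network of entity nodes
(activity in [0, 1]) and reaction transfer nodes. Updates are synchronous
in discrete time. A reaction's firing level is the fuzzy-AND (min) of the
Hill-transformed activities of its inputs and catalysts, attenuated by
prod(1 - hill(inhibitor)) over its inhibitors, and fuzzy-OR'd (max) with
the Hill-transformed activities of its activators. A produced entity takes
the fuzzy-OR (max) over the firing levels of its producing reactions;
source entities (nothing produces them) are clamped to their initial value.

Interacting-pathway simulation scores compare a baseline run against a
perturbed run in which a gene's FI prediction scores are injected onto its
partner entities, either as activation (max-combined) or inhibition
(multiplicative 1 - s). The impact on each reaction-output entity is the
difference in time-course area under the curve, normalized by the horizon;
the reported activation / inhibition score for a gene-pathway pair is the
mean impact over the pathway's reaction outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fi_classifier import FIScoreTable
from .pathway_model import PathwayDatabase


def hill(x: float, K: float, n: float) -> float:
    """Hill transfer function x^n / (K^n + x^n) on [0, 1]."""
    if not 0 <= x <= 1:
        raise ValueError(f"activity out of [0, 1]: {x}")
    if K <= 0:
        raise ValueError("K must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    if x == 0:
        return 0.0
    return x ** n / (K ** n + x ** n)


@dataclass(frozen=True)
class ReactionNode:
    id: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    catalysts: tuple[str, ...] = ()
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()


@dataclass
class BooleanNetwork:
    """Compiled fuzzy-logic network for one pathway."""

    entity_nodes: list[str]
    reactions: list[ReactionNode]
    hill_K: float = 0.5
    hill_n: float = 4.0

    def __post_init__(self) -> None:
        for r in self.reactions:
            if not r.inputs or not r.outputs:
                raise ValueError(f"reaction node {r.id} lacks inputs or outputs")
        known = set(self.entity_nodes)
        for r in self.reactions:
            for eid in r.inputs + r.outputs + r.catalysts + r.activators + r.inhibitors:
                if eid not in known:
                    raise ValueError(f"reaction {r.id} references unknown entity {eid}")

    @property
    def reaction_nodes(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        """(source, target, role) triples; outputs point reaction -> entity."""
        out = []
        for r in self.reactions:
            for role in ("inputs", "catalysts", "activators", "inhibitors"):
                for eid in getattr(r, role):
                    out.append((eid, r.id, role[:-1]))
            for eid in r.outputs:
                out.append((r.id, eid, "output"))
        return out

    def produced_entities(self) -> dict[str, list[int]]:
        """entity -> indices of reactions producing it."""
        prod: dict[str, list[int]] = {}
        for i, r in enumerate(self.reactions):
            for eid in r.outputs:
                prod.setdefault(eid, []).append(i)
        return prod

    def output_entities(self) -> list[str]:
        """Entities appearing as an output of >= 1 reaction, deduplicated, ordered."""
        seen: set[str] = set()
        out: list[str] = []
        for r in self.reactions:
            for eid in r.outputs:
                if eid not in seen:
                    seen.add(eid)
                    out.append(eid)
        return out

    def source_entities(self) -> list[str]:
        produced = set(self.produced_entities())
        return [e for e in self.entity_nodes if e not in produced]


@dataclass
class Perturbation:
    """FI prediction scores injected onto entity nodes.

    ``activation`` max-combines each target's strength with its computed
    activity; ``inhibition`` multiplies the activity by (1 - strength).
    Strength 0 is the exact null in both modes.
    """

    mode: str = "none"
    targets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("none", "activation", "inhibition"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        for node, s in self.targets.items():
            if not 0 <= s <= 1:
                raise ValueError(f"perturbation strength out of [0, 1] for {node}: {s}")

    def apply(self, state: dict[str, float]) -> None:
        if self.mode == "none":
            return
        for node, s in self.targets.items():
            if node not in state:
                continue
            if self.mode == "activation":
                state[node] = max(state[node], s)
            else:
                state[node] = state[node] * (1.0 - s)


@dataclass
class SimulationTrace:
    """Entity activities over steps 0..T (T+1 rows)."""

    nodes: list[str]
    values: np.ndarray
    converged: bool

    @property
    def steps(self) -> int:
        return self.values.shape[0] - 1

    def series(self, node: str) -> np.ndarray:
        return self.values[:, self.nodes.index(node)]


def pathway_to_network(
    db: PathwayDatabase, pathway_id: str, hill_K: float = 0.5, hill_n: float = 4.0
) -> BooleanNetwork:
    """Compile one pathway's reactions into a fuzzy-logic network.

    One entity node per participating entity (complexes stay single nodes),
    one transfer node per reaction; role edges preserved; node order is
    deterministic (sorted reaction ids, entities by first appearance).
    """
    rids = db.descendant_reactions(pathway_id)
    if not rids:
        raise ValueError(f"pathway {pathway_id!r} has no reactions")
    entity_order: list[str] = []
    seen: set[str] = set()
    rnodes: list[ReactionNode] = []
    for rid in rids:
        rxn = db.reactions[rid]
        for eid in rxn.inputs + rxn.outputs + rxn.catalysts + rxn.activators + rxn.inhibitors:
            if eid not in seen:
                seen.add(eid)
                entity_order.append(eid)
        rnodes.append(
            ReactionNode(
                id=rid,
                inputs=rxn.inputs,
                outputs=rxn.outputs,
                catalysts=rxn.catalysts,
                activators=rxn.activators,
                inhibitors=rxn.inhibitors,
            )
        )
    return BooleanNetwork(entity_order, rnodes, hill_K=hill_K, hill_n=hill_n)


def default_initial_state(net: BooleanNetwork) -> dict[str, float]:
    """Every entity starts fully active (1.0); sources stay clamped there.

    A resting state of full activity gives the baseline run a live steady
    state, so that inhibitory perturbations have activity to remove — with
    dead produced entities, AND-gated reactions would never fire and every
    inhibition impact would be structurally zero.
    """
    return {e: 1.0 for e in net.entity_nodes}


def simulate(
    net: BooleanNetwork,
    init: dict[str, float] | None = None,
    steps: int = 100,
    tol: float = 1e-6,
    pert: Perturbation | None = None,
) -> SimulationTrace:
    """Synchronous fuzzy-logic simulation.

    Runs for ``steps`` updates or until the maximum node change drops below
    ``tol`` (converged flag set; pass tol=0 to force the full horizon, which
    keeps traces comparable across runs). The perturbation is applied to
    the state at every step, including the initial one.
    """
    init = init if init is not None else default_initial_state(net)
    for node, v in init.items():
        if not 0 <= v <= 1:
            raise ValueError(f"initial activity out of [0, 1] for {node}: {v}")
    pert = pert if pert is not None else Perturbation()
    produced = net.produced_entities()
    clamped = {e: init.get(e, 0.0) for e in net.source_entities()}
    K, n = net.hill_K, net.hill_n

    state = {e: init.get(e, 0.0) for e in net.entity_nodes}
    pert.apply(state)
    rows = [[state[e] for e in net.entity_nodes]]
    converged = False
    for _ in range(steps):
        h = {e: hill(state[e], K, n) for e in net.entity_nodes}
        firing: list[float] = []
        for r in net.reactions:
            f = min(h[e] for e in r.inputs + r.catalysts)
            for e in r.inhibitors:
                f *= 1.0 - h[e]
            for e in r.activators:
                f = max(f, h[e])
            if not math.isfinite(f):
                raise ArithmeticError(f"non-finite firing level for reaction {r.id}")
            firing.append(f)
        new_state: dict[str, float] = {}
        for e in net.entity_nodes:
            if e in produced:
                new_state[e] = max(firing[i] for i in produced[e])
            else:
                new_state[e] = clamped[e]
        pert.apply(new_state)
        delta = max(abs(new_state[e] - state[e]) for e in net.entity_nodes)
        state = new_state
        rows.append([state[e] for e in net.entity_nodes])
        if tol > 0 and delta < tol:
            converged = True
            break
    return SimulationTrace(list(net.entity_nodes), np.array(rows, dtype=float), converged)


def auc_impact(baseline: SimulationTrace, perturbed: SimulationTrace, node: str) -> float:
    """(AUC_perturbed - AUC_baseline) / T with trapezoidal AUC; in [-1, 1]."""
    if baseline.nodes != perturbed.nodes or baseline.steps != perturbed.steps:
        raise ValueError("traces do not share nodes and horizon")
    if baseline.steps < 1:
        raise ValueError("need at least one step")
    t = baseline.steps
    auc_b = float(np.trapezoid(baseline.series(node)))
    auc_p = float(np.trapezoid(perturbed.series(node)))
    return (auc_p - auc_b) / t


@dataclass
class ImpactResult:
    """Signed per-output impacts and their means for the two assumed FI modes."""

    per_output_activation: dict[str, float]
    per_output_inhibition: dict[str, float]
    average_activation: float
    average_inhibition: float


def simulation_scores(
    gene: str,
    fi_scores: FIScoreTable,
    db: PathwayDatabase,
    pathway_id: str,
    hill_K: float = 0.5,
    hill_n: float = 4.0,
    steps: int = 100,
) -> ImpactResult:
    """Activation and inhibition simulation scores for a gene-pathway pair.

    The gene's FI prediction scores are injected onto the pathway's protein
    entity nodes matching its partner genes; since the FI mode is not
    predicted, one run assumes all injected FIs activate and one assumes
    they all inhibit. Runs use the full fixed horizon so baseline and
    perturbed traces are directly comparable.
    """
    gene = gene.upper()
    net = pathway_to_network(db, pathway_id, hill_K=hill_K, hill_n=hill_n)
    strengths: dict[str, float] = {}
    for (a, b), s in fi_scores.items():
        if gene not in (a, b):
            continue
        partner = b if a == gene else a
        for eid in net.entity_nodes:
            ent = db.entities[eid]
            if ent.kind == "protein" and ent.gene == partner:
                strengths[eid] = max(strengths.get(eid, 0.0), float(s))
    outputs = net.output_entities()
    if not strengths:
        warnings.warn(
            f"gene {gene} has no FI partner in pathway {pathway_id}", stacklevel=2
        )
        zeros = {e: 0.0 for e in outputs}
        return ImpactResult(zeros, dict(zeros), 0.0, 0.0)
    baseline = simulate(net, steps=steps, tol=0.0)
    act = simulate(net, steps=steps, tol=0.0,
                   pert=Perturbation("activation", strengths))
    inh = simulate(net, steps=steps, tol=0.0,
                   pert=Perturbation("inhibition", strengths))
    per_act = {e: auc_impact(baseline, act, e) for e in outputs}
    per_inh = {e: auc_impact(baseline, inh, e) for e in outputs}
    return ImpactResult(
        per_act,
        per_inh,
        float(np.mean(list(per_act.values()))) if per_act else 0.0,
        float(np.mean(list(per_inh.values()))) if per_inh else 0.0,
    )


def trace_to_csv(trace: SimulationTrace, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("step,node,activity\n")
        for t in range(trace.values.shape[0]):
            for j, node in enumerate(trace.nodes):
                fh.write(f"{t},{node},{trace.values[t, j]:.9f}\n")
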