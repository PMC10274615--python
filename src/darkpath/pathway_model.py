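"""Reaction-level pathway data model.

A :class:`PathwayDatabase` holds a small, self-contained event hierarchy in
the style of curated pathway knowledgebases: pathways contain sub-pathways
and reactions; reactions connect physical entities (proteins, complexes,
entity sets, small molecules) through input / output / catalyst / activator /
inhibitor roles. From this structure the package derives

* per-event gene sets (genes propagate up the hierarchy), used as the
  background for pathway enrichment and exported as GMT;
* reference functional interactions (FIs): undirected gene pairs co-occurring
  in complexes or reactions, used as classifier positives.

The on-disk format is a versioned JSON document (see ``load_pathway_db``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._pairs import Pair, canonical_pair

TDL_LEVELS = frozenset({"Tdark", "Tbio", "Tchem", "Tclin", "unknown"})
ENTITY_KINDS = frozenset({"protein", "complex", "set", "small_molecule"})
REACTION_ROLES = ("inputs", "outputs", "catalysts", "activators", "inhibitors")

SCHEMA_VERSION = 1


class PathwayDBError(ValueError):
    """Raised on schema violations, dangling references or hierarchy cycles."""


@dataclass(frozen=True)
class Gene:
    """A gene, identified by its canonical (uppercase) symbol.

    ``tdl`` is the target development level of the protein product:
    Tdark (understudied), Tbio, Tchem, Tclin, or unknown.
    """

    symbol: str
    uniprot: str | None = None
    tdl: str = "unknown"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PathwayDBError("gene symbol must be non-empty")
        if self.symbol != self.symbol.upper():
            raise PathwayDBError(f"gene symbol not canonical: {self.symbol!r}")
        if self.tdl not in TDL_LEVELS:
            raise PathwayDBError(f"unknown tdl {self.tdl!r} for gene {self.symbol}")


@dataclass(frozen=True)
class PhysicalEntity:
    """A protein, complex, entity set or small molecule.

    Proteins carry a gene symbol; complexes and sets carry component entity
    ids that must resolve within the database.
    """

    id: str
    kind: str
    gene: str | None = None
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise PathwayDBError(f"entity {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "protein":
            if not self.gene:
                raise PathwayDBError(f"protein entity {self.id!r} lacks a gene")
            if self.components:
                raise PathwayDBError(f"protein entity {self.id!r} has components")
        elif self.kind in ("complex", "set"):
            if not self.components:
                raise PathwayDBError(f"{self.kind} entity {self.id!r} has no components")


@dataclass(frozen=True)
class Reaction:
    id: str
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    catalysts: tuple[str, ...] = ()
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()
    summation: str | None = None

    def __post_init__(self) -> None:
        if not self.inputs or not self.outputs:
            raise PathwayDBError(f"reaction {self.id!r} needs >=1 input and >=1 output")
        seen: set[str] = set()
        for role in REACTION_ROLES:
            ids = getattr(self, role)
            overlap = seen.intersection(ids)
            if overlap:
                raise PathwayDBError(
                    f"reaction {self.id!r}: entity {sorted(overlap)} in multiple roles"
                )
            seen.update(ids)

    def role_entities(self) -> dict[str, tuple[str, ...]]:
        return {role: getattr(self, role) for role in REACTION_ROLES}


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    children: tuple[str, ...] = ()
    summation: str | None = None


@dataclass
class PathwayDatabase:
    """Id-keyed maps of genes, entities, reactions and pathways.

    Construction validates referential integrity and the DAG property of the
    event hierarchy; a valid instance never has dangling references.
    """

    genes: dict[str, Gene] = field(default_factory=dict)
    entities: dict[str, PhysicalEntity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)
    top_level: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for ent in self.entities.values():
            if ent.kind == "protein" and ent.gene not in self.genes:
                raise PathwayDBError(f"entity {ent.id!r}: unknown gene {ent.gene!r}")
            for comp in ent.components:
                if comp not in self.entities:
                    raise PathwayDBError(f"entity {ent.id!r}: missing component {comp!r}")
        for rxn in self.reactions.values():
            for role, ids in rxn.role_entities().items():
                for eid in ids:
                    if eid not in self.entities:
                        raise PathwayDBError(
                            f"reaction {rxn.id!r}: missing {role[:-1]} entity {eid!r}"
                        )
        for pw in self.pathways.values():
            for child in pw.children:
                if child not in self.pathways and child not in self.reactions:
                    raise PathwayDBError(f"pathway {pw.id!r}: missing child event {child!r}")
        for pid in self.top_level:
            if pid not in self.pathways:
                raise PathwayDBError(f"top_level references missing pathway {pid!r}")
        self._check_acyclic()
        self._check_entity_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done
        stack: list[str] = []

        def visit(pid: str) -> None:
            if state.get(pid) == 1:
                return
            if state.get(pid) == 0:
                cycle = stack[stack.index(pid):] + [pid]
                raise PathwayDBError(f"cycle in event hierarchy: {' -> '.join(cycle)}")
            state[pid] = 0
            stack.append(pid)
            for child in self.pathways[pid].children:
                if child in self.pathways:
                    visit(child)
            stack.pop()
            state[pid] = 1

        for pid in self.pathways:
            visit(pid)

    def _check_entity_acyclic(self) -> None:
        state: dict[str, int] = {}
        stack: list[str] = []

        def visit(eid: str) -> None:
            if state.get(eid) == 1:
                return
            if state.get(eid) == 0:
                cycle = stack[stack.index(eid):] + [eid]
                raise PathwayDBError(f"cycle in entity composition: {' -> '.join(cycle)}")
            state[eid] = 0
            stack.append(eid)
            for comp in self.entities[eid].components:
                visit(comp)
            stack.pop()
            state[eid] = 1

        for eid in self.entities:
            visit(eid)

    # -- derived structure ---------------------------------------------------

    def entity_genes(self, entity_id: str) -> set[str]:
        """Gene symbols of an entity, flattening complexes and sets recursively."""
        ent = self.entities[entity_id]
        if ent.kind == "protein":
            return {ent.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for comp in ent.components:
            out |= self.entity_genes(comp)
        return out

    def descendant_reactions(self, event_id: str) -> list[str]:
        """Reaction ids reachable from an event, in deterministic (sorted) order."""
        if event_id in self.reactions:
            return [event_id]
        if event_id not in self.pathways:
            raise PathwayDBError(f"unknown event id {event_id!r}")
        found: set[str] = set()
        todo = [event_id]
        while todo:
            pid = todo.pop()
            for child in self.pathways[pid].children:
                if child in self.reactions:
                    found.add(child)
                else:
                    todo.append(child)
        return sorted(found)

    def descendant_events(self, pathway_id: str) -> list[str]:
        """All event ids (sub-pathways and reactions) strictly inside a pathway.

        Deterministic order: breadth-first in child order, deduplicated.
        """
        if pathway_id not in self.pathways:
            raise PathwayDBError(f"unknown pathway id {pathway_id!r}")
        out: list[str] = []
        seen: set[str] = set()
        queue = list(self.pathways[pathway_id].children)
        while queue:
            eid = queue.pop(0)
            if eid in seen:
                continue
            seen.add(eid)
            out.append(eid)
            if eid in self.pathways:
                queue.extend(self.pathways[eid].children)
        return out


# -- I/O -------------------------------------------------------------------


def load_pathway_db(path: str | Path) -> PathwayDatabase:
    """Load a pathway database from its JSON document.

    The document has a ``schema_version`` plus four arrays: ``genes``
    (symbol, optional uniprot, optional tdl), ``entities`` (id, kind, gene or
    components), ``reactions`` (id, role lists, optional summation),
    ``pathways`` (id, name, children, optional summation) and a ``top_level``
    list of pathway ids. Gene symbols are uppercased at load.
    """
    with open(path) as fh:
        doc = json.load(fh)
    return pathway_db_from_dict(doc)


def pathway_db_from_dict(doc: dict) -> PathwayDatabase:
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise PathwayDBError(f"unsupported schema_version {version!r}")
    genes: dict[str, Gene] = {}
    for g in doc.get("genes", []):
        sym = str(g["symbol"]).upper()
        if sym in genes:
            raise PathwayDBError(f"duplicate gene symbol {sym!r}")
        genes[sym] = Gene(symbol=sym, uniprot=g.get("uniprot"), tdl=g.get("tdl", "unknown"))
    entities: dict[str, PhysicalEntity] = {}
    for e in doc.get("entities", []):
        if e["id"] in entities:
            raise PathwayDBError(f"duplicate entity id {e['id']!r}")
        gene = e.get("gene")
        entities[e["id"]] = PhysicalEntity(
            id=e["id"],
            kind=e["kind"],
            gene=str(gene).upper() if gene else None,
            components=tuple(e.get("components", ())),
        )
    reactions: dict[str, Reaction] = {}
    for r in doc.get("reactions", []):
        if r["id"] in reactions:
            raise PathwayDBError(f"duplicate reaction id {r['id']!r}")
        reactions[r["id"]] = Reaction(
            id=r["id"],
            inputs=tuple(r.get("inputs", ())),
            outputs=tuple(r.get("outputs", ())),
            catalysts=tuple(r.get("catalysts", ())),
            activators=tuple(r.get("activators", ())),
            inhibitors=tuple(r.get("inhibitors", ())),
            summation=r.get("summation"),
        )
    pathways: dict[str, Pathway] = {}
    for p in doc.get("pathways", []):
        if p["id"] in pathways:
            raise PathwayDBError(f"duplicate pathway id {p['id']!r}")
        if p["id"] in reactions:
            raise PathwayDBError(f"id {p['id']!r} used for both pathway and reaction")
        pathways[p["id"]] = Pathway(
            id=p["id"],
            name=p.get("name", p["id"]),
            children=tuple(p.get("children", ())),
            summation=p.get("summation"),
        )
    return PathwayDatabase(
        genes=genes,
        entities=entities,
        reactions=reactions,
        pathways=pathways,
        top_level=list(doc.get("top_level", [])),
    )


def pathway_db_to_dict(db: PathwayDatabase) -> dict:
    """Serialize a database to the JSON document structure (stable key order)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "genes": [
            {"symbol": g.symbol, "uniprot": g.uniprot, "tdl": g.tdl}
            for g in (db.genes[k] for k in sorted(db.genes))
        ],
        "entities": [
            {
                "id": e.id,
                "kind": e.kind,
                **({"gene": e.gene} if e.gene else {}),
                **({"components": list(e.components)} if e.components else {}),
            }
            for e in (db.entities[k] for k in sorted(db.entities))
        ],
        "reactions": [
            {
                "id": r.id,
                "inputs": list(r.inputs),
                "outputs": list(r.outputs),
                "catalysts": list(r.catalysts),
                "activators": list(r.activators),
                "inhibitors": list(r.inhibitors),
                "summation": r.summation,
            }
            for r in (db.reactions[k] for k in sorted(db.reactions))
        ],
        "pathways": [
            {
                "id": p.id,
                "name": p.name,
                "children": list(p.children),
                "summation": p.summation,
            }
            for p in (db.pathways[k] for k in sorted(db.pathways))
        ],
        "top_level": list(db.top_level),
    }


def save_pathway_db(db: PathwayDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(pathway_db_to_dict(db), fh, indent=1, sort_keys=False)
        fh.write("\n")


# -- gene sets and reference FIs -------------------------------------------


def event_gene_set(db: PathwayDatabase, event_id: str) -> set[str]:
    """Union of gene symbols reachable through an event's descendant reactions.

    Includes genes of all entities in every role, flattening complexes and
    sets; genes propagate up the hierarchy (a pathway's set contains each
    child's set).
    """
    out: set[str] = set()
    for rid in db.descendant_reactions(event_id):
        rxn = db.reactions[rid]
        for ids in rxn.role_entities().values():
            for eid in ids:
                out |= db.entity_genes(eid)
    return out


def extract_reference_fis(
    db: PathwayDatabase, include_regulators: bool = False
) -> set[Pair]:
    """Extract reference functional interactions as canonical gene pairs.

    Pair classes emitted:

    * every two distinct protein components of a common complex (nested
      complexes and sets flattened);
    * every (input, catalyst) gene pair of a reaction;
    * every (input, input) gene pair of a reaction;
    * with ``include_regulators``, (input, activator/inhibitor) pairs too —
      off by default because regulation edges are directional while the FI
      set is undirected.
    """
    fis: set[Pair] = set()

    def add_clique(genes: Iterable[str]) -> None:
        gl = sorted(set(genes))
        for i, a in enumerate(gl):
            for b in gl[i + 1:]:
                fis.add((a, b))

    def add_cross(left: set[str], right: set[str]) -> None:
        for a in left:
            for b in right:
                if a != b:
                    fis.add(canonical_pair(a, b))

    for ent in db.entities.values():
        if ent.kind == "complex":
            add_clique(db.entity_genes(ent.id))

    for rxn in db.reactions.values():
        input_genes: set[str] = set()
        for eid in rxn.inputs:
            input_genes |= db.entity_genes(eid)
        catalyst_genes: set[str] = set()
        for eid in rxn.catalysts:
            catalyst_genes |= db.entity_genes(eid)
        add_clique(input_genes)
        add_cross(input_genes, catalyst_genes)
        if include_regulators:
            reg_genes: set[str] = set()
            for eid in rxn.activators + rxn.inhibitors:
                reg_genes |= db.entity_genes(eid)
            add_cross(input_genes, reg_genes)
    return fis


# -- GMT -------------------------------------------------------------------


def export_gmt(db: PathwayDatabase, path: str | Path) -> None:
    """Write one GMT line per pathway: name, id, then sorted member genes."""
    with open(path, "w") as fh:
        for pid in sorted(db.pathways):
            pw = db.pathways[pid]
            genes = sorted(event_gene_set(db, pid))
            fh.write("\t".join([pw.name, pid, *genes]) + "\n")


def load_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into {set id: gene set} (second column is the id)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            out[fields[1]] = {g.upper() for g in fields[2:] if g}
    return out
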