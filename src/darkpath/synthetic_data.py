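"""Deterministic synthetic fixtures for the full pipeline.

Every external input the method consumes has a generator here: a toy
reaction-level pathway database, binary gene-pair feature channels with a
planted association to the reference FIs, an expression count matrix with
planted co-expression modules (plus a planted low-RIN sample and a planted
PCA outlier), and an abstract corpus whose on-topic abstracts reuse tokens
from their pathway's summation so the hashing embedder can separate
pathways. All generators are pure functions of (config, seed).

Default conditions mirror the shape of the real inputs at desk scale:
channel positive-coverages descend like the published top features (about
0.56 for the GO-sharing-like channel down to 0.2), channel odds-ratio
targets sit well above the 5.0 vetting gate for informative channels and
at 1.0 for null channels, and expression counts follow a Poisson-lognormal
model with one latent factor per pathway module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._pairs import Pair, all_pairs
from .feature_builder import ExpressionMatrix, FeatureChannel
from .nlp_scoring import AbstractRecord, GeneAliasSet, HashingEmbedder
from .pathway_model import (
    Gene,
    PathwayDatabase,
    Pathway,
    PhysicalEntity,
    Reaction,
    extract_reference_fis,
)

#: the hashing embedder used by every synthetic corpus (fixed constant seed)
EMBEDDER_SEED = 7

_DEFAULT_CHANNELS = (
    ("gobp_sharing", "gobp", 40.0, 0.56),
    ("human_ppi", "ppi", 25.0, 0.40),
    ("yeast_ppi_mapped", "ppi", 15.0, 0.33),
    ("domain_pfam", "domain", 10.0, 0.30),
    ("coexpr_tissue_a", "coexpression", 8.0, 0.25),
    ("coexpr_tissue_b", "coexpression", 6.0, 0.20),
    ("null_similarity_a", "similarity", 1.0, 0.10),
    ("null_similarity_b", "similarity", 1.0, 0.10),
)


@dataclass
class SyntheticConfig:
    """Conditions for the synthetic study; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 120
    n_pathways: int = 6
    pathway_size: tuple[int, int] = (6, 14)
    n_channels: int = 8
    channel_enrichment: tuple[float, ...] = tuple(c[2] for c in _DEFAULT_CHANNELS)
    channel_coverage: tuple[float, ...] = tuple(c[3] for c in _DEFAULT_CHANNELS)
    coexpr_module_rho: float = 0.7
    n_samples_or_cells: int = 200
    noise_sd: float = 0.8
    n_abstracts: int = 300
    on_topic_fraction: float = 0.5
    tdark_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_pathways < 1 or self.n_channels < 1:
            raise ValueError("all counts must be positive")
        lo, hi = self.pathway_size
        if not 2 <= lo <= hi:
            raise ValueError("pathway_size range must satisfy 2 <= lo <= hi")
        if hi > self.n_genes:
            raise ValueError("pathway_size exceeds n_genes")
        if self.n_pathways * hi > self.n_genes:
            raise ValueError(
                "pathway gene blocks are disjoint: need n_pathways * max "
                "pathway_size <= n_genes"
            )
        if len(self.channel_enrichment) < self.n_channels:
            raise ValueError("need an enrichment target per channel")
        if len(self.channel_coverage) < self.n_channels:
            raise ValueError("need a coverage per channel")
        if not 0 <= self.on_topic_fraction <= 1:
            raise ValueError("on_topic_fraction must be in [0, 1]")


def _gene_symbol(i: int) -> str:
    return f"G{i:04d}"


def make_toy_pathway_db(cfg: SyntheticConfig) -> PathwayDatabase:
    """Two-level event hierarchy with chained reactions and nested sub-pathways.

    Each top-level pathway owns a disjoint block of genes and a chain of
    reactions over it (the output of one reaction feeds the next, with
    second substrates, catalysts and occasional inhibitors drawn from the
    block), closing with the assembly of a complex from up to four members.
    The chain is covered by several overlapping reaction-window
    sub-pathways, mimicking the redundancy of curated hierarchies where a
    single biological module appears as many nested pathway entries. A
    ``tdark_fraction`` of genes is tagged Tdark. Byte-identical output
    under the same seed.
    """
    rng = np.random.default_rng(cfg.seed)
    symbols = [_gene_symbol(i) for i in range(cfg.n_genes)]
    dark = set(
        rng.choice(symbols, size=int(round(cfg.tdark_fraction * cfg.n_genes)),
                   replace=False)
    )
    genes = {
        s: Gene(symbol=s, uniprot=f"P{i:05d}", tdl="Tdark" if s in dark else "Tbio")
        for i, s in enumerate(symbols)
    }
    entities: dict[str, PhysicalEntity] = {
        f"E_{s}": PhysicalEntity(id=f"E_{s}", kind="protein", gene=s) for s in symbols
    }
    reactions: dict[str, Reaction] = {}
    pathways: dict[str, Pathway] = {}
    top_level: list[str] = []

    shuffled = list(rng.permutation(symbols))
    cursor = 0
    for p in range(cfg.n_pathways):
        size = int(rng.integers(cfg.pathway_size[0], cfg.pathway_size[1] + 1))
        members = shuffled[cursor:cursor + size]
        cursor += size
        pid = f"PW{p:03d}"
        sub_id = f"{pid}_SUB"
        topic = " ".join(f"{pid.lower()}_topic_{t}" for t in range(6))
        rxn_ids: list[str] = []
        # chained reactions covering the member genes: each reaction consumes
        # the previous product plus a second substrate, often with a catalyst
        n_rxn = max(2, size - 1)
        for j in range(n_rxn):
            rid = f"{pid}_R{j}"
            inp = members[j % size]
            out = members[(j + 1) % size]
            if inp == out:
                out = members[(j + 2) % size]
            roles = {f"E_{inp}", f"E_{out}"}
            inputs = [f"E_{inp}"]
            # co-participants drawn from anywhere in the module, the way real
            # reactions reuse shared substrates and enzymes
            second = str(rng.choice(members))
            if f"E_{second}" not in roles and rng.random() < 0.9:
                inputs.append(f"E_{second}")
                roles.add(f"E_{second}")
            catalysts: list[str] = []
            cat = str(rng.choice(members))
            if f"E_{cat}" not in roles and rng.random() < 0.9:
                catalysts = [f"E_{cat}"]
                roles.add(f"E_{cat}")
            inhibitors: list[str] = []
            inh = str(rng.choice(members))
            if f"E_{inh}" not in roles and rng.random() < 0.3:
                inhibitors = [f"E_{inh}"]
            reactions[rid] = Reaction(
                id=rid,
                inputs=tuple(inputs),
                outputs=(f"E_{out}",),
                catalysts=tuple(catalysts),
                inhibitors=tuple(inhibitors),
                summation=f"Reaction {rid} converts {inp} to {out} {topic} "
                          f"step_{j}",
            )
            rxn_ids.append(rid)
        # a complex assembled by the closing reaction
        cx_id = f"{pid}_CPLX"
        comp_genes = members[: min(4, size)]
        entities[cx_id] = PhysicalEntity(
            id=cx_id, kind="complex",
            components=tuple(f"E_{g}" for g in comp_genes),
        )
        rid = f"{pid}_RCPLX"
        reactions[rid] = Reaction(
            id=rid,
            inputs=tuple(f"E_{g}" for g in comp_genes),
            outputs=(cx_id,),
            summation=f"Reaction {rid} assembles the {pid} complex {topic}",
        )
        rxn_ids.append(rid)
        # nested sub-pathways over overlapping reaction windows, emulating the
        # redundancy of curated hierarchies (one module is described by many
        # partially overlapping pathway entries)
        m = len(rxn_ids)
        sub_ids: list[str] = []
        windows: list[tuple[int, int]] = []
        for w, n_win in ((0.6, 4), (0.45, 7)):
            wlen = max(2, math.ceil(w * m))
            for j in range(n_win):
                start = 0 if n_win == 1 else round(j * (m - wlen) / max(1, n_win - 1))
                windows.append((start, min(m, start + wlen)))
        for j, (lo, hi) in enumerate(windows):
            sid = f"{sub_id}{j}"
            pathways[sid] = Pathway(
                id=sid, name=f"{pid} sub-process {j}",
                children=tuple(rxn_ids[lo:hi]),
                summation=f"Sub-pathway {j} of {pid} covering steps {lo} to "
                          f"{hi} {topic}",
            )
            sub_ids.append(sid)
        pathways[pid] = Pathway(
            id=pid, name=f"Synthetic pathway {p}", children=tuple(sub_ids),
            summation=f"Pathway {pid} coordinates {topic} signaling",
        )
        top_level.append(pid)

    return PathwayDatabase(
        genes=genes, entities=entities, reactions=reactions,
        pathways=pathways, top_level=top_level,
    )


def pathway_members(db: PathwayDatabase, pathway_id: str) -> list[str]:
    from .pathway_model import event_gene_set

    return sorted(event_gene_set(db, pathway_id))


def make_feature_channels(
    db: PathwayDatabase, cfg: SyntheticConfig
) -> list[FeatureChannel]:
    """Binary channels with a planted association to the reference FIs.

    Channel i includes each FI pair with probability ``channel_coverage[i]``
    and each non-FI pair with the probability that makes the expected odds
    ratio equal ``channel_enrichment[i]``; the empirical odds ratio lands
    within about +/-30% of the target at the default sizes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    fis = extract_reference_fis(db)
    universe = list(all_pairs(db.genes))
    fi_list = sorted(fis)
    non_fi = [p for p in universe if p not in fis]
    channels: list[FeatureChannel] = []
    base_names = [c[0] for c in _DEFAULT_CHANNELS]
    base_cats = {c[0]: c[1] for c in _DEFAULT_CHANNELS}
    for i in range(cfg.n_channels):
        target = cfg.channel_enrichment[i]
        p1 = cfg.channel_coverage[i]
        if not 0 < p1 < 1 or target <= 0:
            raise ValueError(f"infeasible channel {i}: coverage={p1}, target={target}")
        odds0 = (p1 / (1 - p1)) / target
        p0 = odds0 / (1 + odds0)
        name = base_names[i] if i < len(base_names) else f"channel_{i}"
        category = base_cats.get(name, "similarity")
        pairs: set[Pair] = set()
        take_fi = rng.random(len(fi_list)) < p1
        pairs.update(p for p, t in zip(fi_list, take_fi) if t)
        take_bg = rng.random(len(non_fi)) < p0
        pairs.update(p for p, t in zip(non_fi, take_bg) if t)
        channels.append(FeatureChannel(name, category, pairs))
    return channels


def make_expression_matrix(db: PathwayDatabase, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Poisson-lognormal counts with one latent co-expression factor per pathway.

    Genes of each top-level pathway share a latent factor so their pairwise
    latent correlation is ``coexpr_module_rho`` (0 disables the modules).
    The metadata plants one low-RIN sample (rin 5.0) and one sample
    displaced along the dominant expression axis (the PCA outlier);
    a handful of samples carry a tiny group label that the group-size
    filter must drop.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    symbols = sorted(db.genes)
    n_s = cfg.n_samples_or_cells
    rho = cfg.coexpr_module_rho
    modules_of: dict[str, list[int]] = {}
    for m, pid in enumerate(db.top_level):
        for g in pathway_members(db, pid):
            modules_of.setdefault(g, []).append(m)
    base = rng.uniform(2.0, 6.0, size=len(symbols))
    z = rng.standard_normal((len(db.top_level), n_s))
    x = np.empty((len(symbols), n_s))
    for i, g in enumerate(symbols):
        eps = rng.standard_normal(n_s)
        ms = modules_of.get(g, [])
        if ms and rho > 0:
            shared = z[ms].sum(axis=0) / math.sqrt(len(ms))
            x[i] = math.sqrt(rho) * shared + math.sqrt(1 - rho) * eps
        else:
            x[i] = eps
    # planted PCA outlier: last sample displaced on half the genes
    out_idx = n_s - 1
    x[: len(symbols) // 2, out_idx] += 6.0
    lam = np.exp(base[:, None] + cfg.noise_sd * x)
    counts = rng.poisson(lam)
    sample_ids = [f"S{i:04d}" for i in range(n_s)]
    rin = rng.uniform(6.5, 9.5, size=n_s).round(2)
    rin[0] = 5.0  # planted low-RIN sample
    groups = np.array(["tissue_a"] * n_s, dtype=object)
    if n_s > 10:
        groups[1:6] = "tissue_tiny"  # planted under-sized group
    meta = pd.DataFrame({"rin": rin, "group": groups}, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionMatrix(
        pd.DataFrame(counts, index=symbols, columns=sample_ids), meta
    )


@dataclass
class SyntheticCorpus:
    """Abstracts plus the deterministic embedder and planted ground truth."""

    abstracts: list[AbstractRecord]
    provider: HashingEmbedder
    alias_map: dict[str, GeneAliasSet]
    planted_pathway: dict[str, str]  # gene -> the pathway its abstracts discuss


_FILLER = (
    "study results analysis experiments cells role function expression "
    "levels observed measured report novel data evidence findings"
).split()


def make_abstract_corpus(db: PathwayDatabase, cfg: SyntheticConfig) -> SyntheticCorpus:
    """Corpus with a planted gene-pathway literature signal.

    Every pathway-member gene gets the same number of abstracts, each
    mentioning the gene by symbol; at least one per gene is on-topic
    (reuses tokens from the gene's pathway summation), the rest use generic
    filler vocabulary. The hashing embedder (fixed dimension 384, constant
    seed) therefore places on-topic abstracts closer to their pathway's
    events.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    provider = HashingEmbedder(dim=384, seed=EMBEDDER_SEED)
    member_genes: list[str] = []
    gene_pathway: dict[str, str] = {}
    for pid in db.top_level:
        for g in pathway_members(db, pid):
            if g not in gene_pathway:
                gene_pathway[g] = pid
                member_genes.append(g)
    per_gene = max(2, cfg.n_abstracts // max(1, len(member_genes)))
    n_on = max(1, round(cfg.on_topic_fraction * per_gene))
    abstracts: list[AbstractRecord] = []
    alias_map: dict[str, GeneAliasSet] = {}
    counter = 0
    for g in member_genes:
        pid = gene_pathway[g]
        topic_tokens = [f"{pid.lower()}_topic_{t}" for t in range(6)]
        alias_map[g] = GeneAliasSet(g, {g, f"{g} protein"})
        for j in range(per_gene):
            counter += 1
            pmid = f"PM{counter:07d}"
            filler = list(rng.choice(_FILLER, size=10))
            if j < n_on:
                words = [g, "functions", "in"] + topic_tokens + filler
            else:
                words = [g, "was", "studied"] + filler + list(
                    rng.choice(_FILLER, size=6)
                )
            abstracts.append(AbstractRecord(pmid=pmid, text=" ".join(words)))
    return SyntheticCorpus(abstracts, provider, alias_map, gene_pathway)


# -- on-disk bundle ----------------------------------------------------------


def write_synthetic_dir(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, str]:
    """Write the full synthetic input bundle to a directory.

    Produces pathway JSON, GMT, one pair TSV per channel, expression TSV and
    metadata TSV, corpus JSONL and alias TSV; returns the path map.
    """
    from .pathway_model import export_gmt, save_pathway_db

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = make_toy_pathway_db(cfg)
    paths = {"pathway_db": str(outdir / "pathways.json"),
             "gmt": str(outdir / "pathways.gmt")}
    save_pathway_db(db, paths["pathway_db"])
    export_gmt(db, paths["gmt"])
    for ch in make_feature_channels(db, cfg):
        p = outdir / f"channel_{ch.name}.tsv"
        with open(p, "w") as fh:
            fh.write("geneA\tgeneB\n")
            for a, b in sorted(ch.pairs):
                fh.write(f"{a}\t{b}\n")
        paths[f"channel:{ch.name}"] = str(p)
    expr = make_expression_matrix(db, cfg)
    expr.counts.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    expr.sample_meta.to_csv(outdir / "expression_meta.tsv", sep="\t")
    paths["expression"] = str(outdir / "expression.tsv")
    paths["expression_meta"] = str(outdir / "expression_meta.tsv")
    corpus = make_abstract_corpus(db, cfg)
    with open(outdir / "corpus.jsonl", "w") as fh:
        for rec in corpus.abstracts:
            fh.write(json.dumps({"pmid": rec.pmid, "text": rec.text}) + "\n")
    with open(outdir / "aliases.tsv", "w") as fh:
        fh.write("symbol\talias\n")
        for g in sorted(corpus.alias_map):
            for alias in sorted(corpus.alias_map[g].aliases):
                fh.write(f"{g}\t{alias}\n")
    paths["corpus"] = str(outdir / "corpus.jsonl")
    paths["aliases"] = str(outdir / "aliases.tsv")
    return paths
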