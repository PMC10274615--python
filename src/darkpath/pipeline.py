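"""End-to-end orchestration of the synthetic study.

``run_synthetic_pipeline`` runs the whole chain on generated fixtures:
pathway database -> reference FIs -> feature channels -> odds-ratio vetting
-> classifier training -> FI score prediction -> thresholding -> per-gene
interacting-pathway enrichment -> fuzzy-logic simulation scores.
``score_agreement_experiment`` runs the validation design: FI-based
pathway scores against co-expression-based pathway scores, per-gene
correlations and the skew summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._pairs import all_pairs
from .feature_builder import (
    FeatureMatrix,
    OddsRatioReport,
    assemble_feature_matrix,
    select_features,
)
from .fi_classifier import (
    EvalReport,
    FIClassifier,
    FIScoreTable,
    build_training_set,
    predict_scores,
    threshold_predictions,
    train_and_evaluate,
)
from .fuzzy_sim import simulation_scores
from .pathway_model import PathwayDatabase, extract_reference_fis
from .pathway_scoring import (
    InteractingPathwayRecord,
    interacting_pathways,
    partners_of,
    records_to_tsv,
)
from .synthetic_data import (
    SyntheticConfig,
    make_expression_matrix,
    make_feature_channels,
    make_toy_pathway_db,
)
from .validation import (
    CorrelationRecord,
    GeneScoreVector,
    coexpression_pathway_scores,
    per_gene_correlation,
    skew_summary,
)


@dataclass
class PipelineResult:
    db: PathwayDatabase
    retained_channels: list[str]
    odds_reports: list[OddsRatioReport]
    classifier: FIClassifier
    eval_report: EvalReport
    scores: FIScoreTable
    predicted_fis: set
    records: list[InteractingPathwayRecord] = field(default_factory=list)


def run_synthetic_pipeline(
    cfg: SyntheticConfig,
    neg_ratio: int = 10,
    fi_cutoff: float = 0.8,
    or_threshold: float = 5.0,
    fdr_cutoff: float = 0.05,
    simulate: bool = True,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on synthetic fixtures; fully seeded and deterministic.

    The simulation stage fills activation / inhibition scores for records
    passing the FDR cutoff. When ``outdir`` is given, the FI score table
    and the interacting-pathway records are written there as TSV.
    """
    db = make_toy_pathway_db(cfg)
    fis = extract_reference_fis(db)
    channels = make_feature_channels(db, cfg)
    universe_pairs = set(all_pairs(db.genes))
    retained, reports = select_features(channels, fis, universe_pairs, or_threshold)
    kept = [ch for ch in channels if ch.name in retained]
    ts = build_training_set(fis, set(db.genes), kept, neg_ratio=neg_ratio,
                            seed=cfg.seed)
    clf, eval_report = train_and_evaluate(ts)
    pair_index = sorted(universe_pairs)
    features = assemble_feature_matrix(pair_index, kept)
    scores = predict_scores(clf, pair_index, features)
    predicted = threshold_predictions(scores, fi_cutoff)

    records: list[InteractingPathwayRecord] = []
    for gene in sorted(db.genes):
        if not partners_of(gene, predicted):
            continue
        recs = interacting_pathways(gene, predicted, db,
                                    pathway_ids=list(db.top_level))
        if simulate:
            for rec in recs:
                if rec.fdr < fdr_cutoff and rec.overlap > 0:
                    impact = simulation_scores(gene, scores_for_gene(scores, gene),
                                               db, rec.pathway_id)
                    rec.avg_activation = impact.average_activation
                    rec.avg_inhibition = impact.average_inhibition
        records.extend(recs)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores.to_tsv(str(outdir / "fi_scores.tsv"))
        records_to_tsv(records, str(outdir / "interacting_pathways.tsv"))
    return PipelineResult(db, retained, reports, clf, eval_report, scores,
                          predicted, records)


def scores_for_gene(scores: FIScoreTable, gene: str) -> FIScoreTable:
    gene = gene.upper()
    return FIScoreTable({p: s for p, s in scores.items() if gene in p})


def interacting_pathway_vectors(
    db: PathwayDatabase,
    fi_set: set,
    fdr_cutoff: float = 0.05,
    gene_sets: dict | None = None,
) -> dict[str, GeneScoreVector]:
    """Per-gene score vectors over the gene's interacting pathways.

    A gene's interacting pathways are those whose enrichment FDR falls
    below ``fdr_cutoff``; the vector carries their enrichment scores. Genes
    without partners or without any significant pathway are absent.
    """
    from .pathway_model import event_gene_set

    if gene_sets is None:
        gene_sets = {pid: event_gene_set(db, pid) for pid in db.pathways}
    out: dict[str, GeneScoreVector] = {}
    for gene in sorted(db.genes):
        if not partners_of(gene, fi_set):
            continue
        recs = [r for r in interacting_pathways(gene, fi_set, db,
                                                gene_sets=gene_sets)
                if r.fdr < fdr_cutoff]
        if recs:
            out[gene] = GeneScoreVector(
                gene, [r.pathway_id for r in recs],
                [r.enrichment_score for r in recs],
            )
    return out


def score_agreement_experiment(
    cfg: SyntheticConfig,
    pct: float = 10.0,
    min_pathways: int = 10,
    fdr_cutoff: float = 0.05,
) -> tuple[list[CorrelationRecord], dict | None]:
    """Correlate FI-based and co-expression-based interacting-pathway profiles.

    The curated reference FI set drives the FI-based channel (isolating the
    scoring stages from classifier noise); the co-expression channel takes
    the top ``pct`` percent positively correlated gene pairs of the
    generated expression matrix as functional-correlation pairs. Each
    channel yields per-gene score vectors over its significantly enriched
    pathways; genes with at least ``min_pathways`` pathways significant in
    both channels enter the per-gene Pearson correlation and the skew
    summary. Returns (records, summary); summary is None with fewer than
    two usable records (nothing to test).
    """
    from .feature_builder import coexpression_matrix, top_percentile_pairs
    from .pathway_model import event_gene_set, extract_reference_fis

    db = make_toy_pathway_db(cfg)
    fis = extract_reference_fis(db)
    expr = make_expression_matrix(db, cfg)
    corr = coexpression_matrix(expr)
    co_channel = top_percentile_pairs(corr, pct, name="coexpr",
                                      positive_only=True)
    gene_sets = {pid: event_gene_set(db, pid) for pid in db.pathways}
    fi_vecs = interacting_pathway_vectors(db, fis, fdr_cutoff, gene_sets)
    co_vecs = interacting_pathway_vectors(db, co_channel.pairs, fdr_cutoff,
                                          gene_sets)
    records: list[CorrelationRecord] = []
    for gene in sorted(set(fi_vecs) & set(co_vecs)):
        rec = per_gene_correlation(fi_vecs[gene], co_vecs[gene],
                                   min_pathways=min_pathways,
                                   is_dark=db.genes[gene].tdl == "Tdark")
        if rec is not None:
            records.append(rec)
    summary = skew_summary(records) if len(records) >= 2 else None
    return records, summary
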