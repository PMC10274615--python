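"""Agreement statistics between independent pathway-score channels.

A gene's interacting-pathway profile can be computed from predicted FIs,
from single-cell co-expression, or from the literature. If the predicted
profiles are meaningful, independent profiles of the same gene should
correlate: per-gene Pearson correlations should skew positive. This module
provides the per-gene correlation, the skew summary (sign proportion test
plus two-sample comparisons of -log10(p) and |r| between sign groups),
generic group-difference tests, the co-expression-based pathway scoring
used for single-cell validation, and min-max score scaling for display.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_builder import ExpressionMatrix, coexpression_matrix, top_percentile_pairs
from .pathway_model import PathwayDatabase
from .pathway_scoring import interacting_pathways, partners_of


@dataclass
class GeneScoreVector:
    """One gene's scores over a set of pathways (any scoring channel)."""

    gene: str
    pathway_ids: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.pathway_ids) != len(self.scores):
            raise ValueError("pathway ids and scores are not aligned")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.pathway_ids, dtype=float)


@dataclass
class CorrelationRecord:
    gene: str
    n_pathways: int
    r: float
    p: float
    is_annotated: bool = False
    is_dark: bool = False


def per_gene_correlation(
    a: GeneScoreVector,
    b: GeneScoreVector,
    min_pathways: int = 10,
    is_annotated: bool = False,
    is_dark: bool = False,
) -> CorrelationRecord | None:
    """Pearson correlation between two score vectors of the same gene.

    Pathway ids are intersected first; genes with fewer than
    ``min_pathways`` shared entries, or with a zero-variance vector, are
    reported as missing (None) rather than given a degenerate correlation.
    """
    if a.gene.upper() != b.gene.upper():
        raise ValueError("vectors belong to different genes")
    sa, sb = a.as_series(), b.as_series()
    shared = sa.index.intersection(sb.index)
    x = sa[shared].to_numpy(dtype=float)
    y = sb[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_pathways:
        return None
    if x.std() == 0 or y.std() == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.pearsonr(x, y)
    if not (math.isfinite(res.statistic) and math.isfinite(res.pvalue)):
        return None  # numerically constant vector
    return CorrelationRecord(
        gene=a.gene.upper(),
        n_pathways=len(x),
        r=float(res.statistic),
        p=float(res.pvalue),
        is_annotated=is_annotated,
        is_dark=is_dark,
    )


def skew_summary(records: list[CorrelationRecord]) -> dict:
    """Is the distribution of per-gene correlations positively skewed?

    Counts positive vs negative r (exact two-sided binomial proportion test
    against 0.5), and compares -log10(p) and |r| between the sign groups
    with both Welch t and Mann-Whitney tests (two-sided). With one sign
    group empty the two-sample entries are NaN.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 correlation records")
    pos = [r for r in records if r.r > 0]
    neg = [r for r in records if r.r < 0]
    n_pos, n_neg = len(pos), len(neg)
    out: dict = {"n_pos": n_pos, "n_neg": n_neg}
    if n_pos + n_neg == 0:
        raise ValueError("no nonzero correlations")
    out["proportion_p"] = float(
        stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
    )
    for label, extract in (
        ("neglog10_p", lambda r: -math.log10(max(r.p, 1e-300))),
        ("abs_r", lambda r: abs(r.r)),
    ):
        xs = [extract(r) for r in pos]
        ys = [extract(r) for r in neg]
        if len(xs) >= 2 and len(ys) >= 2:
            out[f"{label}_welch_p"] = float(
                stats.ttest_ind(xs, ys, equal_var=False).pvalue
            )
            out[f"{label}_mannwhitney_p"] = float(
                stats.mannwhitneyu(xs, ys, alternative="two-sided").pvalue
            )
        else:
            out[f"{label}_welch_p"] = math.nan
            out[f"{label}_mannwhitney_p"] = math.nan
    return out


def group_difference_tests(values, groups, kind: str) -> tuple[float, float]:
    """Two-sided Welch t / one-way ANOVA / Mann-Whitney between labelled groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups are not aligned")
    labels = sorted(set(groups.tolist()))
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs >= 2 observations")
    if kind == "welch_t":
        if len(labels) != 2:
            raise ValueError("welch_t needs exactly 2 groups")
        res = stats.ttest_ind(samples[0], samples[1], equal_var=False)
    elif kind == "mann_whitney":
        if len(labels) != 2:
            raise ValueError("mann_whitney needs exactly 2 groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif kind == "anova":
        if len(labels) < 2:
            raise ValueError("anova needs >= 2 groups")
        res = stats.f_oneway(*samples)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    stat = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(p) and kind in ("welch_t", "anova"):
        # identical constant groups: zero effect, zero variance
        stat, p = 0.0, 1.0
    return stat, p


def coexpression_pathway_scores(
    expr: ExpressionMatrix,
    db: PathwayDatabase,
    pct: float = 0.1,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Gene-by-pathway enrichment scores from co-expression partner sets.

    The top ``pct`` percent positively correlated gene pairs (Spearman on
    cpm) are taken as functional-correlation pairs; each gene's partners
    then go through the same binomial / BH enrichment as predicted FI
    partners. Genes with no partners get NaN rows.
    """
    corr = coexpression_matrix(expr)
    channel = top_percentile_pairs(corr, pct, name="scrna", positive_only=True)
    pathway_ids = sorted(db.pathways)
    out = pd.DataFrame(np.nan, index=sorted(expr.genes), columns=pathway_ids)
    for gene in out.index:
        partners = partners_of(gene, channel.pairs)
        if not partners:
            continue
        records = interacting_pathways(gene, channel.pairs, db, universe=universe)
        for rec in records:
            out.loc[gene, rec.pathway_id] = rec.enrichment_score
    return out


def scale_scores(values) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all 0.5."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not np.isfinite(lo) or not np.isfinite(hi):
        raise ValueError("no finite values")
    if lo == hi:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)
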