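"""Gene-pair feature channels for functional-interaction prediction.

A feature channel is a binary set of canonical gene pairs from one evidence
source: a co-expression top-percentile selection, a protein–protein
interaction catalogue (possibly ortholog-mapped from a model organism), a
gene-similarity resource, shared protein domains, or shared GO biological
process annotation. Channels are vetted against reference FIs by odds
ratio (retain only OR > 5 by default) and assembled into a binary
pair-by-channel matrix for classifier training.

Expression handling mirrors standard bulk RNA-seq practice: RIN-based
sample filtering, PCA outlier flagging, counts-per-million normalization
and pairwise Spearman correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._pairs import Pair, canonical_pair

CHANNEL_CATEGORIES = frozenset({"coexpression", "ppi", "similarity", "domain", "gobp"})


@dataclass
class ExpressionMatrix:
    """Gene-by-sample read counts with per-sample metadata.

    ``counts`` is genes x samples (non-negative); ``sample_meta`` is indexed
    by sample id with optional ``rin`` (RNA integrity number) and ``group``
    (tissue / cancer label) columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate gene or sample labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if len(self.sample_meta) and not self.sample_meta.index.isin(
            self.counts.columns
        ).all():
            raise ValueError("sample_meta contains samples absent from the matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, keep: list[str]) -> "ExpressionMatrix":
        meta = self.sample_meta
        if len(meta):
            meta = meta.loc[meta.index.isin(keep)]
        return ExpressionMatrix(self.counts[keep], meta)


@dataclass
class FeatureChannel:
    """A named binary gene-pair feature: membership in ``pairs``."""

    name: str
    category: str
    pairs: set[Pair]

    def __post_init__(self) -> None:
        if self.category not in CHANNEL_CATEGORIES:
            raise ValueError(f"unknown channel category {self.category!r}")
        for a, b in self.pairs:
            if a == b or a > b:
                raise ValueError(f"non-canonical pair in channel {self.name!r}: {(a, b)}")


@dataclass
class OddsRatioReport:
    """2x2 association between a channel and the reference FI set.

    a = channel & FI, b = channel - FI, c = FI - channel,
    d = neither, over the pair universe.
    """

    channel: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class FeatureMatrix:
    """Binary pair-by-channel matrix with optional FI labels."""

    pair_index: list[Pair]
    channels: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pair_index), len(self.channels)):
            raise ValueError("values shape does not match pair_index x channels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature values must be binary")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.uint8)
            if self.labels.shape != (len(self.pair_index),):
                raise ValueError("labels length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channels)
        df.insert(0, "geneA", [p[0] for p in self.pair_index])
        df.insert(1, "geneB", [p[1] for p in self.pair_index])
        if self.labels is not None:
            df["label"] = self.labels
        return df


# -- expression processing --------------------------------------------------


def filter_samples(
    m: ExpressionMatrix, min_rin: float = 6.0, min_samples: int = 30
) -> ExpressionMatrix:
    """Drop samples with RIN <= ``min_rin``, then groups with < ``min_samples``.

    Both boundaries are inclusive on the removal side: a sample at exactly
    the RIN threshold is removed, and a group must retain at least
    ``min_samples`` samples to survive. Warns (rather than failing silently)
    when everything is filtered out.
    """
    keep = list(m.samples)
    meta = m.sample_meta
    if len(meta) and "rin" in meta.columns:
        bad = set(meta.index[meta["rin"] <= min_rin])
        keep = [s for s in keep if s not in bad]
    if len(meta) and "group" in meta.columns:
        groups = meta.loc[meta.index.isin(keep), "group"]
        sizes = groups.value_counts()
        small = set(sizes.index[sizes < min_samples])
        in_small = set(groups.index[groups.isin(small)])
        keep = [s for s in keep if s not in in_small]
    if not keep:
        warnings.warn("all samples removed by filtering", stacklevel=2)
    return m.subset_samples(keep)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each sample column scaled to sum to 1e6."""
    sums = counts.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("sample with zero total counts")
    return counts.div(sums, axis=1) * 1e6


def flag_outliers_pca(m: ExpressionMatrix, z_cut: float = 3.0) -> set[str]:
    """Flag samples whose first-principal-component z-score is >= ``z_cut``.

    Computed on log2(cpm + 1) with genes centered; the sample score is the
    sample loading on PC1. PC1 is oriented so the heavier tail (largest
    absolute score) is positive, then scores are standardized and samples
    with z >= z_cut flagged.
    """
    if len(m.samples) < 3:
        raise ValueError("need >= 3 samples for PCA outlier flagging")
    x = np.log2(cpm(m.counts).to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center each gene
    # sample scores on PC1 via SVD of the gene x sample matrix
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = s[0] * vt[0]
    if abs(scores.min()) > abs(scores.max()):
        scores = -scores
    sd = scores.std()
    if sd == 0:
        return set()
    z = (scores - scores.mean()) / sd
    return {m.samples[i] for i in np.flatnonzero(z >= z_cut)}


def coexpression_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Gene-by-gene Spearman correlation of cpm values.

    Constant genes yield missing (NaN) correlations rather than zeros; for
    all other genes the diagonal is exactly 1.
    """
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples for correlation")
    vals = cpm(m.counts).to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        corr = stats.spearmanr(vals, axis=1).statistic
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    constant = vals.std(axis=1) == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=m.genes, columns=m.genes)


def top_percentile_pairs(
    corr: pd.DataFrame,
    pct: float,
    name: str = "coexpression",
    positive_only: bool = False,
) -> FeatureChannel:
    """Select the top ``pct`` percent of off-diagonal gene pairs by value.

    Exactly ceil(pct/100 * P) pairs are returned, where P counts the
    non-missing off-diagonal unordered pairs (restricted to positive values
    when ``positive_only``). Ties break deterministically by (value
    descending, pair key ascending).
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    genes = list(corr.index)
    vals = corr.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(genes), k=1)
    v = vals[iu, ju]
    ok = np.isfinite(v)
    if positive_only:
        ok &= v > 0
    iu, ju, v = iu[ok], ju[ok], v[ok]
    p_count = len(v)
    if p_count == 0:
        return FeatureChannel(name, "coexpression", set())
    k = math.ceil(pct / 100.0 * p_count)
    items = sorted(
        ((float(v[i]), canonical_pair(genes[iu[i]], genes[ju[i]])) for i in range(p_count)),
        key=lambda t: (-t[0], t[1]),
    )
    return FeatureChannel(name, "coexpression", {pair for _, pair in items[:k]})


# -- ortholog mapping -------------------------------------------------------


def map_pairs_via_orthologs(
    channel: FeatureChannel, ortholog_map: dict[str, set[str]]
) -> tuple[FeatureChannel, dict[str, int]]:
    """Map a model-organism pair channel to human symbols.

    Each source pair expands to the cross-product of its members' human
    orthologs; self-pairs are dropped and the result deduplicated. Returns
    the mapped channel plus a report with counts of mapped and dropped
    source pairs (a pair drops when either member has no ortholog).
    """
    mapped: set[Pair] = set()
    dropped = 0
    for a, b in sorted(channel.pairs):
        ha = ortholog_map.get(a, set())
        hb = ortholog_map.get(b, set())
        if not ha or not hb:
            dropped += 1
            continue
        for x in ha:
            for y in hb:
                if x.upper() != y.upper():
                    mapped.add(canonical_pair(x, y))
    report = {"source_pairs": len(channel.pairs), "dropped": dropped,
              "mapped_pairs": len(mapped)}
    return FeatureChannel(channel.name, channel.category, mapped), report


# -- odds-ratio vetting ------------------------------------------------------


def pairwise_odds_ratio(
    channel: FeatureChannel, fis: set[Pair], universe: set[Pair]
) -> OddsRatioReport:
    """2x2 odds ratio between channel membership and reference-FI membership.

    Zero cells get the Haldane–Anscombe +0.5 correction (applied to all four
    cells) so sparse channels still get a finite, comparable ratio.
    """
    if not universe:
        raise ValueError("empty pair universe")
    if not channel.pairs <= universe:
        raise ValueError(f"channel {channel.name!r} has pairs outside the universe")
    if not fis <= universe:
        raise ValueError("reference FIs outside the universe")
    a = len(channel.pairs & fis)
    b = len(channel.pairs - fis)
    c = len(fis - channel.pairs)
    d = len(universe) - a - b - c
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return OddsRatioReport(channel.name, a, b, c, d, float(orr))


def select_features(
    channels: list[FeatureChannel],
    fis: set[Pair],
    universe: set[Pair],
    threshold: float = 5.0,
) -> tuple[list[str], list[OddsRatioReport]]:
    """Retain channels whose odds ratio is strictly greater than ``threshold``.

    A report is emitted for every channel, retained or not.
    """
    reports = [pairwise_odds_ratio(ch, fis, universe) for ch in channels]
    retained = [r.channel for r in reports if r.odds_ratio > threshold]
    return retained, reports


def assemble_feature_matrix(
    pair_index: list[Pair], channels: list[FeatureChannel]
) -> FeatureMatrix:
    """Binary membership matrix: rows in canonical pair order, columns in input order."""
    names = [ch.name for ch in channels]
    if len(set(names)) != len(names):
        raise ValueError("duplicate channel names")
    pair_index = sorted(pair_index)
    values = np.zeros((len(pair_index), len(channels)), dtype=np.uint8)
    for j, ch in enumerate(channels):
        for i, pair in enumerate(pair_index):
            if pair in ch.pairs:
                values[i, j] = 1
    return FeatureMatrix(pair_index, names, values)


# -- I/O --------------------------------------------------------------------


def load_expression(counts_path: str, meta_path: str | None = None) -> ExpressionMatrix:
    """Read a counts matrix (GCT-like or strict TSV) and optional metadata TSV.

    GCT files ("#1.2" header + dimension line, Name/Description columns) and
    plain TSVs with the gene id in the first column are both accepted. The
    metadata TSV needs a sample_id column plus optional rin and group.
    """
    with open(counts_path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(counts_path, sep="\t", skiprows=2)
        df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
    else:
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.DataFrame()
    if meta_path:
        meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    return ExpressionMatrix(df, meta)


def load_pair_channel(path: str, name: str, category: str = "ppi",
                      min_score: float | None = None) -> FeatureChannel:
    """Read a 2- or 3-column pair TSV (geneA, geneB[, score]) into a channel."""
    df = pd.read_csv(path, sep="\t")
    if min_score is not None and df.shape[1] >= 3:
        df = df[df.iloc[:, 2] >= min_score]
    pairs: set[Pair] = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if str(a).upper() != str(b).upper():
            pairs.add(canonical_pair(str(a), str(b)))
    return FeatureChannel(name, category, pairs)


def load_ortholog_map(path: str) -> dict[str, set[str]]:
    """Read a 2-column TSV (source_gene, human_symbol) into a mapping."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for src, hum in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(src), set()).add(str(hum).upper())
    return out
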