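"""Interacting-pathway enrichment scores.

For each gene, its predicted FI partners are treated as a gene set and
tested for enrichment in every pathway with a one-sided binomial test:
with n partners in the background universe of N genes and a pathway of K
genes, the overlap k is compared with Binomial(n, K/N). P-values are
Benjamini–Hochberg adjusted across pathways within the gene, and the
enrichment score is -log10(FDR).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._pairs import Pair
from .pathway_model import PathwayDatabase, event_gene_set

#: FDR floor applied before the -log10 transform, keeping scores finite
FDR_FLOOR = 1e-300


@dataclass
class InteractingPathwayRecord:
    """Per (gene, pathway) enrichment result.

    ``avg_activation`` / ``avg_inhibition`` are filled by the fuzzy-logic
    simulation stage; enrichment alone leaves them as NaN.
    """

    gene: str
    pathway_id: str
    pathway_name: str
    overlap: int
    partners_in_universe: int
    pathway_size: int
    universe_size: int
    p_value: float
    fdr: float
    enrichment_score: float
    avg_activation: float = math.nan
    avg_inhibition: float = math.nan


def binomial_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, K/N).

    k = overlap between the gene's partners and the pathway, n = partners in
    the universe, K = pathway size, N = universe size. k = 0 gives exactly 1.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < K <= N):
        raise ValueError(f"need 0 < K <= N, got K={K}, N={N}")
    if n > N:
        raise ValueError(f"need n <= N, got n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, K / N))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, order-preserving.

    Adjusted values are monotone (cumulative-minimum enforced) and capped
    at 1; the output aligns with the input indexing.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partners_of(gene: str, fi_set: set[Pair]) -> set[str]:
    """FI partners of a gene in a set of canonical pairs."""
    gene = gene.upper()
    return {b if a == gene else a for a, b in fi_set if gene in (a, b)}


def interacting_pathways(
    gene: str,
    fi_set: set[Pair],
    db: PathwayDatabase,
    universe: set[str] | None = None,
    pathway_ids: list[str] | None = None,
    gene_sets: dict[str, set[str]] | None = None,
) -> list[InteractingPathwayRecord]:
    """Enrichment of a gene's FI partners in each pathway.

    The background ``universe`` defaults to all genes in the database.
    Partners are intersected with the universe before n is computed; one
    record is produced per pathway with a nonzero gene set, BH-adjusted
    across pathways within this gene and sorted by enrichment score
    descending (ties by pathway id). ``gene_sets`` may carry precomputed
    per-pathway gene sets to avoid rederiving them for every gene.
    """
    gene = gene.upper()
    universe = set(universe) if universe is not None else set(db.genes)
    partners = partners_of(gene, fi_set) & universe
    if not partners:
        warnings.warn(f"gene {gene} has no FI partners in the universe", stacklevel=2)
        return []
    n = len(partners)
    N = len(universe)
    ids = pathway_ids if pathway_ids is not None else sorted(db.pathways)
    rows: list[tuple[str, int, int, float]] = []
    for pid in ids:
        pw_all = gene_sets[pid] if gene_sets is not None else event_gene_set(db, pid)
        pw_genes = pw_all & universe
        K = len(pw_genes)
        if K == 0:
            continue
        k = len(partners & pw_genes)
        rows.append((pid, k, K, binomial_pvalue(k, n, K, N)))
    if not rows:
        return []
    fdrs = bh_adjust([r[3] for r in rows])
    records = [
        InteractingPathwayRecord(
            gene=gene,
            pathway_id=pid,
            pathway_name=db.pathways[pid].name,
            overlap=k,
            partners_in_universe=n,
            pathway_size=K,
            universe_size=N,
            p_value=p,
            fdr=float(fdr),
            enrichment_score=-math.log10(max(float(fdr), FDR_FLOOR)),
        )
        for (pid, k, K, p), fdr in zip(rows, fdrs)
    ]
    records.sort(key=lambda r: (-r.enrichment_score, r.pathway_id))
    return records


def records_to_tsv(records: list[InteractingPathwayRecord], path: str) -> None:
    cols = [
        "gene", "pathway_id", "pathway_name", "overlap", "p_value", "fdr",
        "enrichment_score", "avg_activation", "avg_inhibition",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                f"{r.gene}\t{r.pathway_id}\t{r.pathway_name}\t{r.overlap}\t"
                f"{r.p_value:.6e}\t{r.fdr:.6e}\t{r.enrichment_score:.6f}\t"
                f"{r.avg_activation:.6f}\t{r.avg_inhibition:.6f}\n"
            )
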