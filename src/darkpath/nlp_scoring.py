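"""Literature-based pathway annotation scores.

The idea: abstracts mentioning a gene (by symbol, protein name or synonym)
are embedded into fixed-length vectors; each pathway is represented by the
embeddings of its own free-text summation plus those of every event
(sub-pathway or reaction) inside it; the similarity between a pathway and
an abstract is the mean cosine over those event embeddings. A gene's
annotation score for a pathway averages that similarity over its top-k
matched abstracts (ranked by mean similarity across all pathways under
analysis, at most 1,000 kept).

Embedding providers are pluggable. :class:`HashingEmbedder` is a
deterministic bag-of-words embedder (token hashing + signed projection to
a 384-dimensional unit vector) used throughout the test fixtures;
:class:`SentenceTransformerEmbedder` wraps a sentence-embedding model when
the ``sentence_transformers`` package is available.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np
import pandas as pd

from .pathway_model import PathwayDatabase


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"abstract {self.pmid} has empty text")


@dataclass
class GeneAliasSet:
    """Aliases under which a gene may be mentioned; always contains the symbol."""

    gene: str
    aliases: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.gene = self.gene.upper()
        self.aliases = set(self.aliases) | {self.gene}


class EmbeddingProvider(Protocol):
    """Contract: a fixed dimension and a deterministic text -> vector map."""

    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Deterministic token-hash bag-of-words embedder.

    Each token maps, via a blake2b digest, to a fixed pseudo-random vector;
    a text embeds as the normalized sum of its token vectors. Same text in,
    same vector out, across processes and platforms.
    """

    def __init__(self, dim: int = 384, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._token_cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dim)
            self._token_cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        tokens = re.findall(r"\w+", text.lower())
        if not tokens:
            return np.zeros(self.dim)
        v = np.zeros(self.dim)
        for tok in tokens:
            v += self._token_vector(tok)
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v


class SentenceTransformerEmbedder:
    """Production provider wrapping a sentence-embedding model (dim 384 for
    MiniLM-class models). Requires the optional ``sentence_transformers``
    package."""

    def __init__(self, model_name: str = "all-MiniLM-L6-v2"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "sentence_transformers is not installed; use HashingEmbedder "
                "or install the optional dependency"
            ) from exc
        self._model = SentenceTransformer(model_name)
        self.dim = self._model.get_sentence_embedding_dimension()

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional
        return np.asarray(self._model.encode([text])[0], dtype=float)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# -- corpus I/O --------------------------------------------------------------


def load_corpus(path: str) -> list[AbstractRecord]:
    """Read a JSONL corpus of {"pmid": ..., "text": ...} records."""
    out: list[AbstractRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            pmid = str(rec["pmid"])
            if pmid in seen:
                raise ValueError(f"duplicate pmid {pmid}")
            seen.add(pmid)
            out.append(AbstractRecord(pmid=pmid, text=rec["text"]))
    return out


def load_alias_table(path: str) -> dict[str, GeneAliasSet]:
    """Read a TSV (symbol, alias) into per-gene alias sets."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, GeneAliasSet] = {}
    for sym, alias in zip(df.iloc[:, 0], df.iloc[:, 1]):
        sym = str(sym).upper()
        out.setdefault(sym, GeneAliasSet(sym)).aliases.add(str(alias))
    return out


# -- matching and similarity -------------------------------------------------


def _alias_regex(alias: str) -> re.Pattern:
    # all-uppercase aliases are gene symbols: match case-sensitively;
    # protein names and mixed-case synonyms match case-insensitively
    flags = 0 if alias.isupper() else re.IGNORECASE
    return re.compile(rf"\b{re.escape(alias)}\b", flags)


def match_abstracts(
    corpus: Iterable[AbstractRecord], aliases: GeneAliasSet
) -> list[AbstractRecord]:
    """Abstracts containing any alias as a word-boundary-delimited token.

    Deterministic order by pmid.
    """
    if not aliases.aliases:
        raise ValueError("empty alias set")
    patterns = [_alias_regex(a) for a in sorted(aliases.aliases)]
    hits = [rec for rec in corpus if any(p.search(rec.text) for p in patterns)]
    return sorted(hits, key=lambda r: r.pmid)


def event_summation_texts(db: PathwayDatabase, pathway_id: str) -> list[str]:
    """Summation text of a pathway plus all events inside it, in deterministic
    order; events lacking summation text are skipped."""
    texts: list[str] = []
    pw = db.pathways[pathway_id]
    if pw.summation:
        texts.append(pw.summation)
    for eid in db.descendant_events(pathway_id):
        summ = (db.pathways[eid].summation if eid in db.pathways
                else db.reactions[eid].summation)
        if summ:
            texts.append(summ)
    return texts


class PathwayEmbeddingIndex:
    """Cached event-summation embeddings per pathway (rows: events)."""

    def __init__(self, db: PathwayDatabase, provider: EmbeddingProvider):
        self.db = db
        self.provider = provider
        self._cache: dict[str, np.ndarray] = {}

    def event_matrix(self, pathway_id: str) -> np.ndarray:
        mat = self._cache.get(pathway_id)
        if mat is None:
            texts = event_summation_texts(self.db, pathway_id)
            if not texts:
                raise ValueError(f"pathway {pathway_id!r} has no embeddable text")
            mat = np.vstack([self.provider.embed(t) for t in texts])
            self._cache[pathway_id] = mat
        return mat

    def similarity(self, pathway_id: str, abstract_vec: np.ndarray) -> float:
        mat = self.event_matrix(pathway_id)
        return float(np.mean([cosine(row, abstract_vec) for row in mat]))


def event_similarity(
    pathway_id: str,
    abstract_vec: np.ndarray,
    db: PathwayDatabase,
    provider: EmbeddingProvider,
    index: PathwayEmbeddingIndex | None = None,
) -> float:
    """Mean cosine between an abstract vector and the embeddings of the
    pathway's summation and the summations of all events inside it."""
    index = index if index is not None else PathwayEmbeddingIndex(db, provider)
    return index.similarity(pathway_id, abstract_vec)


def annotation_score(
    gene: str,
    pathway_id: str,
    corpus: list[AbstractRecord],
    db: PathwayDatabase,
    provider: EmbeddingProvider,
    k: int = 1000,
    aliases: GeneAliasSet | None = None,
    pathway_ids: list[str] | None = None,
    index: PathwayEmbeddingIndex | None = None,
) -> float:
    """Literature annotation score for a (gene, pathway) pair.

    Among the gene's matched abstracts, rank by mean event similarity
    across ``pathway_ids`` (all pathways being scored; defaults to every
    pathway in the database), keep the top min(k, count), and return the
    mean event similarity of the kept abstracts to the target pathway.
    Returns NaN when the gene matches no abstract.
    """
    table = nlp_validation_scores(
        [gene], pathway_ids if pathway_ids is not None else sorted(db.pathways),
        corpus, db, provider, k=k,
        alias_map={gene.upper(): aliases} if aliases is not None else None,
        index=index,
    )
    if pathway_id not in table.columns:
        raise KeyError(f"pathway {pathway_id!r} not among the scored pathways")
    return float(table.loc[gene.upper(), pathway_id])


def nlp_validation_scores(
    genes: list[str],
    pathways: list[str],
    corpus: list[AbstractRecord],
    db: PathwayDatabase,
    provider: EmbeddingProvider,
    k: int = 1000,
    alias_map: dict[str, GeneAliasSet] | None = None,
    index: PathwayEmbeddingIndex | None = None,
) -> pd.DataFrame:
    """Gene-by-pathway annotation score table.

    Rows for genes without matched abstracts are NaN (missing, not zero).
    Deterministic and invariant to gene or corpus ordering.
    """
    index = index if index is not None else PathwayEmbeddingIndex(db, provider)
    abstract_vecs = {rec.pmid: provider.embed(rec.text) for rec in corpus}
    # abstract x pathway event-similarity matrix, computed once
    pmids = sorted(abstract_vecs)
    sim = np.array(
        [[index.similarity(pid, abstract_vecs[pmid]) for pid in pathways]
         for pmid in pmids]
    ) if pmids else np.zeros((0, len(pathways)))
    row_of = {pmid: i for i, pmid in enumerate(pmids)}
    out = pd.DataFrame(
        np.nan, index=[g.upper() for g in genes], columns=list(pathways)
    )
    for gene in genes:
        gene = gene.upper()
        aliases = (alias_map or {}).get(gene) or GeneAliasSet(gene)
        matched = match_abstracts(corpus, aliases)
        if not matched:
            continue
        rows = [row_of[rec.pmid] for rec in matched]
        mean_sim = sim[rows].mean(axis=1)
        # top-k by average similarity across the pathways under analysis,
        # ties broken by pmid for determinism
        order = sorted(range(len(rows)),
                       key=lambda i: (-mean_sim[i], matched[i].pmid))
        kept = [rows[i] for i in order[: min(k, len(rows))]]
        out.loc[gene] = sim[kept].mean(axis=0)
    return out
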