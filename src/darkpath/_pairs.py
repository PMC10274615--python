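"""Canonical unordered gene-pair helpers used across the package.

Every gene pair in the artifact is an unordered pair of distinct,
uppercased gene symbols stored as a lexicographically sorted 2-tuple.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Iterator

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical (sorted, uppercased) form of a gene pair.

    Raises ``ValueError`` on self-pairs: a gene does not functionally
    interact with itself in this representation.
    """
    a, b = a.upper(), b.upper()
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def all_pairs(genes: Iterable[str]) -> Iterator[Pair]:
    """Yield every canonical pair over a gene universe, in sorted order."""
    for a, b in combinations(sorted({g.upper() for g in genes}), 2):
        yield (a, b)


def pairs_from_iterable(items: Iterable[tuple[str, str]]) -> set[Pair]:
    """Canonicalize and deduplicate an iterable of gene pairs, dropping self-pairs."""
    out: set[Pair] = set()
    for a, b in items:
        a, b = a.upper(), b.upper()
        if a == b:
            continue
        out.add((a, b) if a < b else (b, a))
    return out
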