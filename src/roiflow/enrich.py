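"""Gene-set over-representation analysis.

For a query gene list against a library of gene sets, each tested term gets
an upper-tail hypergeometric p-value, a Benjamini-Hochberg adjusted p, the
contingency odds ratio, and a combined score ``OR * (-ln p)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from roiflow.errors import ConfigurationError, ParseError

#: Background universe size used when a library does not define one.
DEFAULT_BACKGROUND_SIZE = 20003


@dataclass
class GeneSetLibrary:
    """Named gene sets with an optional explicit background universe.

    ``background_size`` is the size N of the universe the hypergeometric
    test draws from; when an explicit ``universe`` is attached the query is
    intersected with it before testing.
    """

    terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    background_size: int = DEFAULT_BACKGROUND_SIZE
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ConfigurationError(f"gene set {term!r} is empty")
            if len(genes) > self.background_size:
                raise ConfigurationError(
                    f"gene set {term!r} larger than background ({self.background_size})"
                )

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentRow:
    term: str
    k: int  # overlap
    K: int  # set size
    n: int  # query size (post-intersection)
    p: float
    adj_p: float
    odds_ratio: float
    combined_score: float
    genes: list[str]


def read_gmt(path: str | Path, background_size: int = DEFAULT_BACKGROUND_SIZE) -> GeneSetLibrary:
    """Parse a GMT file: one term per line, ``id TAB description TAB genes...``.

    Duplicate genes within a term are dropped; case is preserved.
    """
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            term, desc, *genes = fields
            terms[term] = {g for g in genes if g}
            descriptions[term] = desc
    return GeneSetLibrary(terms, descriptions, background_size=background_size)


def write_gmt(lib: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in lib.terms.items():
            desc = lib.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ConfigurationError(
            f"inconsistent contingency counts: k={k}, K={K}, n={n}, N={N}"
        )


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail over-representation p-value P(X >= k).

    X ~ Hypergeometric(N, K, n): overlap between a K-gene set and an n-gene
    query drawn without replacement from an N-gene background.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Contingency odds ratio ``k(N-K-n+k) / ((K-k)(n-k))``.

    Returns 0 for an empty overlap and +inf when either denominator factor
    vanishes with a positive numerator.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 0.0
    num = k * (N - K - n + k)
    den = (K - k) * (n - k)
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den


def combined_score(or_: float, p: float) -> float:
    """Ranking statistic ``OR * (-ln p)``; 0 when p = 1, +inf when p = 0."""
    if or_ < 0:
        raise ConfigurationError("odds ratio must be >= 0")
    if not 0 <= p <= 1:
        raise ConfigurationError(f"p-value {p} outside [0, 1]")
    if p == 0:
        warnings.warn("p = 0 in combined score; returning +inf", stacklevel=2)
        return math.inf
    if p == 1:
        return 0.0
    return or_ * (-math.log(p))


def enrich(query: set[str], lib: GeneSetLibrary) -> list[EnrichmentRow]:
    """Test every library term with a non-empty overlap against the query.

    The query is intersected with the library universe (when present)
    before testing; BH adjustment runs across all tested terms; rows are
    sorted by p ascending. The full table is returned — apply
    :func:`significant` for the reporting filter.
    """
    from roiflow.diffexp import bh_adjust

    if not query:
        raise ConfigurationError("empty query gene set")
    if lib.universe is not None:
        query = set(query) & lib.universe
        if not query:
            raise ConfigurationError("query is disjoint from the background universe")
    query = set(query)
    n = len(query)
    N = lib.background_size

    rows: list[EnrichmentRow] = []
    for term, genes in lib.terms.items():
        overlap = sorted(query & genes)
        k = len(overlap)
        if k == 0:
            continue
        K = len(genes)
        p = hypergeom_p(k, K, n, N)
        or_ = odds_ratio(k, K, n, N)
        rows.append(
            EnrichmentRow(
                term=term, k=k, K=K, n=n, p=p, adj_p=math.nan,
                odds_ratio=or_, combined_score=combined_score(or_, p),
                genes=overlap,
            )
        )
    if rows:
        adj = bh_adjust([r.p for r in rows])
        for row, a in zip(rows, adj):
            row.adj_p = float(a)
    rows.sort(key=lambda r: (r.p, r.term))
    return rows


def significant(rows: list[EnrichmentRow], alpha: float = 0.05) -> list[EnrichmentRow]:
    """Reporting filter: terms with adjusted p below ``alpha``."""
    return [r for r in rows if r.adj_p < alpha]


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view mirroring the result TSV column order."""
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "overlap": [f"{r.k}/{r.K}" for r in rows],
            "p_value": [r.p for r in rows],
            "adjusted_p_value": [r.adj_p for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "combined_score": [r.combined_score for r in rows],
            "genes": [";".join(r.genes) for r in rows],
        }
    )
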