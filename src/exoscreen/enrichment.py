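"""GO-term over-representation of target-gene sets.

One-sided hypergeometric tail test per term: with ``N`` genes in the
universe, ``K`` of them annotated to the term, and ``n`` targets of which
``k`` carry the term, the raw p-value is ``P(X >= k)`` for
``X ~ Hypergeometric(N, K, n)``.  Terms with no annotated target
(``k = 0``) are excluded from both the report and the correction family,
matching common term-finder behaviour; note this choice changes the
adjusted p-values because it changes the number of tests.  A term is
called enriched when its corrected p-value is below ``alpha``
(default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GOAnnotationMap",
    "EnrichmentResult",
    "hypergeom_tail",
    "adjust",
    "go_enrichment",
]


@dataclass
class GOAnnotationMap:
    """term -> gene set annotations over a fixed gene universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            stray = genes - self.universe
            if stray:
                raise ValueError(f"term {term!r} annotates genes outside the universe")
        if not self.universe:
            raise ValueError("empty gene universe")

    @classmethod
    def from_tsv(cls, path: str, universe: Optional[Iterable[str]] = None) -> "GOAnnotationMap":
        """Read a two-column ``term<TAB>gene_id`` file.

        The universe defaults to the union of annotated genes; pass the
        full annotation's gene list to get honest denominators.
        """
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene_id"], dtype=str)
        terms: dict[str, set[str]] = {}
        for term, gene in df.itertuples(index=False):
            terms.setdefault(str(term), set()).add(str(gene))
        frozen = {t: frozenset(g) for t, g in terms.items()}
        uni = frozenset(universe) if universe is not None else frozenset().union(*frozen.values())
        return cls(terms=frozen, universe=uni)


@dataclass
class EnrichmentResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    enriched: bool
    genes: list[str]


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k > K:
        return 0.0
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust(p_values: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing correction, order-preserving with the input.

    ``bonferroni``: min(1, m*p).  ``bh``: Benjamini-Hochberg step-up with
    monotonicity enforcement.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    name = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if name is None:
        raise ValueError(f"unknown correction method {method!r}")
    return multipletests(p, method=name)[1]


def go_enrichment(
    targets: AbstractSet[str],
    go_map: GOAnnotationMap,
    alpha: float = 0.1,
    method: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Test every annotated term for over-representation among targets.

    Targets outside the universe are dropped with a warning.  Only terms
    with ``k >= 1`` enter the report and the correction family.  Results
    are sorted by adjusted p-value (ties broken by term name).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    targets = frozenset(targets)
    stray = targets - go_map.universe
    if stray:
        warnings.warn(
            f"{len(stray)} target gene(s) outside the universe were dropped",
            RuntimeWarning,
            stacklevel=2,
        )
        targets = targets & go_map.universe
    N = len(go_map.universe)
    n = len(targets)
    rows = []
    for term, genes in go_map.terms.items():
        hit = targets & genes
        if not hit:
            continue
        rows.append((term, len(hit), len(genes), sorted(hit)))
    if not rows:
        return []
    p_raw = [hypergeom_tail(k, n, K, N) for _, k, K, _ in rows]
    p_adj = adjust(p_raw, method=method)
    results = [
        EnrichmentResult(
            term=term, k=k, n=n, K=K, N=N,
            p_raw=praw, p_adj=float(padj), enriched=bool(padj < alpha), genes=genes,
        )
        for (term, k, K, genes), praw, padj in zip(rows, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabular report: term, p values, k/n and K/N fractions, gene list."""
    rows = [
        (r.term, r.p_raw, r.p_adj, r.enriched, f"{r.k}/{r.n}", f"{r.K}/{r.N}", ",".join(r.genes))
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["term", "p_raw", "p_adj", "enriched", "targeted/total_targeted", "term/universe", "genes"],
    )
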