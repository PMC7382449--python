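"""Local over-representation analysis (ORA) against gene-set collections.

For a query list of n genes drawn from a universe of N genes, a set with
m members and k overlapping the query is scored by the exact
hypergeometric upper tail P[X ≥ k].  Raw p-values across tested sets are
adjusted by Benjamini–Hochberg FDR.  The universe defaults to the union
of all genes in the collection; a user-supplied reference list is
accepted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import read_gmt

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "ora_test",
    "enrich_all",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sets = {name: set(genes) for name, genes in self.sets.items()}
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        else:
            # harmonize: sets clipped to the declared universe
            self.sets = {n: g & self.universe for n, g in self.sets.items()}

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Optional[Iterable[str]] = None) -> "GeneSetCollection":
        return cls(sets=read_gmt(path), universe=set(universe) if universe else set())


@dataclass
class EnrichmentResult:
    set_name: str
    k_overlap: int
    n_query: int
    m_set: int
    N_universe: int
    p_raw: float
    p_adjusted: float
    overlap_genes: tuple[str, ...] = ()


def ora_test(query: set[str], target: set[str], universe: set[str]) -> float:
    """Exact hypergeometric upper-tail p-value P[X ≥ k] for the overlap of
    a query gene list with one target set inside a gene universe."""
    if not query or not target or not universe:
        raise ValueError("query, target and universe must be nonempty")
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes not in universe: {stray}")
    stray = sorted(target - universe)
    if stray:
        raise ValueError(f"target genes not in universe: {stray}")
    N, m, n = len(universe), len(target), len(query)
    k = len(query & target)
    # survival function is P[X > k-1] = P[X >= k]
    return float(min(1.0, hypergeom.sf(k - 1, N, m, n)))


def enrich_all(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_set_size: int = 3,
    universe: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Test the query against every set in the collection and BH-adjust.

    Sets smaller than ``min_set_size`` (after harmonization) are skipped.
    Results are sorted by (p_adjusted, p_raw, set_name) for a stable,
    reproducible ranking.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    uni = set(universe) if universe is not None else set(collection.universe)

    tested: list[tuple[str, set[str]]] = [
        (name, genes & uni)
        for name, genes in collection.sets.items()
        if len(genes & uni) >= min_set_size
    ]
    if not tested:
        return []
    p_raw = [ora_test(query_set, genes, uni) for _, genes in tested]
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")

    results = [
        EnrichmentResult(
            set_name=name,
            k_overlap=len(query_set & genes),
            n_query=len(query_set),
            m_set=len(genes),
            N_universe=len(uni),
            p_raw=p,
            p_adjusted=float(min(1.0, pa)),
            overlap_genes=tuple(sorted(query_set & genes)),
        )
        for (name, genes), p, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.set_name))
    return results
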