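"""Over-representation analysis and the pharmacogenomic annotation screen.

Enrichment of a query gene list in a gene-set library is tested with the
one-sided hypergeometric (Fisher exact) upper tail: with a universe of N
genes, a term of size s and a query of size q sharing k members,

    p = P(X >= k),  X ~ Hypergeometric(N, s, q)

and the odds ratio is the cross-product ratio of the 2x2 overlap table
(with a Haldane-Anscombe 0.5 added to every cell when any cell is zero).
q-values are Benjamini-Hochberg step-up adjusted within each library.

The PGx screen filters a curated variant-drug-phenotype annotation table
down to the genes of interest, optionally to significant rows or to a
phenotype substring, and reports per-gene counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .genelist import normalize_symbol

RSID_RE = re.compile(r"rs\d+")


@dataclass(frozen=True)
class GeneSet:
    term: str
    library: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise DomainError(f"gene set {self.term!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    library: str
    overlap_k: int
    set_size_s: int
    query_size_q: int
    universe_N: int
    p_value: float
    odds_ratio: float
    q_value: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


DEFAULT_UNIVERSE = 20_000  # protein-coding genome scale


def fisher_enrich(
    query: Iterable[str],
    geneset: GeneSet,
    universe_N: int = DEFAULT_UNIVERSE,
) -> EnrichmentResult:
    """One-sided over-representation test of ``query`` in one gene set."""
    query = {normalize_symbol(g) for g in query}
    members = {normalize_symbol(g) for g in geneset.members}
    q, s = len(query), len(members)
    k = len(query & members)
    if universe_N < max(s, q) or universe_N < q + s - k:
        raise DomainError(
            f"universe N={universe_N} smaller than the union of query ({q}) and set ({s})"
        )
    # upper tail P(X >= k)
    p = float(hypergeom.sf(k - 1, universe_N, s, q))
    a, b, c, d = k, q - k, s - k, universe_N - s - q + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return EnrichmentResult(
        term=geneset.term,
        library=geneset.library,
        overlap_k=k,
        set_size_s=s,
        query_size_q=q,
        universe_N=universe_N,
        p_value=min(1.0, p),
        odds_ratio=float(odds_ratio),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_library(
    query: Iterable[str],
    library: Sequence[GeneSet],
    universe_N: int = DEFAULT_UNIVERSE,
) -> list[EnrichmentResult]:
    """Test every term of a library; BH-adjust within it; rank by (q, p, term)."""
    query = [normalize_symbol(g) for g in query]
    if not query:
        raise DomainError("enrich_library requires a nonempty query")
    if not library:
        raise DomainError("enrich_library requires a nonempty library")
    results = [fisher_enrich(query, gs, universe_N) for gs in library]
    q_values = bh_adjust([r.p_value for r in results])
    results = [
        EnrichmentResult(**{**r.__dict__, "q_value": float(qv)})
        for r, qv in zip(results, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return results


def combined_score(result: EnrichmentResult, z_rank_deviation: float) -> float:
    """Enrichr-style combined score ln(p) * z (optional ranking aid)."""
    return float(-np.log(max(result.p_value, 1e-300)) * z_rank_deviation)


@dataclass(frozen=True)
class PGxAnnotation:
    gene: str
    variant: str
    association_text: str
    p_value: float
    drugs: tuple[str, ...]
    significant: bool
    phenotype: str = ""

    def __post_init__(self):
        if not RSID_RE.fullmatch(self.variant):
            raise DomainError(f"variant must be an rsID (rs\\d+), got {self.variant!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise DomainError(f"p_value must lie in (0, 1], got {self.p_value!r}")


def pgx_screen(
    genes: Iterable[str],
    annotations: Sequence[PGxAnnotation] | pd.DataFrame,
    phenotype_filter: str | None = None,
    significant_only: bool = False,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Filter a PGx annotation table to the genes of interest.

    Returns the filtered table, the per-gene row counts, and the total.
    ``phenotype_filter`` is a case-insensitive substring match.
    """
    genes = {normalize_symbol(g) for g in genes}
    if isinstance(annotations, pd.DataFrame):
        table = annotations.copy()
    else:
        table = pd.DataFrame(
            [
                {
                    "gene": a.gene,
                    "variant": a.variant,
                    "association_text": a.association_text,
                    "p_value": a.p_value,
                    "drugs": ";".join(a.drugs),
                    "significant": a.significant,
                    "phenotype": a.phenotype,
                }
                for a in annotations
            ]
        )
    if table.empty or not genes:
        empty = table.iloc[0:0]
        return empty, pd.Series(dtype=int), 0
    table["gene"] = table["gene"].map(normalize_symbol)
    mask = table["gene"].isin(genes)
    if significant_only and "significant" in table.columns:
        mask &= table["significant"].astype(bool)
    if phenotype_filter and "phenotype" in table.columns:
        mask &= table["phenotype"].str.contains(phenotype_filter, case=False, regex=False)
    filtered = table.loc[mask].reset_index(drop=True)
    counts = filtered.groupby("gene").size().sort_values(ascending=False)
    return filtered, counts, int(mask.sum())
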