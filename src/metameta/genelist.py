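"""Gene-list construction and refinement.

Three lists are built in sequence from the association records:

* PrePGL (pre-primary): every mapped gene supported by a genome-wide
  significant association after ruling out intergenic, non-coding
  transcript and synonymous variants;
* PGL (primary): the PrePGL restricted to protein-coding biotypes
  (pseudogenes and RNA genes dropped) and merged with a fixed risk-gene
  panel, with provenance tags (trait-derived, panel, or both);
* SGL (secondary): the PGL filtered for connectivity against a scored
  interaction table -- genes with no qualifying interaction partner
  inside the list are removed, in one or more rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .effects import AssociationRecord, EXCLUDED_CONTEXTS, GENOME_WIDE_THRESHOLD

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "pseudogene", "rna_gene", "unknown")
NONCODING_BIOTYPES = frozenset({"pseudogene", "rna_gene"})


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene symbol with provenance."""

    symbol: str
    biotype: str = "unknown"
    provenance: str = "cannabis"  # cannabis | gars_panel | both
    source_traits: frozenset[str] = frozenset()
    best_p: float | None = None


@dataclass(frozen=True)
class PanelDefinition:
    """A fixed risk-gene panel: ordered (symbol, variant, risk allele) rows."""

    name: str
    genes: tuple[tuple[str, str, str], ...]

    @property
    def symbols(self) -> list[str]:
        return [normalize_symbol(g[0]) for g in self.genes]


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def build_prepgl(
    associations: Iterable[AssociationRecord],
    annotation: Mapping[str, str] | None = None,
    threshold: float = GENOME_WIDE_THRESHOLD,
    excluded_contexts: frozenset[str] = EXCLUDED_CONTEXTS,
) -> list[GeneRecord]:
    """Pre-primary list: significant, context-filtered, deduplicated genes.

    Keeps records with p < ``threshold`` whose variant context is not in
    ``excluded_contexts``; symbols are deduplicated case-insensitively
    with the smallest supporting p retained.  ``annotation`` maps symbols
    to biotypes; unmapped symbols get biotype ``unknown``.
    """
    annotation = {normalize_symbol(k): v for k, v in (annotation or {}).items()}
    best: dict[str, GeneRecord] = {}
    for rec in associations:
        if rec.p_value is None or not (rec.p_value < threshold):
            continue
        if rec.variant_context in excluded_contexts:
            continue
        if not rec.mapped_gene or not rec.mapped_gene.strip():
            continue
        sym = normalize_symbol(rec.mapped_gene)
        prev = best.get(sym)
        traits = frozenset({rec.trait_id})
        if prev is None:
            best[sym] = GeneRecord(
                symbol=sym,
                biotype=annotation.get(sym, "unknown"),
                provenance="cannabis",
                source_traits=traits,
                best_p=rec.p_value,
            )
        else:
            best[sym] = replace(
                prev,
                best_p=min(prev.best_p, rec.p_value),
                source_traits=prev.source_traits | traits,
            )
    if not best:
        logger.warning("build_prepgl: no gene survived the filters")
    return [best[s] for s in sorted(best)]


def refine_to_pgl(prepgl: Sequence[GeneRecord], annotation: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Drop pseudogenes and RNA genes; unknown biotypes are kept with a warning."""
    annotation = {normalize_symbol(k): v for k, v in (annotation or {}).items()}
    out = []
    for g in prepgl:
        biotype = annotation.get(g.symbol, g.biotype)
        if biotype in NONCODING_BIOTYPES:
            continue
        if biotype == "unknown":
            logger.warning("refine_to_pgl: keeping %s with unknown biotype", g.symbol)
        out.append(replace(g, biotype=biotype))
    return out


def merge_panel(refined: Sequence[GeneRecord], panel: PanelDefinition) -> list[GeneRecord]:
    """Union of the refined list with a risk-gene panel, provenance-tagged.

    Genes present in both sources are tagged ``both`` and counted once;
    the primary-list size is ``len(refined) + len(panel) - overlap``.
    """
    merged = {g.symbol: g for g in refined}
    for sym in panel.symbols:
        if sym in merged:
            merged[sym] = replace(merged[sym], provenance="both")
        else:
            merged[sym] = GeneRecord(symbol=sym, biotype="protein_coding", provenance="gars_panel")
    return [merged[s] for s in sorted(merged)]


def connectivity_filter(
    genes: Sequence[GeneRecord],
    edges: Iterable[tuple[str, str, float]],
    score_min: float = 0.4,
    steps: int = 2,
) -> list[GeneRecord]:
    """Secondary list: drop genes with no qualifying in-list interaction.

    A graph is induced on the gene set using edges with score >=
    ``score_min`` whose endpoints both lie in the set; nodes with no
    neighbour other than themselves are removed, and the removal round is
    repeated ``steps`` times on the induced subgraph (a single round is
    already a fixed point, so extra rounds assert stability).
    """
    symbols = {g.symbol for g in genes}
    graph = nx.Graph()
    graph.add_nodes_from(symbols)
    for u, v, score in edges:
        u, v = normalize_symbol(u), normalize_symbol(v)
        if u in symbols and v in symbols and score >= score_min:
            graph.add_edge(u, v, score=score)
    surviving = set(symbols)
    for _ in range(max(1, steps)):
        sub = graph.subgraph(surviving)
        isolated = {n for n in sub.nodes if all(nbr == n for nbr in sub.neighbors(n))}
        if not isolated:
            break
        surviving -= isolated
    return [g for g in genes if g.symbol in surviving]
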