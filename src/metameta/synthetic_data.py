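"""Synthetic inputs with the statistical structure the pipeline assumes.

Studies are simulated directly on the Fisher-z scale: each study i draws
a true effect theta_i ~ Normal(mu, tau^2) and observes

    y_i = theta_i + eps_i,  eps_i ~ Normal(0, 1/(n_i - 3)),

from which the reported two-tailed p-value is 2 * Phi(-|y_i| sqrt(n_i-3)).
Publication bias is emulated by dropping each non-significant study
(p > alpha_sig) with probability ``suppress_prob``.  Each study
contributes one lead SNP carrying the study p-value plus optional
inflated-p companion SNPs.

The module also fabricates scored interaction tables with planted hubs
and bridge miRNAs, GMT gene-set libraries with one planted enriched
term, and PGx annotation rows.  Every generator draws from a stream
spawned off the master seed, so each table is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import ValidationError
from .effects import VARIANT_CONTEXTS

_DEFAULT_GENE_POOL = tuple(f"GENE{i:04d}" for i in range(400))
_DEFAULT_CONTEXT_PROBS = {
    "intergenic": 0.30,
    "non_coding_transcript": 0.15,
    "synonymous": 0.10,
    "missense": 0.20,
    "regulatory": 0.15,
    "other": 0.10,
}


@dataclass(frozen=True)
class NetworkParams:
    n_genes: int = 40
    n_mirnas: int = 15
    n_tfs: int = 8
    n_chemicals: int = 6
    density: float = 0.08
    hub_degree: int = 12
    n_hubs: int = 1
    n_bridges: int = 2
    panel_size: int = 6


@dataclass(frozen=True)
class LibraryParams:
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    planted_overlap: float = 0.8
    query_size: int = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Generative conditions for every synthetic table.

    Defaults mirror the analysis scale the pipeline targets: 13 studies
    (the scale of a multi-trait GWAS-catalog pull), true mean Fisher-z
    effect mu=0.02 with between-study SD tau=0.01, cohort sizes uniform
    on 5,000-50,000, and no suppression unless asked for.
    """

    seed: int = 0
    K_studies: int = 13
    mu: float = 0.02
    tau: float = 0.01
    n_range: tuple[int, int] = (5_000, 50_000)
    snps_per_study: int = 5
    suppress_prob: float = 0.0
    alpha_sig: float = 0.05
    gene_pool: tuple[str, ...] = _DEFAULT_GENE_POOL
    context_probs: dict = field(default_factory=lambda: dict(_DEFAULT_CONTEXT_PROBS))
    network_params: NetworkParams = field(default_factory=NetworkParams)
    library_params: LibraryParams = field(default_factory=LibraryParams)

    def __post_init__(self):
        if self.tau < 0:
            raise ValidationError(f"tau must be >= 0, got {self.tau}")
        if not (0.0 <= self.suppress_prob <= 1.0):
            raise ValidationError(f"suppress_prob must lie in [0, 1], got {self.suppress_prob}")
        if self.n_range[0] < 100 or self.n_range[1] < self.n_range[0]:
            raise ValidationError(f"invalid n_range {self.n_range} (min >= 100 required)")
        if self.K_studies < 1 or self.snps_per_study < 1:
            raise ValidationError("K_studies and snps_per_study must be >= 1")
        missing = set(self.context_probs) - set(VARIANT_CONTEXTS)
        if missing:
            raise ValidationError(f"unknown variant contexts: {sorted(missing)}")


def _stream(config: SimulationConfig, table: str) -> np.random.Generator:
    """One independent pseudorandom stream per table name."""
    idx = {"studies": 0, "interactions": 1, "genesets": 2, "pgx": 3}[table]
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[idx])


def simulate_studies(config: SimulationConfig) -> pd.DataFrame:
    """Association table: one lead SNP per surviving study plus companions."""
    rng = _stream(config, "studies")
    biotypes = ("protein_coding", "pseudogene", "rna_gene")
    contexts = list(config.context_probs)
    probs = np.array([config.context_probs[c] for c in contexts], dtype=float)
    probs = probs / probs.sum()
    rows = []
    for i in range(config.K_studies):
        n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
        theta = rng.normal(config.mu, config.tau)
        y = theta + rng.normal(0.0, 1.0 / np.sqrt(n - 3))
        z = y * np.sqrt(n - 3)
        p_lead = float(2.0 * ndtr(-abs(z)))
        p_lead = max(p_lead, 1e-300)
        if p_lead > config.alpha_sig and rng.random() < config.suppress_prob:
            continue  # study never published
        study_id = f"GCST{900000 + i}"
        trait_id = f"EFO_{7000 + i % 3}"
        for snp in range(config.snps_per_study):
            if snp == 0:
                p = p_lead
            else:
                # companion SNPs are weaker signals from the same locus
                p = min(1.0, p_lead * 10 ** rng.uniform(2.0, 6.0))
            gene = str(rng.choice(config.gene_pool))
            rows.append(
                {
                    "study_id": study_id,
                    "trait_id": trait_id,
                    "rsid": f"rs{int(rng.integers(10**6, 10**8))}",
                    "mapped_gene": gene,
                    "variant_context": str(rng.choice(contexts, p=probs)),
                    "p_value": p,
                    "sample_size": n,
                    "effect_text": "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "trait_id",
            "rsid",
            "mapped_gene",
            "variant_context",
            "p_value",
            "sample_size",
            "effect_text",
        ],
    )


def gene_biotypes(config: SimulationConfig) -> dict[str, str]:
    """Deterministic biotype annotation over the configured gene pool."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    biotypes = np.array(["protein_coding", "pseudogene", "rna_gene"])
    draws = rng.choice(biotypes, size=len(config.gene_pool), p=[0.75, 0.13, 0.12])
    return {g: str(b) for g, b in zip(config.gene_pool, draws)}


def simulate_interactions(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Layered edge tables with planted hubs and bridge miRNAs.

    Returns (edge table with columns source/target/layer/score, role map).
    Hubs are genes wired to ``hub_degree`` partners in the ppi layer;
    bridges are miRNAs adjacent to at least one panel gene and one
    non-panel ("trait") gene in the gmi layer.  Planted node ids carry
    ``HUB``/``BRIDGE`` markers so tests can identify them.
    """
    p = config.network_params
    if p.hub_degree > p.n_genes - 1:
        raise ValidationError(
            f"hub degree {p.hub_degree} exceeds available genes ({p.n_genes - 1})"
        )
    if p.panel_size >= p.n_genes:
        raise ValidationError("panel_size must be smaller than n_genes")
    rng = _stream(config, "interactions")
    genes = [f"G{i:03d}" for i in range(p.n_genes)]
    for h in range(p.n_hubs):
        genes[h] = f"GHUB{h:02d}"
    mirnas = [f"hsa-miR-{i}" for i in range(p.n_mirnas)]
    for b in range(min(p.n_bridges, p.n_mirnas)):
        mirnas[b] = f"hsa-miR-BRIDGE{b}"
    tfs = [f"TF{i:02d}" for i in range(p.n_tfs)]
    chems = [f"CHEM{i:02d}" for i in range(p.n_chemicals)]
    role_map = (
        {g: "gene" for g in genes}
        | {m: "mirna" for m in mirnas}
        | {t: "tf" for t in tfs}
        | {c: "chemical" for c in chems}
    )
    panel = genes[p.n_hubs : p.n_hubs + p.panel_size]
    trait = [g for g in genes if g not in panel]
    edges: set[tuple[str, str, str]] = set()

    def add(u: str, v: str, layer: str):
        if u != v:
            edges.add((u, v, layer) if u < v else (v, u, layer))

    # background density per layer
    for pool_a, pool_b, layer in (
        (genes, genes, "ppi"),
        (genes, mirnas, "gmi"),
        (tfs, genes, "tf"),
        (chems, genes, "chem"),
    ):
        n_possible = len(pool_a) * len(pool_b)
        n_draw = rng.binomial(n_possible, p.density) if p.density > 0 else 0
        for _ in range(n_draw):
            add(str(rng.choice(pool_a)), str(rng.choice(pool_b)), layer)
    # planted hubs
    for h in range(p.n_hubs):
        partners = rng.choice([g for g in genes if g != genes[h]], size=p.hub_degree, replace=False)
        for q in partners:
            add(genes[h], str(q), "ppi")
    # planted bridges
    for b in range(min(p.n_bridges, p.n_mirnas)):
        add(mirnas[b], str(rng.choice(panel)), "gmi")
        add(mirnas[b], str(rng.choice(trait)), "gmi")
    rows = [
        {"source": u, "target": v, "layer": layer, "score": round(float(rng.uniform(0.15, 0.999)), 3)}
        for u, v, layer in sorted(edges)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "layer", "score"]), role_map


def simulate_genesets(config: SimulationConfig) -> tuple[list, list[str]]:
    """GMT library with one planted enriched term.

    Returns (list of GeneSet, the designated query gene list).  The
    planted term (named ``PLANTED_TERM``) contains ceil(overlap * q) of
    the query plus random padding; background terms are uniform draws.
    """
    from .enrichment import GeneSet

    lp = config.library_params
    if not (0.0 <= lp.planted_overlap <= 1.0):
        raise ValidationError(f"planted_overlap must lie in [0, 1], got {lp.planted_overlap}")
    if lp.term_size_range[1] > len(config.gene_pool):
        raise ValidationError("term size exceeds gene pool")
    rng = _stream(config, "genesets")
    pool = np.array(config.gene_pool)
    query = [str(g) for g in rng.choice(pool, size=lp.query_size, replace=False)]
    sets = []
    for i in range(lp.n_terms - 1):
        size = int(rng.integers(lp.term_size_range[0], lp.term_size_range[1] + 1))
        members = frozenset(str(g) for g in rng.choice(pool, size=size, replace=False))
        sets.append(GeneSet(term=f"TERM_{i:03d}", library="synthetic", members=members))
    k_plant = int(np.ceil(lp.planted_overlap * lp.query_size))
    planted = set(query[:k_plant])
    size = max(int(rng.integers(*lp.term_size_range)), k_plant + 1, 1)
    non_query = [g for g in pool if g not in query]
    pad = rng.choice(non_query, size=max(0, size - len(planted)), replace=False)
    planted |= {str(g) for g in pad}
    if not planted:
        planted = {str(pool[0])}
    sets.append(GeneSet(term="PLANTED_TERM", library="synthetic", members=frozenset(planted)))
    return sets, query


def simulate_pgx(
    config: SimulationConfig,
    n_rows: int = 100,
    significance_rate: float = 0.4,
    phenotype: str = "Heroin Dependence",
) -> pd.DataFrame:
    """PGx annotation rows over the gene pool with rs-formatted variants."""
    if not (0.0 <= significance_rate <= 1.0):
        raise ValidationError(f"significance_rate must lie in [0, 1], got {significance_rate}")
    rng = _stream(config, "pgx")
    drugs = ("heroin", "methadone", "cotinine", "cocaine", "naltrexone")
    rows = []
    for _ in range(n_rows):
        significant = bool(rng.random() < significance_rate)
        p = float(10 ** rng.uniform(-6, np.log10(0.049))) if significant else float(rng.uniform(0.05, 1.0))
        gene = str(rng.choice(config.gene_pool))
        drug = str(rng.choice(drugs))
        rows.append(
            {
                "gene": gene,
                "variant": f"rs{int(rng.integers(10**3, 10**8))}",
                "association_text": f"Allele A is associated with {phenotype} as compared to allele G.",
                "p_value": p,
                "drugs": drug,
                "significant": significant,
                "phenotype": phenotype,
            }
        )
    return pd.DataFrame(rows)
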