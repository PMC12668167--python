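# metameta

Second-level ("meta-meta") GWAS meta-analysis from (p-value, sample-size)
summaries, with the downstream systems-biology stages that typically
follow it: publication-bias diagnostics, gene-list refinement against
scored interaction tables, gene–miRNA / TF co-regulatory network
statistics, offline gene-set enrichment, and pharmacogenomic annotation
screening.

## Who this is for

GWAS-catalog pulls for a phenotype often span several trait accessions,
each already summarized by its own meta-analysis, and often the only
usable numbers per study are a two-tailed p-value and a total sample
size n. `metameta` makes that enough: each study is converted to a
Fisher-z partial-correlation effect

    z_r = Φ⁻¹(1 − p/2) / √(n − 3),   SE = 1/√(n − 3),

studies are pooled per trait with DerSimonian–Laird (DL) random effects

    Q = Σ wᵢ(yᵢ − ȳ)²,  τ² = max(0, (Q − (K−1))/C),  wᵢ* = 1/(SEᵢ² + τ²),

and the trait-level summaries are pooled again in a second level, each
group entering as one pseudo-study rebuilt from its pooled p and total
n. Everything operates on local tables (TSV/GMT); no web services are
queried. A synthetic-data module generates statistically faithful
inputs for every stage, so the whole pipeline is testable offline.

## Worked example

The packaged fixture carries three trait-level summaries (7 studies /
n=1,190,454 at p<6.5e-8; 5 studies / n=568,944 at p=1.48e-5; 1 study /
n=14,754 at p=2e-8 — 13 studies and 1,774,152 subjects in all):

```python
from metameta import GroupSummary, meta_meta
from metameta.io import meta_group_inputs

groups = [
    GroupSummary(label=r["group"], p_value=float(r["p_value"]), total_n=int(r["total_n"]))
    for _, r in meta_group_inputs().iterrows()
]
r = meta_meta(groups)   # pseudo_study mode, DL random effects
print(f"pooled={r.pooled_z:.3f} ci=[{r.ci_lower:.3f},{r.ci_upper:.3f}] "
      f"Z={r.z_stat:.2f} p={r.p_value:.2e} I2={r.I2:.1f}")
print(dict(r.weights))
```

prints

```
pooled=0.011 ci=[0.004,0.018] Z=3.01 p=2.64e-03 I2=91.9
{'Meta1': 43.9, 'Meta2': 42.6, 'Meta3': 13.5}
```

i.e. a small but significant pooled Fisher-z effect (Z=3.01): the two
large trait groups carry nearly equal weight and the single-study group
contributes the rest, with high heterogeneity across traits — exactly
the structure a forest plot of the three groups shows. The same numbers
are available from the shell:

```
metameta metameta groups.tsv --out metameta.json
# meta-meta z=0.011 [0.004, 0.018], Z=3.01, p=0.00264
```

The bias battery on the same three pseudo-studies gives Kendall τ=1.00
(0.67 continuity-corrected), classic fail-safe N≈58, and one study
imputed by trim-and-fill — small-K diagnostics to be read with the usual
caution. Other subcommands: `simulate`, `select`, `meta`, `bias`,
`refine`, `network`, `enrich`, `pgx`, and `run --config pipeline.yaml`
for the full staged pipeline with a per-stage exclusion log.

## Layout

| module | contents |
|---|---|
| `metameta.effects` | p→Z conversion, Fisher-z effects, two-phase study selection |
| `metameta.meta_engine` | fixed / DL random pooling, meta-meta, forest data |
| `metameta.bias_diagnostics` | fail-safe N, Begg–Mazumdar, Egger, trim-and-fill, funnel data |
| `metameta.genelist` | PrePGL → PGL → SGL refinement, panel merge, connectivity filter |
| `metameta.network_stats` | typed multilayer graphs, degree/betweenness, bridge nodes |
| `metameta.enrichment` | hypergeometric over-representation, BH q-values, PGx screen |
| `metameta.synthetic_data` | generators for all of the above, seed-stable |
| `metameta.io` / `metameta.pipeline` / `metameta.cli` | table dialects, fixtures, staged driver, CLI |

See `docs/methods.md` for the model, its assumptions, and known
limitations (notably the measured power of trim-and-fill against
study-level suppression).
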