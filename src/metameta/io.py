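"""Readers and writers for every table dialect plus packaged fixtures.

All tables are UTF-8 TSV with a mandatory header row and '.' decimals;
scientific notation is accepted for p-values.  Column names of
association tables are configurable through a mapping (e.g. loaded from
YAML) so GWAS-catalog exports with their native headers can be read
unchanged.  Malformed rows are collected into a rejects report, never
silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effects import AssociationRecord
from .enrichment import GeneSet
from .errors import ValidationError
from .genelist import GeneRecord, PanelDefinition
from .network_stats import EdgeRecord

ASSOCIATION_COLUMNS = (
    "study_id",
    "trait_id",
    "rsid",
    "mapped_gene",
    "variant_context",
    "p_value",
    "sample_size",
)


@dataclass
class RejectReport:
    """Rows that failed validation, with the reason for each."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, line_no: int, reason: str) -> None:
        self.rows.append((line_no, reason))

    def __len__(self) -> int:
        return len(self.rows)


def read_associations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[AssociationRecord], RejectReport]:
    """Read an association TSV into typed records.

    ``column_map`` maps canonical names (study_id, trait_id, rsid,
    mapped_gene, variant_context, p_value, sample_size, effect_text) to
    the file's actual headers; identity by default.
    """
    column_map = dict(column_map or {})
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {column_map.get(c, c): c for c in ASSOCIATION_COLUMNS + ("effect_text",)}
    table = table.rename(columns=rename)
    missing = [c for c in ASSOCIATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"association table {path} is missing columns: {', '.join(missing)}")
    records: list[AssociationRecord] = []
    rejects = RejectReport()
    for idx, row in table.iterrows():
        line_no = int(idx) + 2  # header is line 1
        p_raw, n_raw = row["p_value"], row["sample_size"]
        if p_raw in ("", "NA", "NaN") or n_raw in ("", "NA", "NaN"):
            rejects.add(line_no, "missing p_value or sample_size")
            continue
        try:
            p = float(p_raw)
            n = int(float(n_raw))
        except (TypeError, ValueError) as exc:
            rejects.add(line_no, f"unparseable p/n: {exc}")
            continue
        try:
            records.append(
                AssociationRecord(
                    study_id=row["study_id"],
                    trait_id=row["trait_id"],
                    rsid=row["rsid"],
                    mapped_gene=row["mapped_gene"],
                    variant_context=row["variant_context"],
                    p_value=p,
                    sample_size=n,
                    effect_text=row.get("effect_text", "") or None,
                )
            )
        except Exception as exc:
            rejects.add(line_no, str(exc))
    return records, rejects


def write_associations(records: Iterable[AssociationRecord], path: str | Path) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "trait_id": r.trait_id,
            "rsid": r.rsid,
            "mapped_gene": r.mapped_gene,
            "variant_context": r.variant_context,
            "p_value": "" if r.p_value is None else repr(r.p_value),
            "sample_size": "" if r.sample_size is None else r.sample_size,
            "effect_text": r.effect_text or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS + ("effect_text",)).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: term <tab> description <tab> member genes...

    The description field is ignored; members are uppercased, empty
    members dropped.  Lines with fewer than three fields raise a parse
    error naming the line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{line_no}: GMT line has fewer than 3 fields")
            term = fields[0]
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise ValidationError(f"{path}:{line_no}: GMT term {term!r} has no members")
            sets.append(GeneSet(term=term, library=Path(path).stem, members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term, gs.library] + sorted(gs.members)) + "\n")


def read_edges(path: str | Path) -> list[EdgeRecord]:
    """Edge TSV: source, target, optional layer, optional score."""
    table = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for col in ("source", "target"):
        if col not in table.columns:
            raise ValidationError(f"edge table {path} is missing column {col!r}")
    return [
        EdgeRecord(
            source=row["source"],
            target=row["target"],
            layer=row.get("layer", "ppi") if "layer" in table.columns else "ppi",
            score=float(row["score"]) if "score" in table.columns and pd.notna(row["score"]) else None,
        )
        for _, row in table.iterrows()
    ]


def write_edges(edges: Iterable[EdgeRecord], path: str | Path) -> None:
    pd.DataFrame([e.__dict__ for e in edges]).to_csv(path, sep="\t", index=False)


def read_scored_edges(path: str | Path) -> list[tuple[str, str, float]]:
    """3-column interaction TSV (source, target, score) for the SGL filter."""
    return [(e.source, e.target, e.score if e.score is not None else 1.0) for e in read_edges(path)]


def write_gene_list(genes: Sequence[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "biotype": g.biotype,
                "provenance": g.provenance,
                "best_p": "" if g.best_p is None else repr(g.best_p),
                "source_traits": ";".join(sorted(g.source_traits)),
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path, name: str = "panel") -> PanelDefinition:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return PanelDefinition(
        name=name,
        genes=tuple((r["symbol"], r["variant"], r["risk_allele"]) for _, r in table.iterrows()),
    )


def read_pgx(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant": str})
    required = {"gene", "variant", "p_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"PGx table {path} is missing columns: {sorted(missing)}")
    if "significant" in table.columns:
        table["significant"] = table["significant"].astype(str).str.lower().isin(("true", "1", "yes"))
    return table


def write_meta_result(result, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# packaged fixtures (transcribed from the source study's printed tables)

def _data_path(name: str):
    return resources.files("metameta.data").joinpath(name)


def gars_panel() -> PanelDefinition:
    """The 10-gene dopaminergic risk panel (symbol, variant, risk allele)."""
    with resources.as_file(_data_path("gars_panel.tsv")) as p:
        return read_panel(p, name="GARS")


def meta_group_inputs() -> pd.DataFrame:
    """The three trait-level meta-analysis summaries: (group, trait, k, n, p)."""
    with resources.as_file(_data_path("meta_groups.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def pgx_annotations() -> pd.DataFrame:
    """The packaged heroin-dependence PGx annotation rows."""
    with resources.as_file(_data_path("pgx_heroin.tsv")) as p:
        return read_pgx(p)
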