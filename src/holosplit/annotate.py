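"""Annotation bookkeeping over protein and domain hit tables.

The searches themselves (protein database, domain models) are external
and database-version dependent; this module consumes their tabular
output, applies the e-value cutoff, attaches best-hit descriptions,
computes annotation rates as printed percentages, and supports keyword
queries for reproduction-related genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AnnotationHit",
    "AnnotationTable",
    "annotation_rate",
    "best_hit_annotation",
    "keyword_search",
    "set_crosstab_percent",
    "parse_annotated_hits",
]


@dataclass(frozen=True)
class AnnotationHit:
    """One row of a protein/domain hit table with an optional description."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    description: str = ""


@dataclass
class AnnotationTable:
    """Per-contig best hits under an e-value cutoff, plus the universe size."""

    source: str  # "protein_db" | "domain_db"
    max_evalue: float
    best_hits: dict[str, AnnotationHit]  # contig id -> its best hit
    n_universe: int

    @property
    def n_annotated(self) -> int:
        return len(self.best_hits)

    @property
    def rate_percent(self) -> float:
        return annotation_rate(self.n_annotated, self.n_universe)


def _round_half_up(value: float, decimals: int) -> float:
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def annotation_rate(n_annotated: int, n_total: int) -> float:
    """Annotation rate as a percentage rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_annotated <= n_total:
        raise ValueError("n_annotated must lie in [0, n_total]")
    return _round_half_up(100.0 * n_annotated / n_total, 1)


def set_crosstab_percent(subset_size: int, set_size: int) -> int:
    """Share of a set falling in a subset, as an integer percentage
    (half-up), the convention used for pie-chart style summaries."""
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if not 0 <= subset_size <= set_size:
        raise ValueError("subset_size must lie in [0, set_size]")
    return int(_round_half_up(100.0 * subset_size / set_size, 0))


def parse_annotated_hits(path: str | Path) -> list[AnnotationHit]:
    """Parse a 12-column tabular hit file with an optional 13th
    description column (the "salltitles"-style extension)."""
    hits: list[AnnotationHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 columns, got {len(fields)}"
                )
            hits.append(
                AnnotationHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    description=fields[12] if len(fields) > 12 else "",
                )
            )
    return hits


def best_hit_annotation(
    hits: Iterable[AnnotationHit],
    n_universe: int,
    max_evalue: float = 1e-5,
    source: str = "protein_db",
) -> AnnotationTable:
    """Keep, per query, the hit with the lowest e-value (ties: highest
    bitscore, then lexicographic subject id) among hits within the cutoff."""
    best: dict[str, AnnotationHit] = {}
    for hit in hits:
        if hit.evalue > max_evalue:
            continue
        cur = best.get(hit.query_id)
        if cur is None or (hit.evalue, -hit.bitscore, hit.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return AnnotationTable(source, max_evalue, best, n_universe)


def keyword_search(table: AnnotationTable, terms: Sequence[str]) -> set[str]:
    """Contig ids whose best-hit description contains any of the terms
    (case-insensitive substring match; union without duplicates)."""
    if not terms:
        raise ValueError("terms must be nonempty")
    lowered = [t.lower() for t in terms]
    return {
        contig_id
        for contig_id, hit in table.best_hits.items()
        if any(t in hit.description.lower() for t in lowered)
    }
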