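"""Term over-representation by the hypergeometric upper tail.

Given a foreground gene set (e.g. genes upregulated in mature testes), a
background universe and a term -> genes map, each term is scored by the
exact probability of drawing at least the observed number of term genes
in a sample of the foreground's size, together with its fold enrichment
(k/n)/(K/N).  A term passes under the default filters when fold > 4 and
P < 0.05; P-values are reported raw (a BH column is emitted for
information only, as the filter operates on raw P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .expression import benjamini_hochberg

__all__ = ["TermMap", "EnrichmentRecord", "hypergeom_tail", "enrich"]


@dataclass
class TermMap:
    """term id -> annotated gene ids, with optional names/categories."""

    genes_by_term: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)  # BP | CC | MF

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.genes_by_term.values():
            out |= genes
        return out

    @classmethod
    def from_tsv(
        cls, pairs_path: str | Path, meta_path: str | Path | None = None
    ) -> "TermMap":
        """Read a 2-column (term, gene) TSV plus an optional
        (term, name, category) metadata TSV."""
        genes_by_term: dict[str, set[str]] = {}
        with open(pairs_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, gene = line.split("\t")[:2]
                genes_by_term.setdefault(term, set()).add(gene)
        names: dict[str, str] = {}
        categories: dict[str, str] = {}
        if meta_path is not None:
            with open(meta_path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    fields = line.split("\t")
                    names[fields[0]] = fields[1] if len(fields) > 1 else ""
                    if len(fields) > 2:
                        categories[fields[0]] = fields[2]
        return cls(genes_by_term, names, categories)


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's over-representation statistics on a foreground set."""

    term: str
    k: int  # foreground genes carrying the term
    n: int  # foreground size
    K: int  # universe genes carrying the term
    N: int  # universe size
    fold: float
    p: float
    q: float  # BH over tested terms, informational
    passes: bool


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    foreground: Iterable[str],
    term_map: TermMap,
    universe: Iterable[str],
    min_fold: float = 4.0,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Score every term with at least one foreground gene, sorted by P.

    ``passes`` is strict on both filters: fold > ``min_fold`` and
    p < ``alpha``.  The foreground must be contained in the universe.
    """
    universe = set(universe)
    foreground = set(foreground)
    outside = foreground - universe
    if outside:
        raise ValueError(
            f"foreground genes outside the universe: {sorted(outside)[:5]}"
        )
    n, N = len(foreground), len(universe)
    records: list[EnrichmentRecord] = []
    raw: list[tuple[str, int, int, float, float]] = []
    for term, genes in term_map.genes_by_term.items():
        K = len(genes & universe)
        k = len(genes & foreground)
        if k < 1:
            continue
        fold = (k / n) / (K / N)
        p = hypergeom_tail(k, n, K, N)
        raw.append((term, k, K, fold, p))
    if not raw:
        return []
    qvals = benjamini_hochberg([r[4] for r in raw])
    for (term, k, K, fold, p), q in zip(raw, qvals):
        records.append(
            EnrichmentRecord(
                term=term,
                k=k,
                n=n,
                K=K,
                N=N,
                fold=fold,
                p=p,
                q=float(q),
                passes=(fold > min_fold) and (p < alpha),
            )
        )
    records.sort(key=lambda r: (r.p, -r.fold, r.term))
    return records


def to_frame(records: Sequence[EnrichmentRecord], term_map: TermMap) -> pd.DataFrame:
    """Tabular view of enrichment results."""
    return pd.DataFrame(
        {
            "term": [r.term for r in records],
            "name": [term_map.names.get(r.term, "") for r in records],
            "category": [term_map.categories.get(r.term, "") for r in records],
            "k": [r.k for r in records],
            "n": [r.n for r in records],
            "K": [r.K for r in records],
            "N": [r.N for r in records],
            "fold": [r.fold for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "passes": [r.passes for r in records],
        }
    )
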