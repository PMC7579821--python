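"""Taxonomic partitioning of holobiont assembly contigs.

A coral gonad assembly mixes transcripts from the coral host, its
intracellular dinoflagellate symbionts (Symbiodiniaceae) and other
organisms.  Each contig is classified from alignment evidence against a
host database and a symbiont database:

* hits against one database only -> exclusive call;
* hits against both -> the single top hit over the combined databases
  decides (ranked by bitscore, then lower e-value, longer alignment, and
  host before symbiont as the final deterministic tie-break);
* no hits -> "other".

The module consumes standard 12-column tabular alignment files; a
built-in k-mer containment screen provides alignment-free pseudo-hits so
the flow can run without an external aligner.  A branch-count ledger with
conservation identities and per-class GC histograms validate the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqcore import ContigSet, SequenceRecord, gc_content, reverse_complement

__all__ = [
    "HitRecord",
    "AssignmentRecord",
    "PartitionLedger",
    "GcProfile",
    "parse_hit_table",
    "kmer_screen",
    "assign_contigs",
    "ledger_totals",
    "gc_profile",
]

HOST = "host"
SYMBIONT = "symbiont"
OTHER = "other"


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit in the 12-column tabular convention
    (1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    subject_db: str  # "host" | "symbiont"
    percent_identity: float
    align_len: int
    evalue: float
    bitscore: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.bitscore < 0 or self.align_len < 1:
            raise ValueError(f"invalid hit for query {self.query_id!r}")


@dataclass(frozen=True)
class AssignmentRecord:
    """Final class call for one contig with the branch it took."""

    contig_id: str
    call: str  # host | symbiont | other
    branch: str  # exclusive_host | exclusive_symbiont |
    #              ambiguous_resolved_host | ambiguous_resolved_symbiont | no_hit
    best_host_bitscore: float | None = None
    best_symbiont_bitscore: float | None = None


@dataclass(frozen=True)
class PartitionLedger:
    """Branch counts with conservation identities (checked on construction)."""

    n_total: int
    n_exclusive_host: int
    n_exclusive_symbiont: int
    n_ambiguous: int
    n_ambiguous_to_host: int
    n_ambiguous_to_symbiont: int
    n_no_hit: int
    n_host_final: int
    n_symbiont_final: int

    def __post_init__(self) -> None:
        errors = []
        if (
            self.n_exclusive_host
            + self.n_exclusive_symbiont
            + self.n_ambiguous
            + self.n_no_hit
            != self.n_total
        ):
            errors.append("exclusive + ambiguous + no_hit != total")
        if self.n_ambiguous_to_host + self.n_ambiguous_to_symbiont != self.n_ambiguous:
            errors.append("ambiguous_to_host + ambiguous_to_symbiont != ambiguous")
        if self.n_host_final != self.n_exclusive_host + self.n_ambiguous_to_host:
            errors.append("host_final != exclusive_host + ambiguous_to_host")
        if (
            self.n_symbiont_final
            != self.n_exclusive_symbiont + self.n_ambiguous_to_symbiont
        ):
            errors.append("symbiont_final != exclusive_symbiont + ambiguous_to_symbiont")
        if any(
            v < 0
            for v in (
                self.n_total,
                self.n_exclusive_host,
                self.n_exclusive_symbiont,
                self.n_ambiguous,
                self.n_ambiguous_to_host,
                self.n_ambiguous_to_symbiont,
                self.n_no_hit,
            )
        ):
            errors.append("negative branch count")
        if errors:
            raise ValueError("ledger identities violated: " + "; ".join(errors))


@dataclass(frozen=True)
class GcProfile:
    """Per-class GC histogram at 1% bins (edges in percent)."""

    label: str
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    mode_percent: float | None


def parse_hit_table(
    path: str | Path, db_label: str, max_evalue: float = 1e-3
) -> list[HitRecord]:
    """Parse a 12-column tab-separated alignment hit table.

    Rows with e-value above ``max_evalue`` are dropped (<= is kept).
    Malformed rows raise with their line number.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_db=db_label,
                    percent_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if hit.evalue <= max_evalue:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# k-mer containment screen (alignment-free stand-in for an external aligner)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    n = len(seq)
    return {
        min(seq[i : i + k], rc[n - i - k : n - i]) for i in range(n - k + 1)
    }


def kmer_screen(
    contigs: Iterable[SequenceRecord],
    host_refs: Iterable[SequenceRecord],
    symbiont_refs: Iterable[SequenceRecord],
    k: int = 21,
    min_containment: float = 0.2,
) -> list[HitRecord]:
    """Emit pseudo-hits from canonical k-mer containment against each database.

    For a contig and a database, containment is the fraction of the
    contig's canonical k-mers present in the pooled database k-mer set.
    A pseudo-hit is emitted when containment >= ``min_containment``, with
    pseudo-bitscore = containment x contig length / k (so longer, better
    contained contigs rank higher, loosely mirroring alignment scores).
    Contigs shorter than ``k`` yield no hits.
    """
    db_sets = {}
    for label, refs in ((HOST, host_refs), (SYMBIONT, symbiont_refs)):
        pooled: set[str] = set()
        for ref in refs:
            if len(ref) >= k:
                pooled |= _canonical_kmers(ref.seq, k)
        if not pooled:
            raise ValueError(f"{label} reference set has no sequences of length >= k")
        db_sets[label] = pooled
    hits: list[HitRecord] = []
    for contig in contigs:
        if len(contig) < k:
            continue
        kmers = _canonical_kmers(contig.seq, k)
        for label, db in db_sets.items():
            containment = len(kmers & db) / len(kmers)
            if containment >= min_containment:
                hits.append(
                    HitRecord(
                        query_id=contig.id,
                        subject_id=f"{label}_db",
                        subject_db=label,
                        percent_identity=100.0 * containment,
                        align_len=len(contig),
                        evalue=0.0,
                        bitscore=containment * len(contig) / k,
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Assignment


def _hit_rank(hit: HitRecord) -> tuple:
    # Higher bitscore, then lower evalue, then longer alignment, then host first.
    return (-hit.bitscore, hit.evalue, -hit.align_len, 0 if hit.subject_db == HOST else 1)


def assign_contigs(
    contigs: ContigSet,
    host_hits: Sequence[HitRecord],
    symbiont_hits: Sequence[HitRecord],
) -> tuple[list[AssignmentRecord], PartitionLedger]:
    """Classify every contig as host / symbiont / other from hit evidence.

    Contigs hitting one database only get an exclusive call; contigs
    hitting both are resolved by the top hit over the combined hit set;
    contigs with no hits are "other".  Output order follows the contig
    set; the result is invariant to the input order of hit rows.
    """
    by_query: dict[str, dict[str, list[HitRecord]]] = {}
    for hit in list(host_hits) + list(symbiont_hits):
        if hit.query_id not in contigs:
            raise ValueError(
                f"hit query {hit.query_id!r} is not in the contig set"
            )
        by_query.setdefault(hit.query_id, {HOST: [], SYMBIONT: []})[
            hit.subject_db
        ].append(hit)

    assignments: list[AssignmentRecord] = []
    n_excl_host = n_excl_sym = n_amb_host = n_amb_sym = n_none = 0
    for contig in contigs:
        hits = by_query.get(contig.id)
        h = sorted(hits[HOST], key=_hit_rank) if hits else []
        s = sorted(hits[SYMBIONT], key=_hit_rank) if hits else []
        best_h = h[0].bitscore if h else None
        best_s = s[0].bitscore if s else None
        if h and s:
            top = min(h[0], s[0], key=_hit_rank)
            if top.subject_db == HOST:
                call, branch = HOST, "ambiguous_resolved_host"
                n_amb_host += 1
            else:
                call, branch = SYMBIONT, "ambiguous_resolved_symbiont"
                n_amb_sym += 1
        elif h:
            call, branch = HOST, "exclusive_host"
            n_excl_host += 1
        elif s:
            call, branch = SYMBIONT, "exclusive_symbiont"
            n_excl_sym += 1
        else:
            call, branch = OTHER, "no_hit"
            n_none += 1
        assignments.append(
            AssignmentRecord(contig.id, call, branch, best_h, best_s)
        )
    ledger = ledger_totals(
        n_exclusive_host=n_excl_host,
        n_exclusive_symbiont=n_excl_sym,
        n_ambiguous_to_host=n_amb_host,
        n_ambiguous_to_symbiont=n_amb_sym,
        n_no_hit=n_none,
    )
    return assignments, ledger


def ledger_totals(
    n_exclusive_host: int,
    n_exclusive_symbiont: int,
    n_ambiguous_to_host: int,
    n_ambiguous_to_symbiont: int,
    n_no_hit: int = 0,
) -> PartitionLedger:
    """Derive all ledger totals from the primitive branch counts.

    The conservation identities (exclusive + ambiguous + no-hit = total;
    final class sizes = exclusive + resolved-ambiguous) hold by
    construction and are re-checked by the ledger itself.
    """
    n_ambiguous = n_ambiguous_to_host + n_ambiguous_to_symbiont
    return PartitionLedger(
        n_total=n_exclusive_host + n_exclusive_symbiont + n_ambiguous + n_no_hit,
        n_exclusive_host=n_exclusive_host,
        n_exclusive_symbiont=n_exclusive_symbiont,
        n_ambiguous=n_ambiguous,
        n_ambiguous_to_host=n_ambiguous_to_host,
        n_ambiguous_to_symbiont=n_ambiguous_to_symbiont,
        n_no_hit=n_no_hit,
        n_host_final=n_exclusive_host + n_ambiguous_to_host,
        n_symbiont_final=n_exclusive_symbiont + n_ambiguous_to_symbiont,
    )


def gc_profile(
    contigs: ContigSet, assignments: Sequence[AssignmentRecord]
) -> list[GcProfile]:
    """Per-class GC histograms at 1% bins plus an "all" profile.

    The mode is the centre of the fullest bin (lowest bin on ties);
    empty classes get an empty histogram and no mode.
    """
    calls = {a.contig_id: a.call for a in assignments}
    missing = [c.id for c in contigs if c.id not in calls]
    if missing:
        raise ValueError(f"contigs without assignment: {missing[:5]}")
    by_class: dict[str, list[float]] = {HOST: [], SYMBIONT: [], OTHER: [], "all": []}
    for contig in contigs:
        pct = 100.0 * gc_content(contig.seq)
        by_class[calls[contig.id]].append(pct)
        by_class["all"].append(pct)
    edges = np.arange(0.0, 101.0, 1.0)
    profiles = []
    for label in (HOST, SYMBIONT, OTHER, "all"):
        values = by_class[label]
        if not values:
            profiles.append(GcProfile(label, (), (), None))
            continue
        counts, _ = np.histogram(values, bins=edges)
        mode = float(edges[int(np.argmax(counts))] + 0.5)
        profiles.append(
            GcProfile(label, tuple(edges), tuple(int(c) for c in counts), mode)
        )
    return profiles
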