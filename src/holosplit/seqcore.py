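"""Sequence substrate: FASTA/FASTQ I/O, read cleaning, GC and assembly
statistics, and six-frame ORF extraction.

This module holds the shared sequence-level machinery used by the
partitioning and redundancy-reduction stages.  Sequences are plain
uppercase nucleotide strings over the IUPAC alphabet; coordinates are
0-based half-open on the forward strand throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_NT = set("ACGTUNRYSWKMBDHV")

__all__ = [
    "SequenceRecord",
    "ContigSet",
    "AssemblyStats",
    "OrfResult",
    "ReadFilterReport",
    "read_fasta",
    "write_fasta",
    "clean_reads",
    "gc_content",
    "reverse_complement",
    "assembly_stats",
    "longest_orf",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (a contig or reference scaffold)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        up = self.seq.upper()
        bad = set(up) - IUPAC_NT
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", up)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)


class ContigSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        self._records[rec.id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._records

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._records[seq_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def subset(self, ids: Iterable[str]) -> "ContigSet":
        return ContigSet(self._records[i] for i in ids)


@dataclass(frozen=True)
class AssemblyStats:
    """Length and composition summary of a sequence set."""

    n_seqs: int
    total_bp: int
    min_len: int
    mean_len: float
    max_len: int
    n50: int
    gc_percent: float


@dataclass(frozen=True)
class OrfResult:
    """An open reading frame located on a nucleotide sequence.

    ``frame`` is +1/+2/+3 on the forward strand or -1/-2/-3 on the
    reverse complement; ``nt_start``/``nt_end`` are always forward-strand
    0-based half-open coordinates of the codon span (stop included in the
    span, excluded from the peptide).
    """

    frame: int
    nt_start: int
    nt_end: int
    peptide: str


@dataclass
class ReadFilterReport:
    """Per-filter bookkeeping for a read-cleaning run."""

    n_in: int = 0
    n_out: int = 0
    n_removed_n_frac: int = 0
    n_removed_short: int = 0
    n_trimmed: int = 0
    n_rejected_malformed: int = 0


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> ContigSet:
    """Read a FASTA file into a :class:`ContigSet`.

    Duplicate ids raise ``ValueError`` naming the offending id; an empty
    file yields an empty set with a warning.
    """
    contigs = ContigSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.add(SequenceRecord(rec.id, str(rec.seq)))
    if len(contigs) == 0:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return contigs


def write_fasta(contigs: Iterable[SequenceRecord], path: str | Path) -> None:
    records = (
        _BioSeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in contigs
    )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Read cleaning

_TRIM_WINDOW = 4


def _trim_3prime(seq: str, quals: list[int], min_q: int) -> tuple[str, list[int]]:
    """Trim the 3' end while the trailing window (<=4 bases) averages below Q."""
    n = len(seq)
    while n > 0:
        w = min(_TRIM_WINDOW, n)
        if sum(quals[n - w : n]) / w >= min_q:
            break
        n -= 1
    return seq[:n], quals[:n]


def clean_reads(
    reads: Iterable,
    min_q: int = 20,
    max_n_frac: float = 0.05,
    min_len: int = 25,
    per_read_quality: bool = False,
) -> tuple[list, ReadFilterReport]:
    """Quality-filter FASTQ reads (phred+33 qualities).

    Reads with an N fraction strictly greater than ``max_n_frac`` are
    removed.  Low-quality 3' bases are trimmed with a sliding mean window
    of 4 below ``min_q`` (or, with ``per_read_quality``, whole reads whose
    mean quality is below ``min_q`` are dropped); reads shorter than
    ``min_len`` after trimming are removed.  ``reads`` is an iterable of
    Biopython ``SeqRecord`` objects carrying ``phred_quality`` annotations.

    Returns the surviving records plus a :class:`ReadFilterReport`.
    """
    report = ReadFilterReport()
    kept: list = []
    for rec in reads:
        report.n_in += 1
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(seq):
            report.n_rejected_malformed += 1
            continue
        if len(seq) and seq.count("N") / len(seq) > max_n_frac:
            report.n_removed_n_frac += 1
            continue
        if per_read_quality:
            if sum(quals) / max(len(quals), 1) < min_q:
                report.n_removed_short += 1
                continue
            new_seq, new_quals = seq, list(quals)
        else:
            new_seq, new_quals = _trim_3prime(seq, list(quals), min_q)
            if len(new_seq) < len(seq):
                report.n_trimmed += 1
        if len(new_seq) < min_len:
            report.n_removed_short += 1
            continue
        out = _BioSeqRecord(Seq(new_seq), id=rec.id, description="")
        out.letter_annotations["phred_quality"] = new_quals
        kept.append(out)
        report.n_out += 1
    return kept, report


# ---------------------------------------------------------------------------
# Composition and assembly statistics


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases; ambiguity codes are excluded
    from numerator and denominator.  Raises on zero unambiguous bases."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T") + seq.count("U")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def assembly_stats(contigs: Iterable[SequenceRecord]) -> AssemblyStats:
    """Summary statistics of a contig set.

    N50 is the length L such that contigs of length >= L accumulate at
    least half of the total bases, found by descending-length accumulation.
    """
    lengths = sorted((len(r) for r in contigs), reverse=True)
    if not lengths:
        raise ValueError("assembly_stats requires a nonempty sequence set")
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    gc = at = 0
    for rec in contigs:
        s = rec.seq
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    gc_percent = 100.0 * gc / (gc + at) if gc + at else float("nan")
    return AssemblyStats(
        n_seqs=len(lengths),
        total_bp=total,
        min_len=lengths[-1],
        mean_len=total / len(lengths),
        max_len=lengths[0],
        n50=n50,
        gc_percent=gc_percent,
    )


# ---------------------------------------------------------------------------
# ORF finding

_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_in_frame(seq: str, offset: int, require_atg: bool) -> Iterator[tuple[int, int]]:
    """Yield (start, end) codon-aligned ORF spans within one reading frame.

    Coordinates are on the given strand; end includes the stop codon when
    one terminates the ORF, else the last complete codon.
    """
    n = len(seq)
    start = None
    for pos in range(offset, n - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if start is not None:
                yield start, pos + 3
                start = None
        elif start is None:
            if not require_atg or codon == "ATG":
                start = pos
    if start is not None:
        last = offset + 3 * ((n - offset) // 3)
        if last > start:
            yield start, last


def longest_orf(
    seq: str, min_aa: int = 30, require_atg: bool = True
) -> OrfResult | None:
    """Longest open reading frame over all six frames (standard code).

    ATG-to-stop by default (stop-to-stop available via ``require_atg=False``);
    the stop codon is excluded from the peptide.  Ties are broken by frame
    order +1, +2, +3, -1, -2, -3, then by leftmost start within the frame.
    Returns ``None`` when no ORF of at least ``min_aa`` residues exists.
    """
    seq = seq.upper()
    n = len(seq)
    best: OrfResult | None = None
    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for offset in range(3):
            frame = strand * (offset + 1)
            for start, end in _orfs_in_frame(s, offset, require_atg):
                pep = str(Seq(s[start:end]).translate())
                if pep.endswith("*"):
                    pep = pep[:-1]
                if len(pep) < min_aa or not pep:
                    continue
                if best is None or len(pep) > len(best.peptide):
                    if strand == 1:
                        nt_start, nt_end = start, end
                    else:
                        nt_start, nt_end = n - end, n - start
                    best = OrfResult(frame, nt_start, nt_end, pep)
    return best
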