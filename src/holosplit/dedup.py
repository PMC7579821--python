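"""Redundancy reduction of the host contig set.

Assemblies of outbred, multi-colony material carry near-duplicate contigs
from haplotypes and inter-individual variation.  The reduction cascade
mirrors the classic greedy-incremental clustering scheme: cluster
nucleotide sequences at 97% identity, translate the surviving
representatives via their longest ORF, then cluster the peptides at 95%
identity.  Representatives of the final clusters form the reference
transcriptome.

Identity between two sequences is defined as the number of matched
positions in the optimal semi-global alignment (the shorter sequence
aligned end-to-end against the best region of the longer; match +1,
mismatch -1, gap -1; among equal-score alignments the one with the most
matches) divided by the length of the shorter sequence — the
shorter-sequence convention used by the reference clustering tool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqcore import ContigSet, SequenceRecord, longest_orf

__all__ = [
    "Cluster",
    "DedupResult",
    "pairwise_identity",
    "greedy_cluster",
    "dedup_pipeline",
]

_MATCH, _MISMATCH, _GAP = 1, -1, -1


@dataclass
class Cluster:
    """A group of mutually redundant sequences and its representative."""

    representative_id: str
    member_ids: list[str]
    level: str  # "nucleotide" | "protein"
    threshold: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _semiglobal_combined(a: str, b: str) -> tuple[int, int]:
    """Optimal semi-global alignment of ``a`` (aligned fully) inside ``b``.

    Returns ``(score, matches)`` maximised lexicographically.  Implemented
    as a single DP over the combined objective score*K + matches with
    K > max matches, so a score improvement always dominates.
    """
    m, n = len(a), len(b)
    K = m + 1
    av, bv = _encode(a), _encode(b)
    gap = _GAP * K
    # diag_add[j] for aligning a[i-1] with b[j-1]
    prev = np.zeros(n + 1, dtype=np.int64)  # row i=0: free leading gap in b
    for i in range(1, m + 1):
        diag = prev[:-1] + np.where(bv == av[i - 1], _MATCH * K + 1, _MISMATCH * K)
        up = prev[1:] + gap
        d = np.maximum(diag, up)
        # left moves form a prefix scan: C[j] = max_{j'<=j} D[j'] + (j-j')*gap
        cur = np.empty(n + 1, dtype=np.int64)
        cur[0] = -i * K  # all of a[:i] gapped against nothing
        t = np.empty(n + 1, dtype=np.int64)
        t[0] = cur[0]
        t[1:] = d - np.arange(1, n + 1) * gap
        cur[1:] = np.maximum.accumulate(t)[1:] + np.arange(1, n + 1) * gap
        prev = cur
    best = int(prev.max())  # free trailing gap in b
    score, matches = divmod(best, K)
    return score, matches


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in the optimal semi-global
    alignment against the longer (see module docstring for the scoring)."""
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    _, matches = _semiglobal_combined(short.upper(), long_.upper())
    return matches / len(short)


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def _prescreen_can_skip(
    kmers_a: Counter, kmers_b: Counter, len_short: int, k: int, threshold: float
) -> bool:
    """Admissible k-mer filter: True only when identity >= threshold is
    provably impossible.

    If the alignment has matches >= t*L over the shorter sequence, at most
    floor((1-t)*L) shorter-sequence positions sit in non-match columns and
    each destroys at most k shared k-mer occurrences; every other k-mer
    occurrence of the shorter lies inside an exactly matched run and so
    also occurs in the longer.  The multiset intersection is therefore at
    least (L-k+1) - k*floor((1-t)*L); below that bound the pair cannot
    reach the threshold.  (Multisets, not sets: repeated k-mers must be
    counted with multiplicity for the positional bound to hold.)
    """
    if len_short < k:
        return False
    lower_bound = (len_short - k + 1) - k * int((1.0 - threshold) * len_short)
    if lower_bound <= 0:
        return False
    shared = sum((kmers_a & kmers_b).values())
    return shared < lower_bound


def greedy_cluster(
    seqs: Iterable[SequenceRecord],
    threshold: float,
    level: str = "nucleotide",
    prescreen_k: int | None = None,
) -> list[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed in descending length (ties by id); each joins
    the first existing cluster whose representative identity is >= the
    threshold, else founds a new cluster.  The representative of every
    cluster is therefore its longest member.  The k-mer prescreen only
    skips pairs provably below the threshold (default k: 8 nt / 3 aa).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if prescreen_k is None:
        prescreen_k = 3 if level == "protein" else 8
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[Counter] = []
    for rec in ordered:
        kmers = _kmer_counts(rec.seq, prescreen_k)
        placed = False
        for cluster, rep, rk in zip(clusters, rep_seqs, rep_kmers):
            if _prescreen_can_skip(kmers, rk, len(rec.seq), prescreen_k, threshold):
                continue
            if pairwise_identity(rec.seq, rep) >= threshold:
                cluster.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], level, threshold))
            rep_seqs.append(rec.seq)
            rep_kmers.append(kmers)
    return clusters


@dataclass
class DedupResult:
    """Outcome of the two-level reduction cascade."""

    reference: ContigSet
    nt_clusters: list[Cluster]
    aa_clusters: list[Cluster]
    representative_of: dict[str, str]  # every input contig id -> surviving id
    n_input: int
    n_after_nt: int
    n_final: int


def dedup_pipeline(
    host_contigs: ContigSet,
    nt_threshold: float = 0.97,
    aa_threshold: float = 0.95,
    min_aa: int = 30,
) -> DedupResult:
    """Two-level reduction: 97% nucleotide clustering, longest-ORF
    translation, then 95% amino-acid clustering of the peptides.

    Nucleotide representatives without an ORF of at least ``min_aa``
    residues bypass the protein level and are retained — dropping them
    would silently shrink the reference set, and coding potential is not
    a stated criterion for membership.
    """
    nt_clusters = greedy_cluster(host_contigs, nt_threshold, "nucleotide")
    nt_rep_of = {m: c.representative_id for c in nt_clusters for m in c.member_ids}

    peptides: list[_ProteinRecord] = []
    no_orf_reps: list[str] = []
    for cluster in nt_clusters:
        rep = host_contigs[cluster.representative_id]
        orf = longest_orf(rep.seq, min_aa=min_aa)
        if orf is None:
            no_orf_reps.append(rep.id)
        else:
            peptides.append(_ProteinRecord(rep.id, orf.peptide))

    aa_clusters = greedy_cluster(peptides, aa_threshold, "protein")
    aa_rep_of = {m: c.representative_id for c in aa_clusters for m in c.member_ids}
    for rep_id in no_orf_reps:
        aa_rep_of[rep_id] = rep_id

    representative_of = {
        contig_id: aa_rep_of[nt_rep_of[contig_id]] for contig_id in host_contigs.ids
    }
    survivors = sorted(set(representative_of.values()))
    return DedupResult(
        reference=host_contigs.subset(survivors),
        nt_clusters=nt_clusters,
        aa_clusters=aa_clusters,
        representative_of=representative_of,
        n_input=len(host_contigs),
        n_after_nt=len(nt_clusters),
        n_final=len(survivors),
    )


class _ProteinRecord:
    """Minimal record for peptide clustering (amino-acid alphabet)."""

    __slots__ = ("id", "seq")

    def __init__(self, seq_id: str, seq: str) -> None:
        self.id = seq_id
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)
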