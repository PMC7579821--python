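"""Synthetic holobiont generator with ground truth.

Emulates the statistical structure the pipeline assumes so that every
stage can be exercised and scored against a known answer:

* host and symbiont reference sequences with distinct base compositions
  (GC centred near 41.5% for the coral host and 50.6% for the
  dinoflagellate symbiont, the separation the GC diagnostic relies on);
* contigs drawn as diverged subsequences of the references, plus
  host+symbiont chimeras (ambiguous contigs), near-duplicate haplotype
  groups, and unrelated "other" sequences;
* negative-binomial counts over a 2 sexes x 4 phases x 3 colonies
  design with planted phase-specific genes whose log2 effects straddle
  the high fold-change thresholds (5 and 8), plus whole-sample outliers
  built by permuting the gene profile (so depth normalization cannot
  absorb them);
* a term map with terms planted to be over-represented in the
  phase-specific sets.

All randomness flows through one integer seed; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import PHASES, CountMatrix
from .seqcore import ContigSet, SequenceRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationOutput",
    "gen_references",
    "gen_contigs",
    "gen_counts",
    "gen_term_map",
    "simulate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    seed: int = 0
    # references
    n_host_refs: int = 4
    n_symbiont_refs: int = 6
    ref_len: int = 100_000
    gc_host: float = 0.415
    gc_symbiont: float = 0.506
    # contigs
    n_host_contigs: int = 250
    n_symbiont_contigs: int = 150
    n_other_contigs: int = 50
    n_ambiguous: int = 50
    contig_len_range: tuple[int, int] = (300, 1500)
    divergence: float = 0.02
    n_dup_groups: int = 10
    dup_group_size_range: tuple[int, int] = (2, 5)
    dup_identity: float = 0.985
    # counts
    n_genes: int = 2000
    n_colonies: int = 3
    baseline_log_mean: float = np.log(30.0)
    baseline_log_sd: float = 1.3
    lib_factor_range: tuple[float, float] = (0.6, 1.4)
    nb_dispersion: float = 0.1
    n_planted_per_sex: int = 40
    planted_effect_female: float = 6.0
    planted_effect_male: float = 9.0
    planted_phase: str = "mature"
    n_moderate_per_sex: int = 20
    moderate_effect: float = 3.0
    moderate_phase: str = "late"
    min_planted_baseline: float = 5.0
    n_outliers_per_sex: int = 1
    outlier_phase: str = "middle"
    # term map
    n_terms: int = 100
    term_size_range: tuple[int, int] = (10, 50)
    n_planted_terms_per_sex: int = 2
    planted_term_size: int = 30
    planted_term_fraction: float = 0.5

    def __post_init__(self) -> None:
        for rate in (self.gc_host, self.gc_symbiont, self.divergence):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_colonies < 2:
            raise ValueError("need >= 2 replicates (colonies) per phase")
        if self.planted_phase not in PHASES or self.moderate_phase not in PHASES:
            raise ValueError("planted phases must be one of the 4 gametogenic phases")


@dataclass
class SyntheticTruth:
    """Ground truth for everything the generator planted."""

    contig_origin: dict[str, str] = field(default_factory=dict)
    # origin in {host, symbiont, other, ambiguous}
    duplicate_groups: list[list[str]] = field(default_factory=list)
    planted_genes: dict[str, dict[str, tuple[str, float]]] = field(
        default_factory=dict
    )  # sex -> gene -> (phase, log2 effect)
    outlier_samples: list[str] = field(default_factory=list)
    planted_terms: dict[str, list[str]] = field(default_factory=dict)  # sex -> terms

    def high_fc_truth(self, sex: str, threshold: float) -> set[str]:
        """Planted genes for a sex whose log2 effect exceeds a threshold."""
        return {
            g
            for g, (_, eff) in self.planted_genes.get(sex, {}).items()
            if eff > threshold
        }


@dataclass
class SimulationOutput:
    """Everything one simulated study provides to the pipeline."""

    host_refs: ContigSet
    symbiont_refs: ContigSet
    contigs: ContigSet
    counts: CountMatrix
    term_map: "object"  # TermMap; typed loosely to avoid a circular import
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Sequences


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point substitutions at the given per-base rate (always to a
    different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(arr.size) < rate)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _mutate_exact(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Exactly ``n_subs`` substitutions at distinct positions, so the
    realized identity to the original equals the configured identity."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n_subs = min(n_subs, arr.size)
    for i in rng.choice(arr.size, size=n_subs, replace=False):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def gen_references(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ContigSet, ContigSet]:
    """Host and symbiont reference sets with class-specific GC content."""
    rng = rng or np.random.default_rng(config.seed)
    host = ContigSet(
        SequenceRecord(f"hostref_{i}", _random_seq(rng, config.ref_len, config.gc_host))
        for i in range(config.n_host_refs)
    )
    sym = ContigSet(
        SequenceRecord(
            f"symref_{i}", _random_seq(rng, config.ref_len, config.gc_symbiont)
        )
        for i in range(config.n_symbiont_refs)
    )
    return host, sym


class _FragmentAllocator:
    """Hands out non-overlapping reference fragments.

    Origin regions of distinct contigs are disjoint, so two contigs are
    near-identical only when the generator planted them as duplicates —
    the property the duplicate-recovery scoring relies on.
    """

    def __init__(self, refs: ContigSet) -> None:
        self._refs = list(refs)
        self._cursor = [0] * len(self._refs)

    def take(self, length: int) -> str:
        for i, ref in enumerate(self._refs):
            if len(ref) - self._cursor[i] >= length:
                start = self._cursor[i]
                self._cursor[i] = start + length
                return ref.seq[start : start + length]
        raise ValueError(
            "reference capacity exhausted; increase ref_len or n refs"
        )


def gen_contigs(
    host_refs: ContigSet,
    symbiont_refs: ContigSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ContigSet, SyntheticTruth]:
    """Contigs as diverged reference subsequences plus chimeras,
    duplicate groups and unrelated sequences; truth records all origins.

    Chimeras are half-host/half-symbiont concatenations recorded with
    origin "ambiguous" — neither class call is wrong for them, so
    accuracy scoring excludes them.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    truth = SyntheticTruth()
    contigs = ContigSet()
    lo, hi = config.contig_len_range
    host_alloc = _FragmentAllocator(host_refs)
    sym_alloc = _FragmentAllocator(symbiont_refs)

    def contig_len() -> int:
        return int(rng.integers(lo, hi + 1))

    n_group_members = 0
    group_sizes = []
    for _ in range(config.n_dup_groups):
        size = int(rng.integers(*config.dup_group_size_range, endpoint=True))
        group_sizes.append(size)
        n_group_members += size
    n_plain_host = max(config.n_host_contigs - n_group_members, 0)

    idx = 0
    for _ in range(n_plain_host):
        seq = _mutate(rng, host_alloc.take(contig_len()), config.divergence)
        cid = f"contig_h{idx}"
        idx += 1
        contigs.add(SequenceRecord(cid, seq))
        truth.contig_origin[cid] = "host"

    mut_rate = 1.0 - config.dup_identity
    for g, size in enumerate(group_sizes):
        founder_seq = _mutate(
            rng, host_alloc.take(contig_len()), config.divergence
        )
        group_ids = []
        for m in range(size):
            cid = f"contig_d{g}_{m}"
            # copies keep the founder's length minus a short 3' truncation so
            # the founder stays the longest member
            if m == 0:
                seq = founder_seq
            else:
                cut = int(rng.integers(10, 50))
                trimmed = founder_seq[: len(founder_seq) - cut]
                seq = _mutate_exact(
                    rng, trimmed, round(mut_rate * len(trimmed))
                )
            contigs.add(SequenceRecord(cid, seq))
            truth.contig_origin[cid] = "host"
            group_ids.append(cid)
        truth.duplicate_groups.append(group_ids)

    for i in range(config.n_symbiont_contigs):
        seq = _mutate(
            rng, sym_alloc.take(contig_len()), config.divergence
        )
        cid = f"contig_s{i}"
        contigs.add(SequenceRecord(cid, seq))
        truth.contig_origin[cid] = "symbiont"

    for i in range(config.n_other_contigs):
        cid = f"contig_o{i}"
        contigs.add(SequenceRecord(cid, _random_seq(rng, contig_len(), 0.45)))
        truth.contig_origin[cid] = "other"

    # chimeras are verbatim half/half concatenations: they model assembly
    # joints, and both database signals should be genuine
    for i in range(config.n_ambiguous):
        half = contig_len() // 2
        seq = host_alloc.take(half) + sym_alloc.take(half)
        cid = f"contig_a{i}"
        contigs.add(SequenceRecord(cid, seq))
        truth.contig_origin[cid] = "ambiguous"

    return contigs, truth


# ---------------------------------------------------------------------------
# Counts


def _sample_ids(config: SimulationConfig) -> list[tuple[str, str, str, int]]:
    out = []
    for sex in ("F", "M"):
        for phase in PHASES:
            for colony in range(1, config.n_colonies + 1):
                out.append((f"{sex}_{phase}_c{colony}", sex, phase, colony))
    return out


def gen_counts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial counts with planted phase effects and outliers.

    Counts follow NB(mean mu, variance mu + phi*mu^2) with log-normal
    per-gene baselines and uniform library-size factors.  Planted genes
    (chosen among genes with baseline mean >= ``min_planted_baseline`` so
    the fold change is identifiable above the pseudo-count) have their
    mean multiplied by 2^effect in the planted phase of one sex.  Outlier
    samples are drawn from a permuted gene profile.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    truth = truth or SyntheticTruth()
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    eligible = np.flatnonzero(baseline >= config.min_planted_baseline)
    need = 2 * (config.n_planted_per_sex + config.n_moderate_per_sex)
    if eligible.size < need:
        raise ValueError("not enough well-expressed genes to plant effects")
    chosen = rng.choice(eligible, size=need, replace=False)
    cursor = 0
    plan: dict[str, dict[int, tuple[str, float]]] = {"F": {}, "M": {}}
    for sex, strong_eff in (
        ("F", config.planted_effect_female),
        ("M", config.planted_effect_male),
    ):
        for _ in range(config.n_planted_per_sex):
            plan[sex][int(chosen[cursor])] = (config.planted_phase, strong_eff)
            cursor += 1
        for _ in range(config.n_moderate_per_sex):
            plan[sex][int(chosen[cursor])] = (config.moderate_phase, config.moderate_effect)
            cursor += 1
    truth.planted_genes = {
        sex: {genes[g]: spec for g, spec in table.items()}
        for sex, table in plan.items()
    }

    samples = _sample_ids(config)
    outliers: list[str] = []
    for sex in ("F", "M"):
        candidates = [
            s for s, sx, ph, _ in samples if sx == sex and ph == config.outlier_phase
        ]
        outliers.extend(candidates[: config.n_outliers_per_sex])
    truth.outlier_samples = outliers

    n_disp = 1.0 / config.nb_dispersion
    columns = {}
    meta_rows = []
    for sample, sex, phase, colony in samples:
        lib_factor = rng.uniform(*config.lib_factor_range)
        mu = baseline.copy()
        for g, (ph, eff) in plan[sex].items():
            if ph == phase:
                mu[g] *= 2.0**eff
        if sample in outliers:
            mu = rng.permutation(baseline)
        mu = mu * lib_factor
        p = n_disp / (n_disp + mu)
        columns[sample] = rng.negative_binomial(n_disp, p)
        meta_rows.append({"sample": sample, "sex": sex, "phase": phase, "colony": colony})

    counts = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# Term map


def gen_term_map(
    config: SimulationConfig,
    truth: SyntheticTruth,
    genes: Sequence[str],
    rng: np.random.Generator | None = None,
):
    """Random terms plus terms planted to be enriched in each sex's
    strongly planted gene set (a configured fraction of the term's genes
    is drawn from that set)."""
    from .enrichment import TermMap

    rng = rng or np.random.default_rng(config.seed + 3)
    genes = list(genes)
    genes_by_term: dict[str, set[str]] = {}
    categories = ("BP", "CC", "MF")
    for i in range(config.n_terms):
        size = int(rng.integers(*config.term_size_range, endpoint=True))
        members = rng.choice(len(genes), size=size, replace=False)
        genes_by_term[f"T{i:04d}"] = {genes[j] for j in members}

    truth.planted_terms = {}
    for sex in ("F", "M"):
        # plant into the strongly upregulated genes only, so the term is
        # enriched in the high fold-change foreground
        planted_pool = sorted(truth.high_fc_truth(sex, 4.0))
        terms = []
        for j in range(config.n_planted_terms_per_sex):
            tid = f"T_planted_{sex}{j}"
            n_from_set = int(config.planted_term_size * config.planted_term_fraction)
            n_from_set = min(n_from_set, len(planted_pool))
            from_set = rng.choice(len(planted_pool), size=n_from_set, replace=False)
            rest = rng.choice(
                len(genes), size=config.planted_term_size - n_from_set, replace=False
            )
            genes_by_term[tid] = {planted_pool[i] for i in from_set} | {
                genes[i] for i in rest
            }
            terms.append(tid)
        truth.planted_terms[sex] = terms

    names = {t: f"synthetic term {t}" for t in genes_by_term}
    cats = {t: categories[i % 3] for i, t in enumerate(genes_by_term)}
    return TermMap(genes_by_term, names, cats), truth


# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig | None = None) -> SimulationOutput:
    """Generate one complete synthetic study (sequences, counts, terms)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    host_refs, sym_refs = gen_references(config, rng)
    contigs, truth = gen_contigs(host_refs, sym_refs, config, rng)
    counts, truth = gen_counts(config, rng, truth)
    term_map, truth = gen_term_map(config, truth, list(counts.counts.index), rng)
    return SimulationOutput(host_refs, sym_refs, contigs, counts, term_map, truth, config)
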