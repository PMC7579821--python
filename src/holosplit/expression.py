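"""Count-matrix analysis of the gonadal gametogenic series.

The design is 2 sexes x 4 ordered gametogenic phases (early, middle,
late, mature) x colonies, one library per gonad sample.  The stage
implements:

* TMM (trimmed mean of M-values) between-sample normalization and CPM;
* sample-outlier detection by average-linkage hierarchical clustering on
  1 - Pearson correlation of log2(CPM+1), with an explicit merge-height
  rule replacing a by-eye dendrogram call;
* per-gene one-way fixed-effects ANOVA on log2(CPM+1) across phases,
  Benjamini-Hochberg adjusted within each sex;
* phase-specific upregulated sets and the high fold-change filters
  (log2 > 5 for ovaries, log2 > 8 for testes, pseudo-CPM 1);
* row Z-scoring for heatmap export and cross-sex overlap accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "DETable",
    "OutlierReport",
    "PHASES",
    "tmm_factors",
    "cpm",
    "detect_outliers",
    "de_test",
    "phase_specific_sets",
    "overlap_sets",
    "zscore_rows",
    "benjamini_hochberg",
]

PHASES = ("early", "middle", "late", "mature")


@dataclass
class CountMatrix:
    """Integer gene x sample counts with per-sample metadata.

    ``counts`` is a genes-by-samples DataFrame; ``meta`` is indexed by
    sample id with columns ``sex`` (F/M), ``phase`` (ordered categorical
    over :data:`PHASES`) and ``colony``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.meta = self.meta.loc[list(self.counts.columns)]
        unknown = set(self.meta["phase"]) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)].copy(), self.meta.copy())

    def split_by_sex(self) -> dict[str, "CountMatrix"]:
        out = {}
        for sex in sorted(self.meta["sex"].unique()):
            ids = self.meta.index[self.meta["sex"] == sex]
            out[sex] = self.subset_samples(list(ids))
        return out


@dataclass
class NormalizedMatrix:
    """TMM factors and CPM values for one count matrix."""

    cpm: pd.DataFrame
    tmm_factor: pd.Series
    meta: pd.DataFrame

    def log_cpm(self, pseudo: float = 1.0) -> pd.DataFrame:
        return np.log2(self.cpm + pseudo)


@dataclass
class DETable:
    """Per-gene across-phase test results for one sex.

    ``phase_means`` holds mean CPM per phase; ``log2fc`` the pairwise
    log2 fold-change matrix between phase means (pseudo-CPM 1).
    """

    table: pd.DataFrame  # columns: F, p, q, is_de, specific_phase
    phase_means: pd.DataFrame  # genes x phases (mean CPM)
    alpha: float

    @property
    def de_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_de"]])


@dataclass
class OutlierReport:
    """Flagged samples and the linkage tree they were read from."""

    linkage: np.ndarray
    sample_ids: list[str]
    merge_heights: pd.Series  # first-merge height per sample
    threshold: float
    flagged: list[str]


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile_ratio(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample.

    For each sample against a reference, gene-wise log2 ratios (M) and
    average log2 abundances (A) are computed over genes positive in both
    libraries after library-size adjustment, doubly trimmed (the most
    extreme ``m_trim`` fraction of M on each side and ``a_trim`` of A),
    and the factor is 2 to the inverse-variance-weighted mean of the
    surviving M values.  Factors are rescaled to geometric mean 1.  The
    default reference is the sample whose upper-quartile count ratio is
    closest to the mean of those ratios.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    lib = mat.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with all-zero counts: {list(counts.columns[zero])}"
        )
    if ref_sample is None:
        f75 = _quantile_ratio(mat, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(counts.columns).index(ref_sample)
    ref = mat[:, ref_idx]
    ref_lib = lib[ref_idx]

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        obs = mat[:, j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            continue
        o, r = obs[keep], ref[keep]
        m = np.log2((o / lib[j]) / (r / ref_lib))
        a = 0.5 * np.log2((o / lib[j]) * (r / ref_lib))
        # asymptotic (delta-method) variance of M
        w = (lib[j] - o) / (lib[j] * o) + (ref_lib - r) / (ref_lib * r)
        n = m.size
        lo_m = np.floor(n * m_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * a_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep2.any() and w[keep2].sum() > 0:
            f = np.nansum(m[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
            if np.isfinite(f):
                factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    meta: pd.DataFrame | None = None,
    pseudo: float = 0.0,
) -> NormalizedMatrix:
    """Counts per million over TMM-effective library sizes:
    cpm[g, s] = 1e6 * (count + pseudo) / (library_size * factor)."""
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    lib = counts.sum(axis=0)
    eff = lib * factors.loc[counts.columns]
    values = 1e6 * (counts + pseudo) / eff
    if meta is None:
        meta = pd.DataFrame(index=counts.columns)
    return NormalizedMatrix(cpm=values, tmm_factor=factors, meta=meta)


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """TMM factors + CPM in one step."""
    factors = tmm_factors(cm.counts)
    return cpm(cm.counts, factors, cm.meta)


# ---------------------------------------------------------------------------
# Outlier detection


def detect_outliers(
    normalized: NormalizedMatrix, n_mads: float = 3.0
) -> OutlierReport:
    """Flag samples whose first merge into the average-linkage tree
    (distance 1 - Pearson r of log2(CPM+1)) happens above
    median + ``n_mads`` x MAD of all first-merge heights.

    The MAD is scaled by 1.4826 for normal consistency.  This replaces a
    visual dendrogram call with a reproducible rule.
    """
    samples = list(normalized.cpm.columns)
    n = len(samples)
    if n < 4:
        raise ValueError("outlier detection requires at least 4 samples")
    log_expr = normalized.log_cpm().to_numpy()
    corr = np.corrcoef(log_expr.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")

    # a leaf's merge height is the height of the first linkage step whose
    # cluster contains it
    first_merge = np.full(n, np.nan)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, (a, b, height, _) in enumerate(Z):
        merged = members[int(a)] + members[int(b)]
        members[n + step] = merged
        for leaf in merged:
            if np.isnan(first_merge[leaf]):
                first_merge[leaf] = height
    med = float(np.median(first_merge))
    mad = 1.4826 * float(np.median(np.abs(first_merge - med)))
    threshold = med + n_mads * mad
    heights = pd.Series(first_merge, index=samples, name="merge_height")
    flagged = [s for s, h in heights.items() if h > threshold]
    return OutlierReport(Z, samples, heights, threshold, flagged)


def remove_outliers(cm: CountMatrix, report: OutlierReport) -> CountMatrix:
    """Drop flagged samples, most isolated first, but never reduce any
    phase below 2 replicates (the across-phase test would be undefined)."""
    flagged = sorted(
        report.flagged, key=lambda s: -float(report.merge_heights[s])
    )
    kept = list(cm.counts.columns)
    for sample in flagged:
        phase = cm.meta.loc[sample, "phase"]
        n_phase = sum(
            1 for s in kept if s != sample and cm.meta.loc[s, "phase"] == phase
        )
        if n_phase >= 2:
            kept.remove(sample)
    return cm.subset_samples(kept)


# ---------------------------------------------------------------------------
# Differential expression


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(pvals, method="fdr_bh")[1]


def de_test(
    normalized: NormalizedMatrix, alpha: float = 0.05, pseudo_fc: float = 1.0
) -> DETable:
    """Per-gene one-way ANOVA on log2(CPM+1) across gametogenic phases.

    P-values are BH-adjusted over all tested genes (one sex per call);
    genes with zero variance across all samples get p = 1.  Each phase
    must retain at least 2 replicates (after any outlier removal).
    """
    phases_present = [p for p in PHASES if (normalized.meta["phase"] == p).any()]
    if len(phases_present) < 2:
        raise ValueError("need at least 2 phases")
    groups_idx = []
    for phase in phases_present:
        idx = np.flatnonzero((normalized.meta["phase"] == phase).to_numpy())
        if idx.size < 2:
            raise ValueError(f"phase {phase!r} has fewer than 2 replicates")
        groups_idx.append(idx)

    log_expr = normalized.log_cpm().to_numpy()
    groups = [log_expr[:, idx] for idx in groups_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = stats.f_oneway(*groups, axis=1)
    flat = np.concatenate(groups, axis=1)
    zero_var = flat.std(axis=1) == 0
    F = np.where(zero_var, 0.0, F)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    q = benjamini_hochberg(p)

    genes = normalized.cpm.index
    phase_means = pd.DataFrame(
        {ph: normalized.cpm.iloc[:, idx].mean(axis=1) for ph, idx in zip(phases_present, groups_idx)},
        index=genes,
    )
    table = pd.DataFrame(
        {"F": F, "p": p, "q": q, "is_de": q < alpha, "specific_phase": None},
        index=genes,
    )
    # phase with strictly maximal mean, DE genes only
    means = phase_means.to_numpy()
    order = np.argsort(means, axis=1)
    top = order[:, -1]
    strict = means[np.arange(len(genes)), top] > means[
        np.arange(len(genes)), order[:, -2]
    ]
    specific = np.where(
        table["is_de"].to_numpy() & strict,
        np.array(phases_present, dtype=object)[top],
        None,
    )
    table["specific_phase"] = specific
    return DETable(table=table, phase_means=phase_means, alpha=alpha)


def phase_specific_sets(
    de: DETable, high_fc_threshold: float, pseudo: float = 1.0
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-phase specific gene sets and their high fold-change subsets.

    A gene is phase-specific when it is differentially expressed and its
    mean CPM in that phase strictly exceeds every other phase.  It passes
    the high-FC filter when additionally
    min over other phases q of log2((mean_p + pseudo)/(mean_q + pseudo))
    exceeds the threshold.
    """
    specific: dict[str, set[str]] = {p: set() for p in de.phase_means.columns}
    high_fc: dict[str, set[str]] = {p: set() for p in de.phase_means.columns}
    means = de.phase_means
    for gene, phase in de.table["specific_phase"].items():
        if phase is None:
            continue
        specific[phase].add(gene)
        row = means.loc[gene]
        others = [p for p in means.columns if p != phase]
        min_lfc = min(
            np.log2((row[phase] + pseudo) / (row[q] + pseudo)) for q in others
        )
        if min_lfc > high_fc_threshold:
            high_fc[phase].add(gene)
    return specific, high_fc


def overlap_sets(
    de_female: DETable, de_male: DETable
) -> dict[str, int]:
    """Cross-sex overlap of differentially expressed gene sets."""
    if set(de_female.table.index) != set(de_male.table.index):
        raise ValueError("DE tables are on different gene universes")
    f, m = de_female.de_genes, de_male.de_genes
    return {
        "female_only": len(f - m),
        "male_only": len(m - f),
        "shared": len(f & m),
        "female_total": len(f),
        "male_total": len(m),
    }


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row Z-scores ((x - row mean) / population sd); constant rows -> 0."""
    if matrix.shape[1] < 2:
        raise ValueError("row Z-scores need at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.repeat(sd == 0, values.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
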