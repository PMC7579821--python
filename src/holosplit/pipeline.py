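"""End-to-end orchestration of the holobiont analysis.

Chains the stages in their natural (linear) order on a simulated or
user-supplied dataset: contig partitioning -> redundancy reduction ->
normalization -> outlier removal -> across-phase differential expression
-> phase-specific sets -> term enrichment, and writes a machine-readable
report whose every number is recomputed from stage outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import numpy as np

from . import dedup as _dedup
from . import enrichment as _enrich
from . import expression as _expr
from . import partition as _part
from .seqcore import assembly_stats
from .synthetic import SimulationConfig, SimulationOutput, simulate

__all__ = ["PipelineConfig", "run", "run_expression", "write_report"]

_SEX_LABEL = {"F": "ovary", "M": "testis"}


@dataclass
class PipelineConfig:
    """Every stage parameter with the study's stated defaults."""

    seed: int = 0
    evalue: float = 1e-3
    annot_evalue: float = 1e-5
    kmer: int = 21
    min_containment: float = 0.2
    nt_identity: float = 0.97
    aa_identity: float = 0.95
    min_orf_aa: int = 30
    alpha: float = 0.05
    lfc_ovary: float = 5.0
    lfc_testis: float = 8.0
    min_fold: float = 4.0
    enrich_alpha: float = 0.05
    drop_outliers: bool = True

    def __post_init__(self) -> None:
        for name in ("nt_identity", "aa_identity"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.evalue < 0 or self.annot_evalue < 0:
            raise ValueError("e-value cutoffs must be nonnegative")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stats_dict(contigs) -> dict[str, Any]:
    s = assembly_stats(contigs)
    return {
        "n_seqs": s.n_seqs,
        "total_bp": s.total_bp,
        "min_len": s.min_len,
        "mean_len": round(s.mean_len, 1),
        "max_len": s.max_len,
        "n50": s.n50,
        "gc_percent": round(s.gc_percent, 1),
    }


def run_expression(
    counts, config: PipelineConfig
) -> dict[str, Any]:
    """Normalization, outlier removal, DE, phase sets and overlaps for
    one count matrix covering both sexes.  Returns per-sex results plus
    the flagged outliers."""
    lfc = {"F": config.lfc_ovary, "M": config.lfc_testis}
    results: dict[str, Any] = {"per_sex": {}}
    outliers: list[str] = []
    de_tables = {}
    for sex, cm in counts.split_by_sex().items():
        norm = _expr.normalize(cm)
        report = _expr.detect_outliers(norm)
        if config.drop_outliers and report.flagged:
            cm = _expr.remove_outliers(cm, report)
            norm = _expr.normalize(cm)
        outliers.extend(report.flagged)
        de = _expr.de_test(norm, alpha=config.alpha)
        specific, high_fc = _expr.phase_specific_sets(de, lfc[sex])
        de_tables[sex] = de
        results["per_sex"][sex] = {
            "label": _SEX_LABEL.get(sex, sex),
            "n_samples_used": len(cm.counts.columns),
            "outliers": report.flagged,
            "n_de": int(de.table["is_de"].sum()),
            "phase_specific_sizes": {p: len(g) for p, g in specific.items()},
            "high_fc_sizes": {p: len(g) for p, g in high_fc.items()},
            "lfc_threshold": lfc[sex],
            "_de_table": de,
            "_specific": specific,
            "_high_fc": high_fc,
        }
    if len(de_tables) == 2:
        results["overlap"] = _expr.overlap_sets(de_tables["F"], de_tables["M"])
    results["outlier_samples"] = outliers
    return results


def run(
    config: PipelineConfig | None = None,
    sim: SimulationOutput | None = None,
    sim_config: SimulationConfig | None = None,
) -> dict[str, Any]:
    """Run the full pipeline and return the report dictionary.

    With no ``sim`` provided, a synthetic study is generated from
    ``sim_config`` (seeded from the pipeline seed by default).
    """
    config = config or PipelineConfig()
    if sim is None:
        sim = simulate(sim_config or SimulationConfig(seed=config.seed))

    # --- partition
    hits = _part.kmer_screen(
        sim.contigs,
        sim.host_refs,
        sim.symbiont_refs,
        k=config.kmer,
        min_containment=config.min_containment,
    )
    host_hits = [h for h in hits if h.subject_db == _part.HOST]
    sym_hits = [h for h in hits if h.subject_db == _part.SYMBIONT]
    assignments, ledger = _part.assign_contigs(sim.contigs, host_hits, sym_hits)
    profiles = _part.gc_profile(sim.contigs, assignments)
    call_of = {a.contig_id: a.call for a in assignments}
    host_ids = [c.id for c in sim.contigs if call_of[c.id] == _part.HOST]

    # --- dedup
    dedup_result = _dedup.dedup_pipeline(
        sim.contigs.subset(host_ids),
        nt_threshold=config.nt_identity,
        aa_threshold=config.aa_identity,
        min_aa=config.min_orf_aa,
    )

    # --- expression
    expr_results = run_expression(sim.counts, config)

    # --- enrichment on the planted-phase high-FC sets
    universe = sim.term_map.annotated_genes & set(sim.counts.counts.index)
    enrichment: dict[str, Any] = {}
    for sex, res in expr_results["per_sex"].items():
        foreground = res["_high_fc"].get(sim.config.planted_phase, set()) & universe
        if not foreground:
            enrichment[sex] = {"n_tested": 0, "passing_terms": []}
            continue
        records = _enrich.enrich(
            foreground,
            sim.term_map,
            universe,
            min_fold=config.min_fold,
            alpha=config.enrich_alpha,
        )
        enrichment[sex] = {
            "n_foreground": len(foreground),
            "n_tested": len(records),
            "passing_terms": [r.term for r in records if r.passes],
        }

    per_class_stats = {"all": _stats_dict(sim.contigs)}
    for label in (_part.HOST, _part.SYMBIONT):
        ids = [c.id for c in sim.contigs if call_of[c.id] == label]
        if ids:
            per_class_stats[label] = _stats_dict(sim.contigs.subset(ids))
    per_class_stats["reference"] = _stats_dict(dedup_result.reference)

    report = {
        "config": asdict(config),
        "ledger": asdict(ledger),
        "gc_modes": {p.label: p.mode_percent for p in profiles},
        "assembly_stats": per_class_stats,
        "dedup": {
            "n_input": dedup_result.n_input,
            "n_after_nt": dedup_result.n_after_nt,
            "n_final": dedup_result.n_final,
        },
        "expression": {
            "outlier_samples": expr_results["outlier_samples"],
            "overlap": expr_results.get("overlap"),
            "per_sex": {
                sex: {k: v for k, v in res.items() if not k.startswith("_")}
                for sex, res in expr_results["per_sex"].items()
            },
        },
        "enrichment": enrichment,
    }
    report["_internals"] = {
        "assignments": assignments,
        "dedup": dedup_result,
        "expression": expr_results,
        "sim": sim,
    }
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Serialize the report (internal objects stripped) as JSON."""
    public = {k: v for k, v in report.items() if not k.startswith("_")}
    Path(path).write_text(json.dumps(public, indent=2, sort_keys=True) + "\n")
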