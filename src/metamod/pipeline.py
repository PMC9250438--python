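"""End-to-end orchestration: tables in, per-cancer-type enrichment out."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import cohort_io
from .cohort_io import (
    EXCLUDED,
    FilterConfig,
    MutationRecord,
    SampleRecord,
    build_mutation_matrix,
)
from .enrichment import EnrichmentConfig, EnrichmentResult, results_to_frame, run_enrichment

log = logging.getLogger(__name__)


def read_driver_list(path) -> dict[str, list[str]]:
    """Two-column TSV (cancer_type, gene) → {cancer_type: [genes]}."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["cancer_type", "gene"], dtype=str)
    # tolerate a header row
    if not frame.empty and frame.iloc[0, 0].strip().lower() in ("cancer_type", "cancertype"):
        frame = frame.iloc[1:]
    drivers: dict[str, list[str]] = {}
    for ct, gene in zip(frame["cancer_type"], frame["gene"]):
        if not ct or not gene or str(gene).strip() == "":
            continue
        drivers.setdefault(str(ct).strip(), []).append(str(gene).strip().upper())
    return {ct: sorted(set(genes)) for ct, genes in drivers.items()}


@dataclass
class RunLog:
    """Per-cancer-type bookkeeping emitted alongside enrichment results."""

    cancer_type: str
    n_metastatic: int = 0
    n_early: int = 0
    n_excluded_by_reason: dict[str, int] = field(default_factory=dict)
    n_drivers: int = 0
    n_modules: int = 0
    runtime_seconds: float = 0.0


def enrich_tables(
    mutations: Sequence[MutationRecord],
    samples: Sequence[SampleRecord],
    drivers: Mapping[str, Sequence[str]],
    filters: FilterConfig | None = None,
    config: EnrichmentConfig | None = None,
) -> tuple[dict[str, list[EnrichmentResult]], list[RunLog]]:
    """Run the full enrichment pipeline over every cancer type with drivers.

    Raises if the mutation and clinical tables share no samples at all.
    """
    config = config or EnrichmentConfig()
    if mutations and samples:
        if not ({m.sample_id for m in mutations} & {s.sample_id for s in samples}):
            raise ValueError("no overlapping samples between mutation and clinical tables")
    assignments = cohort_io.assign_cohorts(samples, filters)
    by_id = {a.sample_id: a for a in assignments}
    results: dict[str, list[EnrichmentResult]] = {}
    logs: list[RunLog] = []
    cancer_types = sorted({s.cancer_type for s in samples})
    for ct in cancer_types:
        t0 = time.perf_counter()
        ct_samples = [s for s in samples if s.cancer_type == ct]
        run_log = RunLog(cancer_type=ct)
        for s in ct_samples:
            a = by_id[s.sample_id]
            if a.label == EXCLUDED:
                run_log.n_excluded_by_reason[a.exclusion_reason] = (
                    run_log.n_excluded_by_reason.get(a.exclusion_reason, 0) + 1
                )
        matrix = build_mutation_matrix(mutations, samples, assignments, ct)
        run_log.n_metastatic = matrix.n_metastatic
        run_log.n_early = matrix.n_early
        driver_list = drivers.get(ct, [])
        if not driver_list:
            log.warning("no driver list for cancer type %s; skipping", ct)
            logs.append(run_log)
            continue
        if matrix.n_metastatic == 0 or matrix.n_early == 0:
            log.warning("cancer type %s lacks one of the cohorts; skipping", ct)
            logs.append(run_log)
            continue
        ct_results = run_enrichment(matrix, driver_list, config)
        results[ct] = ct_results
        run_log.n_modules = ct_results[0].n_tests if ct_results else 0
        run_log.n_drivers = len(
            {g for r in ct_results for g in r.module.genes}
        ) if ct_results else 0
        run_log.runtime_seconds = time.perf_counter() - t0
        log.info(
            "%s: %d metastatic / %d early, %d drivers, %d modules (Bonferroni m), %.2fs",
            ct, run_log.n_metastatic, run_log.n_early, run_log.n_drivers,
            run_log.n_modules, run_log.runtime_seconds,
        )
        logs.append(run_log)
    return results, logs


def all_results_frame(results: Mapping[str, Sequence[EnrichmentResult]]) -> pd.DataFrame:
    frames = [results_to_frame(rs) for rs in results.values() if rs]
    if not frames:
        return results_to_frame([])
    return pd.concat(frames, ignore_index=True)
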