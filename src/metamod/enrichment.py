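"""Gene-module mutation enrichment between metastatic and early-primary cohorts.

A *gene module* is a set of driver genes all mutated (nonsilently) in the
same sample; a single driver gene is the size-1 special case.  For each
module the analysis builds the 2×2 table

    =============  ==========  =============
                   carries M   does not
    metastatic     a           b
    early primary  c           d
    =============  ==========  =============

and asks whether the carrier frequency differs between the cohorts with a
two-sided Fisher exact test.  The two-sided P is the minimum-likelihood
definition: the sum of hypergeometric probabilities of every table with
the same margins that is no more probable than the observed one,

    P = Σ_{k : Pr(k) ≤ Pr(a)·(1+ε)} C(K,k)·C(N−K,n−k)/C(N,n),

with N = a+b+c+d, K = a+c, n = a+b and a small relative tie tolerance
ε = 1e-7 (the convention of standard statistical software).  Probabilities
are accumulated in log space so deep tails remain accurate.  P values are
adjusted per cancer type with the Bonferroni correction q = min(1, P·m),
where m is the number of modules tested in that cancer type.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cohort_io import EARLY_PRIMARY, METASTATIC, MutationMatrix

log = logging.getLogger(__name__)

#: relative tolerance when comparing hypergeometric probabilities for the
#: minimum-likelihood two-sided sum (treats near-equal tables as ties)
TIE_RELATIVE_TOLERANCE = 1e-7


@dataclass(frozen=True)
class GeneModule:
    """A canonical (sorted, duplicate-free) set of driver gene symbols."""

    genes: tuple[str, ...]

    def __init__(self, genes: Iterable[str]):
        canon = tuple(sorted(set(genes)))
        if not canon or any(not g for g in canon):
            raise ValueError("a gene module needs at least one nonempty gene symbol")
        object.__setattr__(self, "genes", canon)

    @property
    def name(self) -> str:
        return "-".join(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b metastatic with/without, c/d early-primary with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_metastatic(self) -> int:
        return self.a + self.b

    @property
    def n_early(self) -> int:
        return self.c + self.d

    @property
    def met_freq(self) -> float:
        return self.a / self.n_metastatic if self.n_metastatic else float("nan")

    @property
    def early_freq(self) -> float:
        return self.c / self.n_early if self.n_early else float("nan")


def haldane_odds_ratio(table: ContingencyTable) -> float:
    """Cross-product odds ratio, with 0.5 added to every cell if any is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _log_choose(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def fisher_exact_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact P and Haldane-corrected odds ratio.

    Degenerate margins (an empty row or an all-zero carrier column) have a
    single admissible table, so P = 1 by convention.  The odds ratio uses
    the Haldane 0.5 correction on zero cells; the exact P never does.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N, K, n = a + b + c + d, a + c, a + b
    orr = haldane_odds_ratio(table)
    if N == 0:
        return 1.0, orr
    k_min, k_max = max(0, n - (N - K)), min(n, K)
    ks = np.arange(k_min, k_max + 1)
    log_pmf = _log_choose(K, ks) + _log_choose(N - K, n - ks) - _log_choose(N, n)
    log_obs = log_pmf[a - k_min]
    keep = log_pmf <= log_obs + math.log1p(TIE_RELATIVE_TOLERANCE)
    p = float(np.exp(logsumexp(log_pmf[keep])))
    return min(p, 1.0), orr


def bonferroni_adjust(p_values: Sequence[float], n_tests: int) -> list[float]:
    """Family-wise Bonferroni adjustment: q_i = min(1, p_i · n_tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if n_tests < len(p_values):
        raise ValueError("n_tests must be at least the number of p-values")
    return [min(1.0, p * n_tests) for p in p_values]


# ---------------------------------------------------------------------------
# module enumeration and counting


def select_driver_genes(
    matrix: MutationMatrix, driver_list: Sequence[str], min_met_samples: int = 5
) -> list[str]:
    """Drivers with nonsilent mutations in at least ``min_met_samples`` metastatic samples.

    Returned in descending order of metastatic carrier count, ties broken
    alphabetically, so downstream enumeration is deterministic.
    """
    if not driver_list:
        raise ValueError("driver_list must be nonempty")
    met = matrix.cohort_mask(METASTATIC)
    gidx = matrix.gene_index
    counts: dict[str, int] = {}
    for gene in {g.upper() for g in driver_list}:
        j = gidx.get(gene)
        counts[gene] = int(matrix.indicator[met, j].sum()) if j is not None else 0
    kept = [g for g, n in counts.items() if n >= min_met_samples]
    if not kept:
        log.warning(
            "no driver gene reaches %d metastatic carriers in %s",
            min_met_samples,
            matrix.cancer_type,
        )
    return sorted(kept, key=lambda g: (-counts[g], g))


def enumerate_modules(genes: Sequence[str], max_size: int) -> list[GeneModule]:
    """All gene subsets of size 1..max_size, in canonical order."""
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    if max_size > len(genes):
        log.warning("max_size %d exceeds gene count %d; capping", max_size, len(genes))
        max_size = len(genes)
    ordered = sorted(set(genes))
    return [
        GeneModule(combo)
        for k in range(1, max_size + 1)
        for combo in itertools.combinations(ordered, k)
    ]


def module_carrier_count(matrix: MutationMatrix, module: GeneModule, cohort: str) -> int:
    """Number of cohort samples nonsilently mutated in EVERY gene of the module."""
    gidx = matrix.gene_index
    missing = [g for g in module.genes if g not in gidx]
    if missing:
        raise KeyError(f"genes absent from the mutation matrix: {missing}")
    cols = [gidx[g] for g in module.genes]
    carrier = matrix.indicator[:, cols].all(axis=1)
    return int(carrier[matrix.cohort_mask(cohort)].sum())


# ---------------------------------------------------------------------------
# enrichment run


@dataclass
class EnrichmentConfig:
    """Knobs for an enrichment run.

    min_met_samples: a driver gene enters the analysis only if nonsilently
        mutated in at least this many metastatic samples (default 5).
    max_module_size: largest module enumerated (default 3 genes).
    alpha / alpha_strict: the q-value thresholds flagged as * and **.
    max_modules: guard rail — refuse to enumerate more modules than this
        unless ``force`` is set.
    """

    min_met_samples: int = 5
    max_module_size: int = 3
    alpha: float = 0.05
    alpha_strict: float = 0.01
    max_modules: int = 1_000_000
    force: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    """One module's 2×2 counts, odds ratio, Fisher P and Bonferroni q."""

    cancer_type: str
    module: GeneModule
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    q_value: float
    n_tests: int
    enriched_in: str  # metastatic | early_primary | none

    def significance(self, alpha: float = 0.05, alpha_strict: float = 0.01) -> str:
        if self.q_value < alpha_strict:
            return "**"
        if self.q_value < alpha:
            return "*"
        return ""


def _direction(odds_ratio: float) -> str:
    if odds_ratio > 1:
        return METASTATIC
    if odds_ratio < 1:
        return EARLY_PRIMARY
    return "none"


def run_enrichment(
    matrix: MutationMatrix,
    driver_list: Sequence[str],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Full per-cancer-type enrichment: driver selection, module enumeration,
    Fisher test per module, Bonferroni over the modules actually tested.

    Results are sorted by q, then P, then module size, then gene list.
    """
    config = config or EnrichmentConfig()
    if matrix.n_metastatic == 0 or matrix.n_early == 0:
        raise ValueError("both cohorts must be nonempty")
    drivers = select_driver_genes(matrix, driver_list, config.min_met_samples)
    if not drivers:
        return []
    max_size = min(config.max_module_size, len(drivers))
    n_modules = sum(math.comb(len(drivers), k) for k in range(1, max_size + 1))
    if n_modules > config.max_modules and not config.force:
        raise ValueError(
            f"{n_modules} modules would be enumerated (> {config.max_modules}); "
            "raise max_modules or set force=True"
        )
    modules = enumerate_modules(drivers, config.max_module_size)
    met = matrix.cohort_mask(METASTATIC)
    n_met = int(met.sum())
    n_early = len(matrix.sample_ids) - n_met
    gidx = matrix.gene_index
    indicator = matrix.indicator

    raw: list[tuple[GeneModule, ContingencyTable, float, float]] = []
    for module in modules:
        cols = [gidx[g] for g in module.genes]
        carrier = indicator[:, cols[0]] if len(cols) == 1 else indicator[:, cols].all(axis=1)
        a = int(carrier[met].sum())
        c = int(carrier.sum()) - a
        table = ContingencyTable(a, n_met - a, c, n_early - c)
        p, orr = fisher_exact_two_sided(table)
        raw.append((module, table, p, orr))

    m = len(modules)
    qs = bonferroni_adjust([p for _, _, p, _ in raw], m)
    results = [
        EnrichmentResult(
            cancer_type=matrix.cancer_type,
            module=module,
            table=table,
            odds_ratio=orr,
            p_value=p,
            q_value=q,
            n_tests=m,
            enriched_in=_direction(orr),
        )
        for (module, table, p, orr), q in zip(raw, qs)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, len(r.module), r.module.genes))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular result export; modules are hyphenated as in APC-PTPRT-TP53."""
    rows = [
        {
            "cancer_type": r.cancer_type,
            "module": r.module.name,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "met_freq": r.table.met_freq,
            "early_freq": r.table.early_freq,
            "odds_ratio": r.odds_ratio,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "n_tests": r.n_tests,
            "enriched_in": r.enriched_in,
            "significance": r.significance(),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "module", "a", "b", "c", "d", "met_freq", "early_freq",
            "odds_ratio", "p_value", "q_value", "n_tests", "enriched_in", "significance",
        ],
    )
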