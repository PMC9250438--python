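"""Kaplan–Meier estimation and the log-rank test for alteration strata.

Samples are dichotomised into an *altered* group (at least one nonsilent
mutation in at least one gene of interest) and a *wild-type* group, and
their time-to-event distributions are compared.  The estimator and test
are implemented directly from their definitions:

* Kaplan–Meier: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over the distinct event
  times t_i, with d_i events and n_i subjects at risk just before t_i;
  subjects censored at t_i are still at risk at t_i (events precede
  censorings at tied times).
* Log-rank: at each distinct event time the expected number of group-1
  events under the null is E_1 += d·n_1/n with hypergeometric variance
  V += d·(n_1/n)·(n_2/n)·(n−d)/(n−1); the statistic (O_1−E_1)²/V is
  referred to a χ² distribution with 1 degree of freedom.

The module is endpoint-agnostic: which clinical column supplies the time
and event (progression-free vs overall survival) is the caller's choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort_io import MutationMatrix

log = logging.getLogger(__name__)

ALTERED = "altered"
WILD_TYPE = "wild_type"


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample's follow-up: time in months and whether the event was observed."""

    sample_id: str
    time: float
    event: bool
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


@dataclass
class KMCurve:
    """Kaplan–Meier step function evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event (right-continuous step function)."""
        i = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank summary: O/E per group, variance, χ²(1) and P."""

    observed: tuple[float, float]
    expected: tuple[float, float]
    variance: float
    chi_square: float
    p_value: float
    n_groups: tuple[int, int]
    df: int = 1


def read_survival_table(path) -> list[SurvivalRecord]:
    """Read a TSV with columns SAMPLE_ID, TIME_MONTHS, EVENT (0/1)."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("SAMPLE_ID", "TIME_MONTHS", "EVENT"):
        if col not in frame.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    return [
        SurvivalRecord(str(r.SAMPLE_ID), float(r.TIME_MONTHS), bool(int(r.EVENT)))
        for r in frame.itertuples(index=False)
    ]


def group_by_alteration(
    matrix: MutationMatrix,
    genes: Sequence[str],
    survival_table: Sequence[SurvivalRecord],
) -> list[SurvivalRecord]:
    """Label each survival record altered / wild-type by mutation status.

    A sample is *altered* iff it carries ≥1 nonsilent mutation in ≥1 of
    the listed genes; samples present in the matrix but without any such
    mutation are wild-type.  Survival records whose sample is not in the
    matrix are dropped with a logged count.
    """
    gene_set = {g.upper() for g in genes}
    if not gene_set:
        raise ValueError("gene set must be nonempty")
    gidx = matrix.gene_index
    missing = sorted(g for g in gene_set if g not in gidx)
    if missing:
        raise KeyError(f"genes absent from the mutation matrix: {missing}")
    cols = [gidx[g] for g in sorted(gene_set)]
    altered_vec = matrix.indicator[:, cols].any(axis=1)
    altered_ids = {s for s, alt in zip(matrix.sample_ids, altered_vec) if alt}
    known = set(matrix.sample_ids)
    labeled: list[SurvivalRecord] = []
    dropped = 0
    for rec in survival_table:
        if rec.sample_id not in known:
            dropped += 1
            continue
        labeled.append(replace(rec, group=ALTERED if rec.sample_id in altered_ids else WILD_TYPE))
    if dropped:
        log.warning("dropped %d survival records with samples absent from the matrix", dropped)
    return labeled


def split_groups(records: Sequence[SurvivalRecord]) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    altered = [r for r in records if r.group == ALTERED]
    wild = [r for r in records if r.group == WILD_TYPE]
    return altered, wild


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit estimate of the survivor function."""
    if not records:
        raise ValueError("at least one survival record is required")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    event_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    n_events = np.array([(events & (times == t)).sum() for t in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(event_times, survival, at_risk, n_events)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-group log-rank test; invariant to which group is passed first."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta = np.array([r.time for r in group_a], dtype=float)
    ea = np.array([r.event for r in group_a], dtype=bool)
    tb = np.array([r.time for r in group_b], dtype=float)
    eb = np.array([r.event for r in group_b], dtype=bool)
    o1, o2 = float(ea.sum()), float(eb.sum())
    total_events = o1 + o2
    if total_events == 0:
        warnings.warn("no events in either group; log-rank P set to 1", stacklevel=2)
        return LogRankResult((0.0, 0.0), (0.0, 0.0), 0.0, 0.0, 1.0, (len(group_a), len(group_b)))
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    e1 = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d = int((ea & (ta == t)).sum()) + int((eb & (tb == t)).sum())
        e1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var > 0:
        chi_square = (o1 - e1) ** 2 / var
        p_value = float(chi2.sf(chi_square, df=1))
    else:
        chi_square, p_value = 0.0, 1.0
    return LogRankResult(
        observed=(o1, o2),
        expected=(e1, total_events - e1),
        variance=var,
        chi_square=chi_square,
        p_value=p_value,
        n_groups=(len(group_a), len(group_b)),
    )
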