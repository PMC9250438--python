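"""Reading, normalisation and cohort assignment for panel-sequencing cohorts.

This module turns MAF-style somatic mutation tables and clinical sample
tables into the two analysis cohorts the enrichment test compares:

* ``metastatic`` — metastasis-tissue samples plus stage-IV primaries;
* ``early_primary`` — primary tumours of stages I–III.

Samples known to be microsatellite-instability-high (MSI-H) are excluded
because their globally elevated mutation load would confound gene-level
frequency comparisons; samples of unknown tissue origin, and primary
samples whose stage is not recorded, are excluded as well.  The retained
samples are summarised per cancer type as a boolean sample × gene matrix
whose entries flag the presence of at least one *nonsilent* (protein
altering) mutation: missense, frameshift, nonsense, nonstop, splice-site
or translation-start-site calls.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

# cohort labels
METASTATIC = "metastatic"
EARLY_PRIMARY = "early_primary"
EXCLUDED = "excluded"

# exclusion reasons
MSI_H_EXCLUDED = "msi_h"
UNKNOWN_ORIGIN = "unknown_origin"
UNKNOWN_STAGE_PRIMARY = "unknown_stage_primary"
ASSAY_FILTERED = "assay_filtered"

UNKNOWN = "unknown"


class ConfigurationError(ValueError):
    """Raised when an input table does not match the configured dialect."""


def _norm_token(value: object) -> str:
    """Normalise a vocabulary token: lowercase, strip all punctuation."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return re.sub(r"[^0-9a-z]", "", str(value).lower())


def _load_variant_vocabulary() -> tuple[frozenset[str], frozenset[str]]:
    raw = yaml.safe_load(
        resources.files("metamod").joinpath("data/variant_classes.yaml").read_text()
    )
    nonsilent = {
        _norm_token(tok)
        for tokens in raw["nonsilent"].values()
        for tok in tokens
    }
    silent = {_norm_token(tok) for tok in raw["silent"]}
    return frozenset(nonsilent), frozenset(silent)


_NONSILENT_TOKENS, _SILENT_TOKENS = _load_variant_vocabulary()


def classify_nonsilent(variant_classification: str) -> bool:
    """Return True if a variant-classification token is protein altering.

    The nonsilent set comprises missense, frameshift (insertion or
    deletion), nonsense, nonstop, splice-site and translation-start-site
    calls; everything else (silent, UTR, intronic, unknown tokens) is
    treated as silent.  Matching is case- and punctuation-insensitive.
    """
    if not variant_classification or not str(variant_classification).strip():
        raise ValueError("variant_classification must be a nonempty token")
    return _norm_token(variant_classification) in _NONSILENT_TOKENS


def is_known_variant_class(variant_classification: str) -> bool:
    tok = _norm_token(variant_classification)
    return tok in _NONSILENT_TOKENS or tok in _SILENT_TOKENS


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (sample, gene, variant classification)."""

    sample_id: str
    gene: str
    variant_classification: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene or not self.variant_classification:
            raise ValueError("sample_id, gene and variant_classification must be nonempty")

    @property
    def nonsilent(self) -> bool:
        return classify_nonsilent(self.variant_classification)


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one sequenced sample, already normalised."""

    sample_id: str
    patient_id: str
    cancer_type: str
    sample_type: str  # primary | metastasis | unknown
    stage: str  # I | II | III | IV | unknown
    msi_status: str  # MSS | MSI-H | unknown
    assay_id: str = UNKNOWN


@dataclass(frozen=True)
class CohortAssignment:
    """The cohort label given to one sample, with the exclusion reason if any."""

    sample_id: str
    label: str  # metastatic | early_primary | excluded
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if (self.label == EXCLUDED) != (self.exclusion_reason is not None):
            raise ValueError("excluded assignments (and only those) carry a reason")


@dataclass
class FilterConfig:
    """Sample-level filters applied before cohort assignment.

    assay_allowlist restricts the analysis to samples sequenced on the
    listed panels (e.g. the MSK-IMPACT assays); when None, no panel
    restriction is applied.
    """

    assay_allowlist: frozenset[str] | None = None


# ---------------------------------------------------------------------------
# table dialects


@dataclass(frozen=True)
class MutationDialect:
    sample_id: str = "Tumor_Sample_Barcode"
    gene: str = "Hugo_Symbol"
    variant_classification: str = "Variant_Classification"
    protein_change: str = "HGVSp_Short"


@dataclass(frozen=True)
class ClinicalDialect:
    sample_id: str = "SAMPLE_ID"
    patient_id: str = "PATIENT_ID"
    cancer_type: str = "CANCER_TYPE"
    sample_type: str = "SAMPLE_TYPE"
    stage: str = "STAGE"
    msi_status: str = "MSI_STATUS"
    assay_id: str = "SEQ_ASSAY_ID"


_STAGE_MAP = {
    "i": "I", "1": "I",
    "ii": "II", "2": "II",
    "iii": "III", "3": "III",
    "iv": "IV", "4": "IV",
}

_SAMPLE_TYPE_MAP = {
    "primary": "primary",
    "primarytumor": "primary",
    "primarytumour": "primary",
    "metastasis": "metastasis",
    "metastatic": "metastasis",
    "metastasistissue": "metastasis",
    "metastaticrecurrence": "metastasis",
}

_MSI_MAP = {
    "mss": "MSS",
    "stable": "MSS",
    "msistable": "MSS",
    "microsatellitestable": "MSS",
    "msih": "MSI-H",
    "msihigh": "MSI-H",
    "instabilityhigh": "MSI-H",
    "msiinstabilityhigh": "MSI-H",
}


def normalize_stage(value: object) -> str:
    tok = _norm_token(value)
    if tok.startswith("stage"):
        tok = tok[len("stage"):]
    # drop sub-stage letters: IIA -> II, but leave "iv" intact
    if tok not in _STAGE_MAP:
        tok = re.sub(r"[abc]+$", "", tok)
    return _STAGE_MAP.get(tok, UNKNOWN)


def normalize_sample_type(value: object) -> str:
    return _SAMPLE_TYPE_MAP.get(_norm_token(value), UNKNOWN)


def normalize_msi(value: object) -> str:
    return _MSI_MAP.get(_norm_token(value), UNKNOWN)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        log.warning("input table %s is empty", path)
        return pd.DataFrame()


def mutation_records_from_frame(
    frame: pd.DataFrame, dialect: MutationDialect = MutationDialect()
) -> list[MutationRecord]:
    """Build MutationRecords from a MAF-style DataFrame.

    Rows with an empty sample or gene field are dropped (count logged);
    gene symbols are uppercased.
    """
    if frame.empty:
        return []
    for col in (dialect.sample_id, dialect.gene, dialect.variant_classification):
        if col not in frame.columns:
            raise ConfigurationError(f"mutation table is missing mapped column {col!r}")
    has_protein = dialect.protein_change in frame.columns
    samples = frame[dialect.sample_id].to_numpy()
    genes = frame[dialect.gene].to_numpy()
    classes = frame[dialect.variant_classification].to_numpy()
    proteins = frame[dialect.protein_change].to_numpy() if has_protein else [None] * len(frame)
    records = []
    dropped = 0
    for s, g, vc, pc in zip(samples, genes, classes, proteins):
        if not _nonempty(s) or not _nonempty(g) or not _nonempty(vc):
            dropped += 1
            continue
        records.append(
            MutationRecord(
                sample_id=str(s).strip(),
                gene=str(g).strip().upper(),
                variant_classification=str(vc).strip(),
                protein_change=str(pc).strip() if _nonempty(pc) else None,
            )
        )
    if dropped:
        log.warning("dropped %d mutation rows with empty sample/gene/class fields", dropped)
    unknown = Counter(
        r.variant_classification for r in records if not is_known_variant_class(r.variant_classification)
    )
    if unknown:
        log.info("unrecognised variant classifications treated as silent: %s", dict(unknown))
    return records


def _nonempty(value: object) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and np.isnan(value):
        return False
    return bool(str(value).strip())


def read_mutation_table(path, dialect: MutationDialect = MutationDialect()) -> list[MutationRecord]:
    """Read a tab-separated MAF-style mutation table from disk."""
    return mutation_records_from_frame(_read_tsv(path), dialect)


def sample_records_from_frame(
    frame: pd.DataFrame, dialect: ClinicalDialect = ClinicalDialect()
) -> list[SampleRecord]:
    """Build normalised SampleRecords from a clinical DataFrame.

    Stage, sample-type and MSI values are normalised case-insensitively;
    unrecognised values map to ``unknown`` and are tallied in the log.
    Duplicate sample IDs raise an error listing the duplicates.
    """
    if frame.empty:
        return []
    if dialect.sample_id not in frame.columns:
        raise ConfigurationError(f"clinical table is missing mapped column {dialect.sample_id!r}")
    ids = frame[dialect.sample_id].astype(str).str.strip()
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate sample_id values in clinical table: {dup}")

    def col(name: str) -> Iterable[object]:
        if name in frame.columns:
            return frame[name].to_numpy()
        return [None] * len(frame)

    unknown_tally: Counter[str] = Counter()
    records: list[SampleRecord] = []
    for sid, pid, ct, st, stage, msi, assay in zip(
        ids,
        col(dialect.patient_id),
        col(dialect.cancer_type),
        col(dialect.sample_type),
        col(dialect.stage),
        col(dialect.msi_status),
        col(dialect.assay_id),
    ):
        stype = normalize_sample_type(st)
        nstage = normalize_stage(stage)
        nmsi = normalize_msi(msi)
        if stype == UNKNOWN and _nonempty(st):
            unknown_tally[f"sample_type:{st}"] += 1
        if nstage == UNKNOWN and _nonempty(stage):
            unknown_tally[f"stage:{stage}"] += 1
        if nmsi == UNKNOWN and _nonempty(msi):
            unknown_tally[f"msi:{msi}"] += 1
        records.append(
            SampleRecord(
                sample_id=sid,
                patient_id=str(pid).strip() if _nonempty(pid) else UNKNOWN,
                cancer_type=str(ct).strip() if _nonempty(ct) else UNKNOWN,
                sample_type=stype,
                stage=nstage,
                msi_status=nmsi,
                assay_id=str(assay).strip() if _nonempty(assay) else UNKNOWN,
            )
        )
    if unknown_tally:
        log.info("unrecognised clinical values normalised to 'unknown': %s", dict(unknown_tally))
    return records


def read_clinical_table(path, dialect: ClinicalDialect = ClinicalDialect()) -> list[SampleRecord]:
    """Read a tab-separated clinical sample table from disk."""
    return sample_records_from_frame(_read_tsv(path), dialect)


# ---------------------------------------------------------------------------
# cohort assignment


def assign_cohort(sample: SampleRecord, filters: FilterConfig | None = None) -> CohortAssignment:
    """Assign one sample to the metastatic or early-primary cohort.

    Rules, in order: known MSI-H samples are excluded; samples of unknown
    tissue origin are excluded; samples sequenced on a panel outside the
    configured allow-list (when one is configured) are excluded; metastasis
    tissue or stage-IV disease puts a sample in the metastatic cohort
    (each such sample counts once); stage I–III primaries form the
    early-primary cohort; primaries of unknown stage are excluded because
    cohort membership cannot be decided for them.
    """
    filters = filters or FilterConfig()
    if sample.msi_status == "MSI-H":
        return CohortAssignment(sample.sample_id, EXCLUDED, MSI_H_EXCLUDED)
    if sample.sample_type == UNKNOWN:
        return CohortAssignment(sample.sample_id, EXCLUDED, UNKNOWN_ORIGIN)
    if filters.assay_allowlist is not None and sample.assay_id not in filters.assay_allowlist:
        return CohortAssignment(sample.sample_id, EXCLUDED, ASSAY_FILTERED)
    if sample.sample_type == "metastasis" or sample.stage == "IV":
        return CohortAssignment(sample.sample_id, METASTATIC)
    if sample.stage in ("I", "II", "III"):
        return CohortAssignment(sample.sample_id, EARLY_PRIMARY)
    return CohortAssignment(sample.sample_id, EXCLUDED, UNKNOWN_STAGE_PRIMARY)


def assign_cohorts(
    samples: Sequence[SampleRecord], filters: FilterConfig | None = None
) -> list[CohortAssignment]:
    return [assign_cohort(s, filters) for s in samples]


def assignments_frame(
    samples: Sequence[SampleRecord], assignments: Sequence[CohortAssignment]
) -> pd.DataFrame:
    """Normalised cohort table (sample_id, cancer_type, label, exclusion_reason)."""
    by_id = {a.sample_id: a for a in assignments}
    rows = [
        {
            "sample_id": s.sample_id,
            "cancer_type": s.cancer_type,
            "label": by_id[s.sample_id].label,
            "exclusion_reason": by_id[s.sample_id].exclusion_reason or "",
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["sample_id", "cancer_type", "label", "exclusion_reason"])


# ---------------------------------------------------------------------------
# mutation matrix


@dataclass
class MutationMatrix:
    """Sample × gene nonsilent-mutation indicator for one cancer type.

    ``indicator[i, j]`` is True iff sample ``sample_ids[i]`` carries at
    least one nonsilent mutation in ``genes[j]``.  Only samples assigned
    to one of the two analysis cohorts are present; ``cohort_of`` maps
    each sample to its cohort label.
    """

    cancer_type: str
    sample_ids: list[str]
    genes: list[str]
    indicator: np.ndarray
    cohort_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.indicator.shape != (len(self.sample_ids), len(self.genes)):
            raise ValueError("indicator dimensions do not match id lists")
        missing = [s for s in self.sample_ids if s not in self.cohort_of]
        if missing:
            raise ValueError(f"samples without a cohort label: {missing[:5]}")

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cohort_mask(self, label: str) -> np.ndarray:
        return np.array([self.cohort_of[s] == label for s in self.sample_ids], dtype=bool)

    @property
    def n_metastatic(self) -> int:
        return int(self.cohort_mask(METASTATIC).sum())

    @property
    def n_early(self) -> int:
        return int(self.cohort_mask(EARLY_PRIMARY).sum())


def build_mutation_matrix(
    mutations: Sequence[MutationRecord],
    samples: Sequence[SampleRecord],
    assignments: Sequence[CohortAssignment],
    cancer_type: str,
) -> MutationMatrix:
    """Assemble the nonsilent indicator matrix for one cancer type.

    Exactly the non-excluded samples of that cancer type appear (sorted by
    sample ID for determinism); silent mutations and mutations from
    excluded or unknown samples contribute nothing.  Mutations referencing
    samples absent from the clinical table are dropped with a logged count.
    """
    label_of = {a.sample_id: a.label for a in assignments}
    clinical_ids = {s.sample_id for s in samples}
    included = sorted(
        s.sample_id
        for s in samples
        if s.cancer_type == cancer_type and label_of.get(s.sample_id) != EXCLUDED
    )
    if any(s.sample_id not in label_of for s in samples if s.cancer_type == cancer_type):
        raise ValueError("assignments do not cover all samples of the cancer type")
    included_set = set(included)
    pairs: set[tuple[str, str]] = set()
    unknown_samples = 0
    for m in mutations:
        if m.sample_id not in clinical_ids:
            unknown_samples += 1
            continue
        if m.sample_id not in included_set:
            continue
        if m.nonsilent:
            pairs.add((m.sample_id, m.gene))
    if unknown_samples:
        log.warning(
            "dropped %d mutations referencing samples absent from the clinical table",
            unknown_samples,
        )
    genes = sorted({g for _, g in pairs})
    indicator = np.zeros((len(included), len(genes)), dtype=bool)
    sidx = {s: i for i, s in enumerate(included)}
    gidx = {g: i for i, g in enumerate(genes)}
    for s, g in pairs:
        indicator[sidx[s], gidx[g]] = True
    cohort_of = {s: label_of[s] for s in included}
    return MutationMatrix(
        cancer_type=cancer_type,
        sample_ids=included,
        genes=genes,
        indicator=indicator,
        cohort_of=cohort_of,
    )
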