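import numpy as np
import pandas as pd
import pytest

from metamod.cohort_io import (
    EARLY_PRIMARY,
    METASTATIC,
    MutationMatrix,
)


@pytest.fixture
def clinical_frame() -> pd.DataFrame:
    """Six-sample clinical table covering every assignment rule."""
    return pd.DataFrame(
        {
            "SAMPLE_ID": ["S1", "S2", "S3", "S4", "S5", "S6"],
            "PATIENT_ID": ["P1", "P2", "P3", "P4", "P5", "P6"],
            "CANCER_TYPE": ["CRC"] * 6,
            "SAMPLE_TYPE": ["Primary", "Metastasis", "Primary", "Primary", "Unknown", "Primary"],
            "STAGE": ["Stage II", "Stage I", "Stage IV", "Stage III", "Stage II", "N/A"],
            "MSI_STATUS": ["MSS", "MSS", "MSS", "MSI-High", "MSS", "MSS"],
            "SEQ_ASSAY_ID": ["IMPACT468"] * 6,
        }
    )


@pytest.fixture
def mutation_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Tumor_Sample_Barcode": ["S1", "S1", "S2", "S3", "S4", "S6", "SX"],
            "Hugo_Symbol": ["PTPRT", "PTPRT", "APC", "TP53", "PTPRT", "APC", "TP53"],
            "Variant_Classification": [
                "Missense_Mutation",
                "Nonsense_Mutation",
                "Frame_Shift_Del",
                "Silent",
                "Missense_Mutation",
                "Splice_Site",
                "Missense_Mutation",
            ],
            "HGVSp_Short": ["p.G826R", "p.R100*", "p.T200fs", "p.L50=", "p.A1V", "", "p.Q2H"],
        }
    )


def toy_matrix(indicator, cohorts, genes=None, cancer_type="TOY") -> MutationMatrix:
    """Small hand-built matrix; cohorts is a list of 'M'/'E' flags."""
    indicator = np.asarray(indicator, dtype=bool)
    n, g = indicator.shape
    sample_ids = [f"S{i}" for i in range(n)]
    genes = genes or [f"G{j}" for j in range(g)]
    cohort_of = {
        s: (METASTATIC if flag == "M" else EARLY_PRIMARY)
        for s, flag in zip(sample_ids, cohorts)
    }
    return MutationMatrix(cancer_type, sample_ids, list(genes), indicator, cohort_of)
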