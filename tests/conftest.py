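import numpy as np
import pandas as pd
import pytest

from cqnorm.cq_data import AssayPanel, CqDataset, SampleSheet
from cqnorm.quantification import RQMatrix


def make_rq(gene_values: dict[str, list[float]], log2_se: float = 0.0) -> RQMatrix:
    """RQ matrix straight from linear-scale values (uniform log2 SE)."""
    values = pd.DataFrame(gene_values).T
    values.columns = [f"S{i + 1}" for i in range(values.shape[1])]
    values.index.name = "assay_id"
    se = pd.DataFrame(log2_se, index=values.index, columns=values.columns)
    af = pd.Series(2.0, index=values.index)
    return RQMatrix(values=values, log2_se=se, reference_point="min_cq",
                    amplification_factors=af)


def make_dataset(cq_by_sample_assay: dict, groups: dict[str, str] | None = None,
                 roles: dict[str, str] | None = None,
                 plate_of_sample: dict[str, str] | None = None) -> CqDataset:
    """Dataset from {(sample, assay): [replicate Cqs (None = undetected)]}."""
    rows = []
    for (sample, assay), reps in cq_by_sample_assay.items():
        plate = (plate_of_sample or {}).get(sample, "plate1")
        for r, cq in enumerate(reps, start=1):
            rows.append((sample, assay, r, plate, np.nan if cq is None else cq))
    measurements = pd.DataFrame(
        rows, columns=["sample_id", "assay_id", "replicate", "plate_id", "cq"]
    )
    sample_ids = sorted({s for s, _ in cq_by_sample_assay})
    assay_ids = sorted({a for _, a in cq_by_sample_assay})
    groups = groups or {}
    samples = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "group": [groups.get(s, "tumour" if s.startswith("T") else "normal")
                  for s in sample_ids],
    }))
    roles = roles or {}
    panel = AssayPanel(pd.DataFrame({
        "assay_id": assay_ids,
        "role": [roles.get(a, "reference_candidate") for a in assay_ids],
    }))
    return CqDataset(measurements, samples, panel)


@pytest.fixture
def toy_rq() -> RQMatrix:
    """Three genes over four samples: A and B in constant ratio, C flat."""
    return make_rq({"A": [1, 2, 4, 8], "B": [1, 2, 4, 8], "C": [1, 1, 1, 1]})
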