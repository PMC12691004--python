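"""Feature-table assembly and modality-block conventions.

Feature tables are pandas DataFrames (patients x features) whose column
prefixes encode the modality block:

* ``clin_``  -- 8 clinical covariates (numeric + full one-hot categorical),
* ``dvh_``   -- 12 dose-volume parameters,
* ``hcr_``   -- handcrafted radiomics (105 per ROI),
* ``dlr_original_`` / ``dlr_skin5mm_`` / ``dlr_ptv100_`` / ``dlr_v5gy_``
  -- deep features per input design (4224 each).

Categorical one-hot encoding keeps every level (no reference drop);
regularized models absorb the collinearity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dosederm.core import ClinicalRecord

BLOCKS = ("clinical", "dvh", "hcr", "dlr_original", "dlr_skin5mm",
          "dlr_ptv100", "dlr_v5gy")

_PREFIX = {
    "clinical": "clin_", "dvh": "dvh_", "hcr": "hcr_",
    "dlr_original": "dlr_original_", "dlr_skin5mm": "dlr_skin5mm_",
    "dlr_ptv100": "dlr_ptv100_", "dlr_v5gy": "dlr_v5gy_",
}


def block_of(column: str) -> str:
    """Modality block a feature column belongs to (longest-prefix match)."""
    for block in sorted(_PREFIX, key=lambda b: -len(_PREFIX[b])):
        if column.startswith(_PREFIX[block]):
            return block
    raise ValueError(f"column {column!r} matches no modality block")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "clin_age": r.age,
            "clin_bmi": r.bmi,
            "clin_laterality_left": float(r.laterality == "left"),
            "clin_laterality_right": float(r.laterality == "right"),
            "clin_surgery_tm_mrm": float(r.surgery == "TM/MRM"),
            "clin_surgery_bcs": float(r.surgery == "BCS"),
            "clin_scf": float(r.scf),
            "clin_imn": float(r.imn),
            "clin_chemotherapy": float(r.chemotherapy),
        }
        for stage in range(5):
            row[f"clin_ajcc_{stage}"] = float(r.ajcc_stage == stage)
        rows.append(row)
    return pd.DataFrame(rows, index=[r.patient_id for r in records])


def dvh_frame(dvh_dicts: list[dict], patient_ids: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(dvh_dicts, index=patient_ids)
    return df.rename(columns={c: f"dvh_{c}" for c in df.columns})


def labels_from_records(records: list[ClinicalRecord]) -> pd.Series:
    return pd.Series([int(r.rd_grade_ge2) for r in records],
                     index=[r.patient_id for r in records], name="rd_grade_ge2")


def combine_blocks(frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-wise concatenation with index alignment and name checks."""
    parts = []
    for block, df in frames.items():
        bad = [c for c in df.columns if block_of(c) != block]
        if bad:
            raise ValueError(f"columns {bad[:3]} not tagged for block {block}")
        parts.append(df)
    out = pd.concat(parts, axis=1)
    if out.columns.duplicated().any():
        raise ValueError("duplicate feature names across blocks")
    if out.isna().any().any():
        raise ValueError("feature table contains missing values")
    return out


def cohort_feature_table(cohort) -> tuple[pd.DataFrame, pd.Series]:
    """Clinical + DVH table straight from a synthetic cohort object."""
    records = [p.record for p in cohort.patients]
    ids = [r.patient_id for r in records]
    X = combine_blocks({
        "clinical": clinical_frame(records),
        "dvh": dvh_frame([p.dvh for p in cohort.patients], ids),
    })
    return X, labels_from_records(records)


def population_feature_table(records, dvh_arrays: dict) -> pd.DataFrame:
    """Clinical + DVH table from the covariate-level sampler output."""
    ids = [r.patient_id for r in records]
    dvh = pd.DataFrame({f"dvh_{k}": np.asarray(v) for k, v in dvh_arrays.items()},
                       index=ids)
    return combine_blocks({"clinical": clinical_frame(records), "dvh": dvh})
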